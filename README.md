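# genarc

Compressed, random-access archives of collections of assembled genomes of
one species — pangenome assembly sets, haplotype panels, bacterial isolate
collections.  Such collections are hugely redundant (two human haplotypes
differ by ~0.1%), yet general-purpose compressors neither exploit that
redundancy across files nor let you pull out one contig without
decompressing everything.  `genarc` stores a collection so that the archive
grows only marginally per added sample and any contig, range, sample or the
whole collection can be extracted by decompressing only the few frames the
query touches.  Archives can be extended in place with new samples.

## Method

Compression is a three-stage process.

1. **Candidate k-mers.**  All canonical k-mers (k = 31 by default; the
   lexicographic minimum of a k-mer and its reverse complement) of a
   user-supplied reference genome are counted; those occurring exactly once
   are *candidates*.
2. **Splitters.**  Each reference contig is scanned left to right: the
   first candidate occurrence becomes a *splitter*, the scan resumes one
   *segment size* (60 kb by default) later, and the last candidate of the
   contig is also kept.  This yields roughly `L / segment_size` splitters
   spread uniformly over the reference.
3. **Adding genomes.**  Every contig of every added genome (the reference
   is added first) is cut at splitter occurrences into *segments*; a
   splitter's k bases belong to both neighboring segments.  Segments are
   grouped by their terminating splitter pair, after normalizing
   orientation so the lexicographically smaller canonical splitter comes
   first (group identity is strand-free).  The first segment of a group is
   its reference, stored radix-packed (4, 3 or 2 symbols/byte depending on
   the segment's alphabet) and zstd-compressed; every later member is
   LZSS-parsed against it into literal/match tokens, and up to *block
   size* (50) such descriptions are concatenated and zstd-compressed as
   one frame — the unit of random access.

   Segments with one terminating splitter (contig boundaries) join the
   cheapest existing group sharing that splitter, or found a new group;
   segments with none are distributed by a deterministic content hash into
   16 bucket groups.  When a segment spans a pair (s1, s2) with no group
   but groups (s1, s3) and (s3, s2) exist, the middle splitter is taken to
   be missing from that haplotype (an evolutionary event) and the segment
   is split at the cost-optimal division point — computed exactly by one
   forward and one backward LZSS cost pass — into two one-splitter members
   of the flanking groups.

An *adaptive* mode for divergent collections (e.g. bacteria) buffers the
contigs of each incoming sample that match no splitter, extends the
splitter set from k-mers unique to that buffer and absent from the
reference, and re-segments the buffer once, so later samples of the same
clade compress as ordinary two-splitter groups.

The archive is a single file of zstd frames plus zstd-compressed metadata
(contig descriptions: group id, in-group segment id, orientation, length,
overlap per segment).  Appending loads the directory, touches only
partially filled tail blocks, writes new frames after the existing data
region, and never rewrites a sealed frame.  Archive bytes are a pure
function of inputs and parameters: identical runs produce identical files.

## Worked example

```
$ genarc simulate --seed 7 --out-dir demo --ref-len 200000 --samples 4
wrote 5 FASTA files to demo
$ cd demo
$ genarc create -o pan.gar -k 31 --segment-size 10000 ref.fa sample01.fa sample02.fa sample03.fa
$ genarc append -o pan.gar sample04.fa
$ genarc listset pan.gar
ref
sample01
sample02
sample03
sample04
$ genarc info pan.gar
{
  "samples": 5,
  "contigs": 12,
  "splitters": 21,
  "groups": {"pair": 21, "single": 2, "bucket": 0, "total": 23},
  ...
  "file_size": 75357,
  ...
}
$ genarc getctg pan.gar sample02_ctg001:1001-1080
>sample02_ctg001
TCCTCTACTTGCTCGGCAGCGGTTGAAGGTCCAAAGGACGCCCGTCCCAGTGAAATCCTCACCAGCTTCGTAAAACTTCC
```

Five genomes of 200 kb each (about 1 MB of FASTA) compress to a 75 kB
archive: the reference accounts for nearly all of it, and each additional
~0.1%-divergent haplotype adds only a few kilobytes of parse descriptions.
`getctg` extracted an 80-base window (samtools-style 1-based inclusive
coordinates) by decompressing only the frames covering that window.
Ranges, samples (`getset`), the whole collection (`getcol`) and listings
(`listset`, `listctg`, `info`) all work the same way; `--adaptive` on
`create`/`append` enables the divergent-collection mode.

The same functionality is available as a library:

```python
from genarc import ArchiveBuilder, ArchiveReader, build_archive, load_genome

build_archive("pan.gar", load_genome("ref.fa"), [load_genome("s1.fa")])
with ArchiveReader("pan.gar") as reader:
    window = reader.get_contig("s1", "ctg1", 1000, 1080)
```

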