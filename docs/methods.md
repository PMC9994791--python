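# Methods

## Model of the data

`genarc` assumes a collection of assemblies of one species: every genome is
a set of contigs that are, outside of a sparse set of variants and
rearrangements, long exact copies of a reference genome.  The design bets
that k-mers unique in the reference act as reliable anchors in every other
genome of the species: a 31-mer that occurs once in the reference will, with
high probability, occur once and in the homologous place in each other
haplotype.  Segments cut at the same pair of anchors are therefore
near-copies of each other, which is what makes per-group reference-based
parsing effective.  The scheme degrades gracefully when the bet fails: a
missing anchor triggers a cost-optimal two-way split, anchors absent
entirely leave one- or zero-splitter segments that fall back to
cost-scored group joining or hashed buckets.

## Parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| `k` | 31 | bases | splitter k-mer length; odd, 11–32 so a canonical form fits 2 bits/base in 64 bits and no k-mer is its own reverse complement |
| `segment_size` | 60 000 | bases | target anchor spacing; smaller values suit small (e.g. bacterial) genomes — 1500 is a sensible choice there |
| `block_size` | 50 | segments | descriptions per zstd frame; larger blocks compress better but cost more per random access (500 for small genomes) |
| `adaptive` | off | — | extend splitters from each sample's unmatched contigs |
| `min_match` | 20 | bases | minimum LZSS match; short enough to thread between nearby SNPs, long enough that chance 16-mer seeds rarely extend to spurious matches |
| `mmer` | 16 | bases | match-finder seed length; 16 symbols × 4-bit IUPAC codes fill a 64-bit key exactly |
| `zstd_level` | 19 | — | all frames; the design favours ratio over write speed |
| `spt1_join_threshold` | 0.5 | — | a one-splitter segment joins a group only if its parse costs less than half of storing it raw (packed payload plus 32 bytes of frame/directory overhead a new group would cost) |

## Alphabet and orientation

Sequences are upper-cased on ingestion and restricted to the 16 IUPAC
nucleotide codes; case is the only information deliberately not preserved.
The complement table pairs A–T, C–G, R–Y, K–M, B–V, D–H and fixes S, W, N.
U is kept self-complementary rather than mapped to A: with U→A the table
is 2-to-1 (T and U collide), reverse complementing twice would turn U into
T, and any segment stored in flipped orientation would silently lose U on
extraction.  An involutory table is a precondition for losslessness, and
archives exercise it constantly because group identity is strand-free.
Only A/C/G/T windows participate in k-mer canonicalization; windows
containing any other symbol are skipped when counting candidates, so
splitters are always pure-ACGT k-mers.

Zero-splitter segments are strand-canonicalized (the lexicographically
smaller of the sequence and its reverse complement) before hashing, so a
contig and its reverse complement land in the same bucket; the bucket hash
is blake2b with an 8-byte digest, modulo 16, pinned in the archive header.
Two-splitter segments whose two terminating splitters have the same
canonical form break the orientation tie by the smaller whole sequence.

## LZSS codec and the division point

Parsing is greedy: at each position the longest reference match seeded by a
16-mer hit is taken if it reaches `min_match`, else one literal.  Ties go
to the leftmost reference occurrence.  Serialization is flag-coded —
literal runs as `0x00` + varint length + raw symbols, matches as `0x01` +
4-byte little-endian offset + varint(length − min_match), `0xFF` as the
terminator.  The fixed-width offset is deliberate: it makes the serialized
cost of a match independent of the offset value, and therefore the cost of
the greedy parse of every prefix of a segment computable from one full
parse (a truncated match keeps its cost shape) and the cost of every
suffix computable by a right-to-left recurrence over the
longest-match-length array (greedy parsing of a suffix is its head token
plus the greedy parse of the rest, with literal-run merging accounted
exactly).  The division point of a missing-splitter segment — argmin over
i of prefix-cost(i) against one flanking group plus suffix-cost(i) against
the other, smallest i on ties — is then *exactly* the point exhaustive
re-parsing of every split would choose, at linear rather than quadratic
cost.  When a flanking group stores its members in the opposite
orientation, the corresponding cost array is computed on the reverse
complement of the segment and read reversed, which keeps the search exact
in all four orientation combinations.  The search range is clamped so the
contig-first piece always covers the k bases it overlaps with its
predecessor.

Variable-length integers are LEB128; archives record every codec parameter
in their header, so readers never depend on compile-time defaults.

## Archive layout and appending

A file is `magic | version | frames… | metadata | footer`.  Frames (group
references, blocks) are addressed by offset from the metadata, which is
itself zstd-compressed and located through a fixed-size footer.  Appending
truncates the old metadata, writes only new frames after the existing data
region, and rewrites metadata and footer; sealed frames are never touched.
A partially filled tail block that receives new members is re-written as a
new frame and its old frame becomes dead space — bounded by one partial
block per touched group per append, a deliberate trade of a few hundred
bytes for strict immutability of everything already written.  Builders are
single-threaded by construction; archive bytes are a pure function of
inputs and parameters, which the test suite asserts by hashing.

Extraction decompresses only the group references and blocks covering the
requested interval.  The reader counts frame decompressions and
decompressed bytes (`frames_touched`, `bytes_decompressed`, cache misses
of a per-reader frame cache), which the tests use to assert that access
cost depends on the query, not on the archive's sample count.

## Adaptive mode

Contigs of an incoming sample that contain no splitter occurrence at all
are buffered.  After the sample's other contigs are placed, canonical
k-mers unique within the buffer, minus every k-mer present in the
reference (any multiplicity, recomputed from the archived reference sample
when appending) and minus already-registered splitters, feed the same
spaced walk used on the reference; the new splitters join the global
registry and the buffer is segmented once more.  There is no recursion: a
contig still splitter-free after its own sample's extension is stored as
spt-0.  Splitter ids are insertion-ordered and persist in the header, so
append continues the id sequence without the original FASTA.

## Synthetic collections

The generator emulates a haplotype panel: a uniform random ACGT reference;
per sample, SNPs (binomial, default 10⁻³/base), short indels (10⁻⁴/base,
geometric lengths, mean 3), kilobase-scale inversions (2×10⁻⁶/base) and
translocations (10⁻⁶/base), fragmentation at up to 3 uniform breakpoints,
then lower-case runs (~5% of bases), N runs and stray IUPAC symbols.  One
RNG stream per spec, consumed in that pinned order, makes output a pure
function of the spec.  A truth table (event counts and positions) is
emitted alongside.  The two-clade variant mutates the reference wholesale
(default 30% SNPs) to make a second clade whose 31-mers are almost
entirely absent from the first, with only the clade-A reference given to
the compressor — the scenario adaptive mode addresses.

Two properties of real assemblies are deliberately *not* emulated.
Mutations are independent across samples, so no two haplotypes share a
variant; real panels share most variation, which makes their group members
near-identical and is precisely what blocked compression exploits.
Passing tests therefore demonstrate correctness, locality and the
direction of the block-size trade-off, but understate the magnitude of the
block-size benefit on real data: measured here, per-sample growth at block
size 50 is about half of the growth at block size 1, not the several-fold
gap seen on real haplotype panels.  Second, there is no sequencing error
or mis-assembly; segments either match well or not at all.

## Problem sizes

The test suite exercises a 1 Mb reference with 10 samples across the full
parameter grid k ∈ {17, 31} × segment_size ∈ {1500, 10⁴, 6×10⁴} ×
block_size ∈ {1, 50, 500}, locality on 300 kb × {5, 50} samples, marginal
growth on 500 kb × 20 samples, the adaptive comparison on a 500 kb
two-clade panel of 20 samples, and 10⁴ randomized codec round trips; the
acceptance script uses the same scales.  These sizes keep a full run in a
few minutes while giving every code path (division points, bucket groups,
tail-block reopening, IUPAC decoration) realistic traffic.

## Known limitations

* Archives are not interchange-compatible with other tools' formats; the
  token layout and metadata are this package's own.
* Case information is dropped (inputs are upper-cased), as is any FASTA
  header text beyond the first whitespace-delimited token.
* The spt-1 join rule scores candidate groups by full parses against each
  group reference; for splitters contained in very many groups this is the
  slowest placement path.
* Appending leaves dead tail-block frames behind; there is no compaction
  command.
* One writer at a time; no concurrent access control.
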