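"""Shared containers: archive parameters and in-memory genomes."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Params:
    """Tunable archive parameters.

    k: splitter k-mer length (odd, 11..32; default 31).
    segment_size: target spacing of splitters in bases (default 60000).
    block_size: segment descriptions per compressed block (default 50).
    adaptive: extend the splitter set from each added sample's unmatched
        contigs (for divergent collections such as bacteria, where a larger
        block size, e.g. 500, and a shorter segment size, e.g. 1500, also
        pay off).
    min_match / mmer: LZSS minimum match length and match-finder seed
        length (see :mod:`genarc.lzss`).
    zstd_level: compression level for all archive frames.
    """

    k: int = 31
    segment_size: int = 60000
    block_size: int = 50
    adaptive: bool = False
    min_match: int = 20
    mmer: int = 16
    zstd_level: int = 19
    spt1_join_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (11 <= self.k <= 32) or self.k % 2 == 0:
            raise ValueError("k must be odd and in [11, 32]")
        if self.segment_size <= self.k:
            raise ValueError("segment_size must exceed k")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.mmer > 16:
            raise ValueError("mmer must be <= 16")
        if self.min_match < self.mmer:
            raise ValueError("min_match must be >= mmer")


@dataclass
class Genome:
    """A named sample: an ordered list of (contig name, sequence) pairs."""

    name: str
    contigs: list[tuple[str, bytes]] = field(default_factory=list)

    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def contig_names(self) -> list[str]:
        return [name for name, _ in self.contigs]
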