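"""Synthetic pangenome collections with controlled divergence.

Emulates a collection of highly similar haplotype assemblies: a uniform
random reference plus per-sample mutated copies (SNPs, short indels, block
inversions, translocations), fragmented into contigs at random
breakpoints, optionally decorated with lower-case runs, N runs and stray
IUPAC symbols.  Generation is a pure function of the :class:`SimSpec`: a
single RNG stream seeded from ``spec.seed`` is consumed in a pinned event
order (reference, then per sample: SNPs -> indels -> inversions ->
translocations -> fragmentation -> casing/N/IUPAC decoration), so the same
spec always yields byte-identical output.  A truth table of applied events
accompanies the collection.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .model import Genome

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP[_a] = _b
_IUPAC_EXTRA = np.frombuffer(b"RYSWKMBDHVU", dtype=np.uint8)


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic collection.

    Rates are per base; ``indel_mean_len`` parameterizes a geometric
    length distribution.  Defaults describe a 1 Mb reference with 10
    haplotypes at 0.1% SNP divergence plus sparse indels, a couple of
    kilobase-scale inversions and about one translocation per genome,
    moderate contig fragmentation, and light lower-case / N / IUPAC
    decoration.
    """

    seed: int = 0
    ref_len: int = 1_000_000
    n_samples: int = 10
    snp_rate: float = 0.001
    indel_rate: float = 1e-4
    indel_mean_len: float = 3.0
    inversion_rate: float = 2e-6
    inversion_len: int = 1000
    translocation_rate: float = 1e-6
    translocation_len: int = 1000
    max_breakpoints: int = 3
    lowercase_fraction: float = 0.05
    lowercase_run_len: int = 500
    n_run_rate: float = 2e-6
    n_run_len: int = 100
    iupac_rate: float = 1e-5
    n_ref_contigs: int = 1

    def __post_init__(self) -> None:
        for name in (
            "snp_rate",
            "indel_rate",
            "inversion_rate",
            "translocation_rate",
            "lowercase_fraction",
            "n_run_rate",
            "iupac_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.ref_len <= 0 or self.n_samples < 0:
            raise ValueError("ref_len must be positive and n_samples >= 0")
        if self.indel_mean_len < 1 or self.indel_mean_len >= self.ref_len:
            raise ValueError("indel_mean_len must be in [1, ref_len)")
        if not 1 <= self.n_ref_contigs <= self.ref_len:
            raise ValueError("n_ref_contigs out of range")
        if self.inversion_len >= self.ref_len or self.translocation_len >= self.ref_len:
            raise ValueError("event block length must be below ref_len")


def _random_reference(rng: np.random.Generator, length: int) -> np.ndarray:
    return _ACGT[rng.integers(0, 4, length)]


def _apply_snps(rng, arr: np.ndarray, rate: float, events: dict) -> np.ndarray:
    count = int(rng.binomial(len(arr), rate)) if rate > 0 else 0
    if count:
        pos = np.sort(rng.choice(len(arr), size=count, replace=False))
        base_idx = np.searchsorted(_ACGT, arr[pos])  # arr is ACGT here
        shift = rng.integers(1, 4, count)
        arr = arr.copy()
        arr[pos] = _ACGT[(base_idx + shift) % 4]
        events["snp_positions"] = pos.tolist()
    events["snps"] = count
    return arr


def _apply_indels(rng, arr: np.ndarray, spec: SimSpec, events: dict) -> np.ndarray:
    count = int(rng.binomial(len(arr), spec.indel_rate)) if spec.indel_rate > 0 else 0
    events["indels"] = count
    if not count:
        return arr
    pos = np.sort(rng.choice(len(arr), size=count, replace=False))
    lens = rng.geometric(1.0 / spec.indel_mean_len, count)
    is_ins = rng.random(count) < 0.5
    parts = []
    prev = 0
    recorded = []
    for p, ln, ins in zip(pos, lens, is_ins):
        p, ln = int(p), int(ln)
        if p < prev:
            continue  # swallowed by a previous deletion
        parts.append(arr[prev:p])
        if ins:
            parts.append(_ACGT[rng.integers(0, 4, ln)])
            prev = p
        else:
            prev = min(p + ln, len(arr))
        recorded.append({"pos": p, "len": ln, "type": "ins" if ins else "del"})
    parts.append(arr[prev:])
    events["indel_events"] = recorded
    return np.concatenate(parts)


def _apply_inversions(rng, arr: np.ndarray, spec: SimSpec, events: dict) -> np.ndarray:
    lam = len(arr) * spec.inversion_rate
    count = int(rng.poisson(lam)) if lam > 0 else 0
    events["inversions"] = count
    recorded = []
    if count:
        arr = arr.copy()
        for _ in range(count):
            length = min(spec.inversion_len, len(arr) - 1)
            p = int(rng.integers(0, len(arr) - length))
            arr[p : p + length] = _COMP[arr[p : p + length]][::-1]
            recorded.append({"pos": p, "len": length})
    events["inversion_events"] = recorded
    return arr


def _apply_translocations(rng, arr: np.ndarray, spec: SimSpec, events: dict) -> np.ndarray:
    lam = len(arr) * spec.translocation_rate
    count = int(rng.poisson(lam)) if lam > 0 else 0
    events["translocations"] = count
    recorded = []
    for _ in range(count):
        length = min(spec.translocation_len, len(arr) - 1)
        src = int(rng.integers(0, len(arr) - length))
        block = arr[src : src + length].copy()
        rest = np.concatenate([arr[:src], arr[src + length :]])
        dst = int(rng.integers(0, len(rest) + 1))
        arr = np.concatenate([rest[:dst], block, rest[dst:]])
        recorded.append({"src": src, "dst": dst, "len": length})
    events["translocation_events"] = recorded
    return arr


def _fragment(rng, arr: np.ndarray, spec: SimSpec, events: dict) -> list[np.ndarray]:
    nb = int(rng.integers(0, spec.max_breakpoints + 1))
    if nb and len(arr) > 1:
        bps = np.unique(rng.integers(1, len(arr), nb))
    else:
        bps = np.zeros(0, dtype=np.int64)
    events["breakpoints"] = bps.tolist()
    return np.split(arr, bps)


def _decorate(rng, pieces: list[np.ndarray], spec: SimSpec, events: dict) -> list[np.ndarray]:
    """N runs, stray IUPAC symbols, then lower-case runs (lossy on case only)."""
    out = []
    n_runs = 0
    iupac = 0
    lc_runs = 0
    for arr in pieces:
        arr = arr.copy()
        length = len(arr)
        if length == 0:
            out.append(arr)
            continue
        lam = length * spec.n_run_rate
        for _ in range(int(rng.poisson(lam)) if lam > 0 else 0):
            p = int(rng.integers(0, length))
            arr[p : p + spec.n_run_len] = ord("N")
            n_runs += 1
        if spec.iupac_rate > 0:
            count = int(rng.binomial(length, spec.iupac_rate))
            if count:
                pos = rng.choice(length, size=count, replace=False)
                arr[pos] = _IUPAC_EXTRA[rng.integers(0, len(_IUPAC_EXTRA), count)]
                iupac += count
        if spec.lowercase_fraction > 0:
            runs = int(spec.lowercase_fraction * length / spec.lowercase_run_len)
            if runs:
                # runs may overlap; build a mask so no base is lowered twice
                mask = np.zeros(length, dtype=bool)
                for _ in range(runs):
                    p = int(rng.integers(0, length))
                    mask[p : p + spec.lowercase_run_len] = True
                    lc_runs += 1
                arr[mask] += 32  # ASCII lower-case
        out.append(arr)
    events["n_runs"] = n_runs
    events["iupac_symbols"] = iupac
    events["lowercase_runs"] = lc_runs
    return out


def _mutate_sample(
    rng: np.random.Generator, ref: np.ndarray, spec: SimSpec, name: str
) -> tuple[Genome, dict]:
    events: dict = {"name": name}
    arr = _apply_snps(rng, ref, spec.snp_rate, events)
    arr = _apply_indels(rng, arr, spec, events)
    arr = _apply_inversions(rng, arr, spec, events)
    arr = _apply_translocations(rng, arr, spec, events)
    pieces = _fragment(rng, arr, spec, events)
    pieces = _decorate(rng, pieces, spec, events)
    contigs = [
        (f"{name}_ctg{i:03d}", piece.tobytes()) for i, piece in enumerate(pieces, 1)
    ]
    return Genome(name, contigs), events


def _split_reference(ref: np.ndarray, spec: SimSpec, name: str) -> Genome:
    pieces = np.array_split(ref, spec.n_ref_contigs)
    return Genome(
        name, [(f"chr{i:02d}", p.tobytes()) for i, p in enumerate(pieces, 1)]
    )


def simulate_collection(spec: SimSpec) -> tuple[Genome, list[Genome], dict]:
    """Reference, mutated samples and the truth table of applied events."""
    rng = np.random.default_rng(spec.seed)
    ref = _random_reference(rng, spec.ref_len)
    reference = _split_reference(ref, spec, "reference")
    samples = []
    truth: dict = {"spec": asdict(spec), "samples": []}
    for i in range(1, spec.n_samples + 1):
        genome, events = _mutate_sample(rng, ref, spec, f"sample{i:02d}")
        samples.append(genome)
        truth["samples"].append(events)
    return reference, samples, truth


def two_clade_collection(
    spec: SimSpec, divergence_between: float
) -> tuple[Genome, list[Genome], dict]:
    """Two clades at the given mutual SNP divergence; half the samples each.

    Only the clade-A reference is returned as the archive reference, which
    leaves clade B entirely outside the splitter universe when the
    divergence is high — the scenario adaptive mode exists for.  A
    divergence of 0 degenerates to :func:`simulate_collection`.
    """
    if not 0.0 <= divergence_between <= 1.0:
        raise ValueError("divergence_between must be in [0, 1]")
    if divergence_between == 0.0:
        return simulate_collection(spec)
    rng = np.random.default_rng(spec.seed)
    ref_a = _random_reference(rng, spec.ref_len)
    clade_events: dict = {}
    ref_b = _apply_snps(rng, ref_a, divergence_between, clade_events)
    reference = _split_reference(ref_a, spec, "reference")
    n_a = spec.n_samples // 2
    samples = []
    truth: dict = {
        "spec": asdict(spec),
        "divergence_between": divergence_between,
        "clade_b_snps": clade_events["snps"],
        "samples": [],
    }
    for i in range(1, spec.n_samples + 1):
        base = ref_a if i <= n_a else ref_b
        clade = "A" if i <= n_a else "B"
        genome, events = _mutate_sample(rng, base, spec, f"sample{i:02d}")
        events["clade"] = clade
        samples.append(genome)
        truth["samples"].append(events)
    return reference, samples, truth
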