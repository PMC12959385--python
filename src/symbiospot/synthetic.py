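"""Synthetic inputs for the spatial phylotyper and the rate model.

Emulates (a) FFPE 16S spatial capture on a barcoded chip: a spot lattice,
read 1 carrying a 25-base coordinate barcode (CID) and a 10-base molecular
barcode (MID), read 2 carrying 75-base fragments of one of two reference
sequences that differ at exactly one base, with i.i.d. substitution
errors; and (b) scintillation-counter measurements of ¹⁴C tracer uptake
with Poisson counting noise and killed controls.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from symbiospot.rates import IncubationRecord

__all__ = [
    "ReferencePair",
    "FieldConfig",
    "TruthTable",
    "ReadSimConfig",
    "IncubationSimConfig",
    "SimulatedReads",
    "make_reference_pair",
    "simulate_field",
    "simulate_reads",
    "simulate_incubation",
    "load_references",
]

_BASES = np.array(list("ACGT"))

#: Default mock-reference length, full-16S scale.
DEFAULT_REFERENCE_LENGTH = 1500
#: Default kept window on the reference (1-based inclusive), 47 nt.
DEFAULT_WINDOW = (907, 953)
#: Default diagnostic position, the window midpoint.
DEFAULT_DIAGNOSTIC_POS = 930

WINDOW_LENGTH = 47


@dataclass(frozen=True)
class ReferencePair:
    """Two mock 16S references differing at exactly one base.

    ``seq_a`` carries the A allele and ``seq_g`` the G allele at
    ``diagnostic_pos`` (1-based); ``window`` is the 47-nt region (1-based
    inclusive) used for classification, containing the diagnostic base.
    """

    seq_a: str
    seq_g: str
    diagnostic_pos: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_g):
            raise ValueError("references must have equal length")
        diffs = [i for i, (a, g) in enumerate(zip(self.seq_a, self.seq_g)) if a != g]
        if diffs != [self.diagnostic_pos - 1]:
            raise ValueError("references must differ exactly at diagnostic_pos")
        start, end = self.window
        if end - start + 1 != WINDOW_LENGTH:
            raise ValueError(f"window must have length {WINDOW_LENGTH}")
        if not (start <= self.diagnostic_pos <= end):
            raise ValueError("diagnostic_pos must lie inside the window")
        if self.seq_a[self.diagnostic_pos - 1] != "A":
            raise ValueError("seq_a must carry base A at diagnostic_pos")
        if self.seq_g[self.diagnostic_pos - 1] != "G":
            raise ValueError("seq_g must carry base G at diagnostic_pos")

    @property
    def window_a(self) -> str:
        """The 47-nt classification window of phylotype A."""
        s, e = self.window
        return self.seq_a[s - 1 : e]

    @property
    def window_g(self) -> str:
        s, e = self.window
        return self.seq_g[s - 1 : e]

    def to_fasta(self, path) -> None:
        """Write both references; window and diagnostic position go in the
        record descriptions so the pair round-trips."""
        meta = f"diagnostic_pos={self.diagnostic_pos} window={self.window[0]}-{self.window[1]}"
        records = [
            SeqRecord(Seq(self.seq_a), id="phylotype_A", description=meta),
            SeqRecord(Seq(self.seq_g), id="phylotype_G", description=meta),
        ]
        SeqIO.write(records, path, "fasta")


def load_references(path) -> ReferencePair:
    """Read a reference pair written by :meth:`ReferencePair.to_fasta`."""
    recs = {r.id: r for r in SeqIO.parse(path, "fasta")}
    try:
        rec_a, rec_g = recs["phylotype_A"], recs["phylotype_G"]
    except KeyError as exc:
        raise ValueError("FASTA must contain phylotype_A and phylotype_G") from exc
    fields = dict(tok.split("=") for tok in rec_a.description.split()[1:] if "=" in tok)
    diag = int(fields["diagnostic_pos"])
    start, end = (int(v) for v in fields["window"].split("-"))
    return ReferencePair(str(rec_a.seq), str(rec_g.seq), diag, (start, end))


def make_reference_pair(
    seed: int,
    diagnostic_pos: int = DEFAULT_DIAGNOSTIC_POS,
    window: tuple[int, int] = DEFAULT_WINDOW,
    length: int = DEFAULT_REFERENCE_LENGTH,
) -> ReferencePair:
    """Generate a random reference pair with one diagnostic base.

    The sequence is uniform random over ACGT except at ``diagnostic_pos``,
    where phylotype A carries A and phylotype G carries G. Deterministic
    for a fixed seed.
    """
    start, end = window
    if end - start + 1 != WINDOW_LENGTH:
        raise ValueError(f"window must have length {WINDOW_LENGTH}")
    if not (start <= diagnostic_pos <= end):
        raise ValueError("diagnostic_pos must lie inside the window")
    if end > length:
        raise ValueError("window exceeds reference length")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    seq_a = seq.copy()
    seq_a[diagnostic_pos - 1] = "A"
    seq_g = seq.copy()
    seq_g[diagnostic_pos - 1] = "G"
    return ReferencePair("".join(seq_a), "".join(seq_g), diagnostic_pos, window)


# ---------------------------------------------------------------------------
# planted phylotype fields


@dataclass
class FieldConfig:
    """Spatial layout of the planted per-spot phylotype-A fraction.

    ``domain-mosaic`` partitions the tissue into ``n_domains`` contiguous
    stripes of alternating pure phylotype (fraction 0 or 1), emulating
    spatially segregated symbiont pouches; ``well-mixed`` draws each
    spot's A fraction from Beta(mixing_beta, mixing_beta), which
    concentrates near 0.5 for large ``mixing_beta``.
    """

    grid_width: int
    grid_height: int
    field_model: str = "domain-mosaic"
    n_domains: int = 2
    mixing_beta: float = 1000.0
    tissue_mask: Optional[set[tuple[int, int]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_width < 20 or self.grid_height < 20:
            raise ValueError("grid dimensions must be >= 20")
        if self.field_model not in ("domain-mosaic", "well-mixed"):
            raise ValueError(f"unknown field_model {self.field_model!r}")
        if self.mixing_beta <= 0:
            raise ValueError("mixing_beta must be > 0")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")

    def spots(self) -> list[tuple[int, int]]:
        if self.tissue_mask is not None:
            return sorted(self.tissue_mask)
        return [(x, y) for y in range(self.grid_height) for x in range(self.grid_width)]


@dataclass
class TruthTable:
    """Planted per-spot true fraction of phylotype A, indexed by (x, y)."""

    frac_a: dict[tuple[int, int], float]

    def __getitem__(self, spot: tuple[int, int]) -> float:
        return self.frac_a[spot]

    def __len__(self) -> int:
        return len(self.frac_a)

    def spots(self) -> list[tuple[int, int]]:
        return sorted(self.frac_a)

    def to_frame(self) -> pd.DataFrame:
        rows = [(x, y, f) for (x, y), f in sorted(self.frac_a.items())]
        return pd.DataFrame(rows, columns=["x", "y", "frac_a"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        return cls({(int(r.x), int(r.y)): float(r.frac_a)
                    for r in df.itertuples(index=False)})


def simulate_field(config: FieldConfig) -> TruthTable:
    """Plant a per-spot phylotype-A fraction field on the tissue.

    Domain-mosaic stripes run along the longer grid axis with
    randomly jittered boundaries; stripe ``i`` is pure phylotype A when
    ``i`` is even, pure G when odd, so adjacent domains always differ and
    the field has exactly ``n_domains`` contiguous single-phylotype
    regions.
    """
    spots = config.spots()
    if not spots:
        raise ValueError("tissue_mask is empty")
    rng = np.random.default_rng(config.seed)
    frac: dict[tuple[int, int], float] = {}
    if config.field_model == "well-mixed":
        draws = rng.beta(config.mixing_beta, config.mixing_beta, size=len(spots))
        frac = {s: float(p) for s, p in zip(spots, draws)}
        return TruthTable(frac)

    # domain-mosaic: jittered stripe boundaries along the wider axis
    axis = 0 if config.grid_width >= config.grid_height else 1
    extent = config.grid_width if axis == 0 else config.grid_height
    n = config.n_domains
    if n == 1:
        bounds = np.array([extent], dtype=float)
    else:
        base = np.linspace(extent / n, extent * (n - 1) / n, n - 1)
        jitter = rng.uniform(-0.25, 0.25, size=n - 1) * (extent / n)
        bounds = np.append(np.sort(base + jitter), extent)
    for s in spots:
        coord = s[axis]
        domain = int(np.searchsorted(bounds, coord, side="right"))
        frac[s] = 1.0 if domain % 2 == 0 else 0.0
    return TruthTable(frac)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadSimConfig:
    """Read-generation parameters for the spatial capture simulator."""

    mean_reads_per_spot: float = 10.0
    read2_length: int = 75
    error_rate: float = 0.0
    cid_length: int = 25
    mid_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read2_length < WINDOW_LENGTH:
            raise ValueError(f"read2_length must be >= {WINDOW_LENGTH}")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.mean_reads_per_spot < 0:
            raise ValueError("mean_reads_per_spot must be >= 0")


@dataclass
class SimulatedReads:
    """Paired reads plus the barcode mask and per-read ground truth.

    ``true_allele`` records which reference each read 2 was drawn from
    ('A' or 'G'), before sequencing errors — the oracle for classifier
    tests.  ``read_starts`` holds the 0-based fragment start on the
    reference.
    """

    names: list[str]
    read1: list[str]
    read2: list[str]
    spots: list[tuple[int, int]]
    true_allele: list[str]
    read_starts: list[int]
    mask: dict[str, tuple[int, int]]  # CID -> (x, y)
    reads_per_spot: dict[tuple[int, int], int]

    def __len__(self) -> int:
        return len(self.names)

    def write_fastq(self, r1_path, r2_path) -> None:
        """Write the pairs as two FASTQ files (uniform quality)."""
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for name, r1, r2 in zip(self.names, self.read1, self.read2):
                f1.write(f"@{name}\n{r1}\n+\n{'I' * len(r1)}\n")
                f2.write(f"@{name}\n{r2}\n+\n{'I' * len(r2)}\n")

    def write_mask(self, path) -> None:
        rows = sorted(self.mask.items(), key=lambda kv: kv[1])
        pd.DataFrame(
            [(cid, x, y) for cid, (x, y) in rows], columns=["cid", "x", "y"]
        ).to_csv(path, sep="\t", index=False)


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        for row in _decode(rng.integers(0, 4, size=(n - len(out), length))):
            if row not in seen:
                seen.add(row)
                out.append(row)
    return out


def _decode(codes: np.ndarray) -> list[str]:
    """Row-wise 0..3 integer codes -> ACGT strings."""
    chars = _BASES[codes]
    return ["".join(row) for row in chars]


def simulate_reads(
    truth: TruthTable, refs: ReferencePair, config: ReadSimConfig
) -> SimulatedReads:
    """Generate paired reads over the planted field.

    Per spot, the read count is Poisson(mean_reads_per_spot); each read 2
    is a ``read2_length`` fragment of seq_A or seq_G (Bernoulli on the
    spot's planted A fraction) starting uniformly over valid positions,
    with i.i.d. substitution errors.  Read 1 is the spot's CID followed
    by a random MID.  Fragments that miss the classification window are
    emitted regardless — rejecting them is the classifier's job.
    """
    ref_len = len(refs.seq_a)
    if config.read2_length > ref_len:
        raise ValueError("read2_length exceeds reference length")
    rng = np.random.default_rng(config.seed)
    spots = truth.spots()
    cids = _random_barcodes(rng, len(spots), config.cid_length)
    mask = dict(zip(cids, spots))
    code_of = {b: i for i, b in enumerate("ACGT")}
    arr_a = np.array([code_of[b] for b in refs.seq_a], dtype=np.int8)
    arr_g = np.array([code_of[b] for b in refs.seq_g], dtype=np.int8)
    n_max_start = ref_len - config.read2_length + 1

    counts = rng.poisson(config.mean_reads_per_spot, size=len(spots))
    n_total = int(counts.sum())
    spot_idx = np.repeat(np.arange(len(spots)), counts)
    p_a = np.array([truth[s] for s in spots])[spot_idx]
    is_a = rng.random(n_total) < p_a
    starts = rng.integers(0, n_max_start, size=n_total)

    # fragment matrix of base codes, then i.i.d. substitutions: adding
    # 1..3 mod 4 yields a uniform draw over the three other bases
    pos = starts[:, None] + np.arange(config.read2_length)[None, :]
    frags = np.where(is_a[:, None], arr_a[pos], arr_g[pos])
    if config.error_rate > 0:
        hit = rng.random(frags.shape) < config.error_rate
        shift = rng.integers(1, 4, size=frags.shape)
        frags = np.where(hit, (frags + shift) % 4, frags)
    mids = _decode(rng.integers(0, 4, size=(n_total, config.mid_length)))

    r2s = _decode(frags)
    cid_per_read = [cids[i] for i in spot_idx]
    return SimulatedReads(
        names=[f"read_{i}" for i in range(n_total)],
        read1=[c + m for c, m in zip(cid_per_read, mids)],
        read2=r2s,
        spots=[spots[i] for i in spot_idx],
        true_allele=["A" if a else "G" for a in is_a],
        read_starts=[int(s) for s in starts],
        mask=mask,
        reads_per_spot={s: int(c) for s, c in zip(spots, counts)},
    )


# ---------------------------------------------------------------------------
# incubation simulation


@dataclass
class IncubationSimConfig:
    """Forward model of a radiotracer incubation.

    Expected filter DPM is ``dpm_dic_total × (1 − exp(−true_k × t)) +
    control_background_dpm``; with ``counting_noise='poisson'`` the
    observed DPM is a Poisson draw around that expectation, emulating
    scintillation counting statistics.  Killed controls retain only the
    background (true_k = 0).
    """

    true_k: float = 7.4e-4
    dpm_dic_total: float = 3.7e4
    t_days: float = 1.0
    dic_mmol_per_l: float = 2.64
    volume_l: float = 0.015
    control_background_dpm: float = 0.0
    counting_noise: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_k < 0:
            raise ValueError("true_k must be >= 0")
        if self.dpm_dic_total <= 0:
            raise ValueError("dpm_dic_total must be > 0")
        if self.t_days <= 0:
            raise ValueError("t_days must be > 0")
        if self.counting_noise not in ("none", "poisson"):
            raise ValueError("counting_noise must be 'none' or 'poisson'")


def simulate_incubation(
    config: IncubationSimConfig, n_replicates: int
) -> list[IncubationRecord]:
    """Simulate replicate incubations with matched killed controls.

    Each record's ``dpm_poc`` is the (noisy) filter DPM and
    ``control_dpm`` an independent killed-control draw with the same
    background.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(config.seed)
    expected = config.dpm_dic_total * -np.expm1(-config.true_k * config.t_days)
    records = []
    for i in range(n_replicates):
        signal = expected + config.control_background_dpm
        control = config.control_background_dpm
        if config.counting_noise == "poisson":
            signal = float(rng.poisson(signal)) if signal > 0 else 0.0
            control = float(rng.poisson(control)) if control > 0 else 0.0
        records.append(IncubationRecord(
            dpm_poc=float(signal),
            dpm_dic=config.dpm_dic_total,
            t_days=config.t_days,
            dic_mmol_per_l=config.dic_mmol_per_l,
            volume_l=config.volume_l,
            control_dpm=float(control),
            label=f"sim_{i}",
        ))
    return records


def write_incubations(records: list[IncubationRecord], path) -> None:
    """Write incubation records as a tab-delimited table."""
    pd.DataFrame([{
        "label": r.label,
        "dpm_poc": r.dpm_poc,
        "dpm_dic": r.dpm_dic,
        "t_days": r.t_days,
        "dic_mmol_per_l": r.dic_mmol_per_l,
        "volume_l": r.volume_l,
        "norm_factor": r.norm_factor,
        "control_dpm": r.control_dpm,
        "temperature_c": r.temperature_c,
    } for r in records]).to_csv(path, sep="\t", index=False)
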