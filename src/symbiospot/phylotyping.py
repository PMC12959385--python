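"""Single-base spatial phylotyping of two 16S variants.

Reads are assigned to phylotype A or G only when they contain the full
47-nt diagnostic window of one reference with zero mismatches (sequence
mode), or when a pre-computed alignment passes the unique-hit /
MAPQ 255 / 47M filter and carries a diagnostic-position allele
(alignment mode).  Spot counts are aggregated into square bins (default
20 × 20 spots ≈ one host cell), a bin is valid from 180 classified reads,
and a dominant phylotype is called when its read fraction strictly
exceeds 95% — equivalently, when the major:minor count ratio exceeds 19.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from symbiospot.synthetic import ReferencePair

__all__ = [
    "CID_SLICE",
    "MID_SLICE",
    "BarcodeMask",
    "ClassifiedRead",
    "AlignmentFilter",
    "SpotCounts",
    "HeterogeneitySummary",
    "SampleFrequency",
    "load_mask",
    "demux",
    "classify_read",
    "classify_alignment",
    "accumulate",
    "bin_aggregate",
    "call_bins",
    "summarize",
    "sample_frequency",
    "concordance_r2",
]

# Read-1 layout: CID occupies bases 1–25, MID bases 26–35 (1-based).
CID_SLICE = slice(0, 25)
MID_SLICE = slice(25, 35)
_MIN_READ1_LEN = 35

BarcodeMask = dict[str, tuple[int, int]]


def load_mask(path) -> BarcodeMask:
    """Load the coordinate-barcode mask (TSV: cid, x, y).

    Raises
    ------
    ValueError
        On duplicate CIDs or malformed/negative coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cid": str})
    if df["cid"].duplicated().any():
        dup = df.loc[df["cid"].duplicated(), "cid"].iloc[0]
        raise ValueError(f"duplicate CID in mask: {dup}")
    try:
        xs = df["x"].astype(int)
        ys = df["y"].astype(int)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed coordinate in mask: {exc}") from exc
    if (xs < 0).any() or (ys < 0).any():
        raise ValueError("mask coordinates must be non-negative")
    return {c: (int(x), int(y)) for c, x, y in zip(df["cid"], xs, ys)}


def write_mask(mask: BarcodeMask, path) -> None:
    pd.DataFrame(
        [(cid, x, y) for cid, (x, y) in sorted(mask.items(), key=lambda kv: kv[1])],
        columns=["cid", "x", "y"],
    ).to_csv(path, sep="\t", index=False)


def demux(read1: str, mask: BarcodeMask) -> Optional[tuple[tuple[int, int], str]]:
    """Resolve read 1 to its chip spot and molecular barcode.

    Returns ``((x, y), mid)``, or ``None`` when the CID is not in the
    mask (the caller counts the drop).  Read 1 must be at least 35 nt.
    """
    if len(read1) < _MIN_READ1_LEN:
        raise ValueError(f"read 1 shorter than {_MIN_READ1_LEN} nt")
    spot = mask.get(read1[CID_SLICE])
    if spot is None:
        return None
    return spot, read1[MID_SLICE]


def classify_read(read2: str, refs: ReferencePair) -> str:
    """Call a read's phylotype by exact full-window matching.

    The read is 'A' iff it contains the entire 47-nt window of the
    phylotype-A reference with zero mismatches, 'G' for the G window;
    'unclassified' otherwise, including reads that cover only part of
    the window.  The two windows differ at the diagnostic base, so no
    read can match both.
    """
    if refs.window_a in read2:
        return "A"
    if refs.window_g in read2:
        return "G"
    return "unclassified"


@dataclass(frozen=True)
class AlignmentFilter:
    """Conjunctive alignment-acceptance criteria for pre-aligned reads.

    Mirrors the unique-hit (NH:i:1), MAPQ 255, CIGAR 47M extraction used
    with spliced aligners whose MAPQ 255 marks unique mappings.
    """

    require_unique: bool = True
    required_mapq: int = 255
    required_match_length: int = 47


def classify_alignment(
    record,
    filt: AlignmentFilter,
    diagnostic_pos0: int,
    a_allele: str = "A",
    g_allele: str = "G",
) -> str:
    """Call a phylotype from a SAM/BAM alignment record.

    ``record`` is a :class:`pysam.AlignedSegment` (or compatible). The
    record passes only if it is a unique hit (NH tag = 1), its mapping
    quality equals the required value, and its CIGAR is a single
    contiguous match of the required length.  The call is decided by the
    read base aligned over ``diagnostic_pos0`` (0-based reference
    coordinate): A allele → 'A', G allele → 'G', anything else (or the
    position not covered) → 'unclassified'.

    Raises
    ------
    ValueError
        If the record lacks an NH tag, CIGAR, or sequence.
    """
    if record.is_unmapped:
        return "unclassified"
    if filt.require_unique:
        try:
            nh = record.get_tag("NH")
        except KeyError as exc:
            raise ValueError(f"{record.query_name}: missing NH tag") from exc
        if nh != 1:
            return "unclassified"
    if record.mapping_quality != filt.required_mapq:
        return "unclassified"
    cig = record.cigartuples
    if cig is None:
        raise ValueError(f"{record.query_name}: missing CIGAR")
    if cig != [(0, filt.required_match_length)]:
        return "unclassified"
    seq = record.query_sequence
    if seq is None:
        raise ValueError(f"{record.query_name}: missing sequence")
    offset = diagnostic_pos0 - record.reference_start
    if not (0 <= offset < filt.required_match_length):
        return "unclassified"
    base = seq[offset].upper()
    if base == a_allele.upper():
        return "A"
    if base == g_allele.upper():
        return "G"
    return "unclassified"


@dataclass(frozen=True)
class ClassifiedRead:
    """One demultiplexed, classified read."""

    spot: tuple[int, int]
    mid: str
    call: str  # 'A', 'G' or 'unclassified'

    def __post_init__(self) -> None:
        if self.call not in ("A", "G", "unclassified"):
            raise ValueError(f"invalid call {self.call!r}")


@dataclass
class SpotCounts:
    """Per-spot phylotype read tallies."""

    counts: dict[tuple[int, int], Counter] = field(default_factory=dict)

    def add(self, spot: tuple[int, int], call: str, n: int = 1) -> None:
        self.counts.setdefault(spot, Counter())[call] += n

    def total(self, call: Optional[str] = None) -> int:
        if call is None:
            return sum(sum(c.values()) for c in self.counts.values())
        return sum(c[call] for c in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (x, y, c["A"], c["G"], c["unclassified"])
            for (x, y), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["x", "y", "n_A", "n_G", "n_unclassified"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def accumulate(
    classified: Iterable[ClassifiedRead], dedup_mid: bool = False
) -> SpotCounts:
    """Tally classified reads per spot.

    With ``dedup_mid`` each (spot, MID, call) triple counts at most once,
    collapsing molecular duplicates; off by default — raw read counts
    are the spatial signal.
    """
    out = SpotCounts()
    seen: set[tuple[tuple[int, int], str, str]] = set()
    for read in classified:
        if dedup_mid:
            key = (read.spot, read.mid, read.call)
            if key in seen:
                continue
            seen.add(key)
        out.add(read.spot, read.call)
    return out


def bin_aggregate(
    spots: SpotCounts, bin_size: int = 20, min_reads: int = 180
) -> pd.DataFrame:
    """Aggregate spot counts into square bins.

    Bin index is componentwise ``floor(spot / bin_size)``; a bin is
    valid when its classified-read total (n_A + n_G) reaches
    ``min_reads``.  Returns one row per occupied bin with columns
    bx, by, n_A, n_G, total, valid, frac_A, ratio_AG.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    agg: dict[tuple[int, int], Counter] = {}
    for (x, y), c in spots.counts.items():
        b = (x // bin_size, y // bin_size)
        agg.setdefault(b, Counter()).update(c)
    rows = []
    for (bx, by), c in sorted(agg.items()):
        n_a, n_g = c["A"], c["G"]
        total = n_a + n_g
        frac_a = n_a / total if total > 0 else math.nan
        if n_g > 0:
            ratio = n_a / n_g
        else:
            ratio = math.inf if n_a > 0 else math.nan
        rows.append((bx, by, n_a, n_g, total, total >= min_reads, frac_a, ratio))
    return pd.DataFrame(
        rows, columns=["bx", "by", "n_A", "n_G", "total", "valid", "frac_A", "ratio_AG"]
    )


def call_bins(bins: pd.DataFrame, dominance: float = 0.95) -> pd.DataFrame:
    """Call a dominant phylotype per valid bin.

    A valid bin is A-dominant iff frac_A strictly exceeds ``dominance``
    (at the default 0.95 this is exactly n_A > 19·n_G), G-dominant iff
    frac_A < 1 − dominance, 'mixed' otherwise; invalid bins get
    'invalid'.  Returns a copy with a ``call`` column.
    """
    if not (0.5 < dominance < 1.0):
        raise ValueError("dominance must be in (0.5, 1)")
    out = bins.copy()
    calls = []
    for row in out.itertuples(index=False):
        # the G side is compared as n_G/total > dominance (not frac_A <
        # 1 - dominance) so both boundaries are exact in floating point
        if not row.valid:
            calls.append("invalid")
        elif row.frac_A > dominance:
            calls.append("A-dominant")
        elif row.total > 0 and row.n_G / row.total > dominance:
            calls.append("G-dominant")
        else:
            calls.append("mixed")
    out["call"] = calls
    return out


@dataclass
class HeterogeneitySummary:
    """Spatial-heterogeneity statistics over valid bins.

    ``histogram`` counts valid bins over 20 frac_A intervals of width 5%
    ([0,0.05), …, [0.95,1]); ``extreme_fraction`` is the share of valid
    bins in the two outermost intervals; ``single_phylotype_fraction``
    comes in a strict sense (minor count exactly 0) and a dominance
    sense (called A- or G-dominant); ``neighbor_discordance`` is the
    fraction of 4-adjacent valid dominant-called bin pairs whose calls
    disagree (NaN when no such pair exists).
    """

    n_valid_bins: int
    single_phylotype_fraction_strict: float
    single_phylotype_fraction_dominance: float
    histogram: list[int]
    extreme_fraction: float
    neighbor_discordance: float

    def to_dict(self) -> dict:
        return {
            "n_valid_bins": self.n_valid_bins,
            "single_phylotype_fraction_strict": self.single_phylotype_fraction_strict,
            "single_phylotype_fraction_dominance": self.single_phylotype_fraction_dominance,
            "histogram": self.histogram,
            "extreme_fraction": self.extreme_fraction,
            "neighbor_discordance": self.neighbor_discordance,
        }


def summarize(bins: pd.DataFrame) -> HeterogeneitySummary:
    """Compute heterogeneity statistics over the valid, called bins."""
    if "call" not in bins.columns:
        raise ValueError("bins must be called first (call_bins)")
    valid = bins[bins["valid"]]
    n = len(valid)
    if n == 0:
        raise ValueError("no valid bins")
    frac = valid["frac_A"].to_numpy()
    hist, _ = np.histogram(frac, bins=np.linspace(0.0, 1.0, 21))
    strict = float(((valid["n_A"] == 0) | (valid["n_G"] == 0)).mean())
    dominant_mask = valid["call"].isin(["A-dominant", "G-dominant"])
    dominance = float(dominant_mask.mean())
    extreme = float(((frac <= 0.05) | (frac >= 0.95)).mean())

    calls = {
        (int(r.bx), int(r.by)): r.call
        for r in valid[dominant_mask].itertuples(index=False)
    }
    pairs = disagree = 0
    for (bx, by), call in calls.items():
        for nb in ((bx + 1, by), (bx, by + 1)):  # each 4-neighbour pair once
            other = calls.get(nb)
            if other is not None:
                pairs += 1
                disagree += call != other
    discordance = disagree / pairs if pairs else math.nan
    return HeterogeneitySummary(
        n_valid_bins=n,
        single_phylotype_fraction_strict=strict,
        single_phylotype_fraction_dominance=dominance,
        histogram=[int(h) for h in hist],
        extreme_fraction=extreme,
        neighbor_discordance=discordance,
    )


@dataclass(frozen=True)
class SampleFrequency:
    """Sample-level phylotype-G frequency among classified reads."""

    sample: str
    n_a: int
    n_g: int
    frac_g: float


def sample_frequency(n_a: int, n_g: int, sample: str = "") -> SampleFrequency:
    """Phylotype-G read fraction, the per-sample strain-frequency estimate."""
    if n_a + n_g <= 0:
        raise ValueError("no classified reads")
    return SampleFrequency(sample=sample, n_a=n_a, n_g=n_g, frac_g=n_g / (n_a + n_g))


def concordance_r2(pairs: Iterable[tuple[float, float]]) -> float:
    """Squared Pearson correlation between two frequency estimators.

    Used to check that independent estimates of per-sample phylotype
    frequency (e.g. diagnostic-base read counts vs gene-family strain
    decomposition) agree.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
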