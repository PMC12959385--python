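"""Radiotracer DIC-assimilation kinetics and temperature response.

A ¹⁴C-bicarbonate tracer is added to a sealed incubation; the fraction of
the labelled DIC pool recovered on the particulate (POC) filter after time
``t`` gives a first-order turnover rate constant

    k = -ln(1 - DPM_POC / DPM_DIC) / t      [day⁻¹]

which, multiplied by the ambient DIC concentration and the incubation
volume, yields the DIC assimilation rate in nmol C per incubation unit
(one live clam, or one gill-homogenate vial scaled back to a whole clam)
per day.  The temperature response of ``k`` is summarised by ordinary
least-squares polynomial fits with a closed-form interior-maximum
(optimum temperature) for the cubic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NMOL_PER_MMOL",
    "LIVE_CLAM_VOLUME_L",
    "GILL_VIAL_VOLUME_L",
    "GILL_NORM_FACTOR",
    "IncubationRecord",
    "TemperatureResponse",
    "PolyFit",
    "turnover_k",
    "assim_rate",
    "seawater_rate",
    "equivalence_volume",
    "fit_polynomial",
    "peak_temperature",
    "ratio_to_max",
    "read_incubations",
    "write_rates",
]

#: Conversion from mmol (the unit of [DIC] per litre) to nmol, so that
#: rates come out in nmol C·day⁻¹ at incubation-volume scale.
NMOL_PER_MMOL = 1e6

#: Incubation volume of a single live clam (litres).
LIVE_CLAM_VOLUME_L = 0.015
#: Incubation volume of a gill-homogenate serum vial (litres).
GILL_VIAL_VOLUME_L = 0.010
#: One vial holds the gill homogenate of a quarter clam; multiply by 4 to
#: report per-clam rates.
GILL_NORM_FACTOR = 4.0


@dataclass
class IncubationRecord:
    """One radiotracer incubation measurement.

    Parameters
    ----------
    dpm_poc
        Radioactivity retained on the POC filter (disintegrations per
        minute).
    dpm_dic
        Total activity of the added DIC tracer (DPM).
    t_days
        Incubation duration in days.
    dic_mmol_per_l
        Ambient DIC concentration (mmol·L⁻¹).
    volume_l
        Incubation volume in litres (0.015 live clam, 0.010 gill vial).
    norm_factor
        Per-clam normalisation (1 for a live clam, 4 for a quarter-clam
        gill vial); any positive value is accepted.
    control_dpm
        Filter DPM of the matched killed control, if measured.
    label
        Sample identifier used in error messages and output tables.
    temperature_c
        Incubation temperature (°C), when part of a temperature series.
    """

    dpm_poc: float
    dpm_dic: float
    t_days: float
    dic_mmol_per_l: Optional[float] = None
    volume_l: float = LIVE_CLAM_VOLUME_L
    norm_factor: float = 1.0
    control_dpm: Optional[float] = None
    label: str = ""
    temperature_c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dpm_dic <= 0:
            raise ValueError(f"{self.label or 'record'}: dpm_dic must be > 0")
        if self.dpm_poc < 0:
            raise ValueError(f"{self.label or 'record'}: dpm_poc must be >= 0")
        if self.t_days <= 0:
            raise ValueError(f"{self.label or 'record'}: t_days must be > 0")
        if self.volume_l <= 0:
            raise ValueError(f"{self.label or 'record'}: volume_l must be > 0")
        if self.norm_factor <= 0:
            raise ValueError(f"{self.label or 'record'}: norm_factor must be > 0")


def turnover_k(record: IncubationRecord, subtract_control: bool = False) -> float:
    """Turnover rate constant k (day⁻¹) of the DIC pool.

    ``k = -ln(1 - DPM_POC / DPM_DIC) / t``.  When ``subtract_control`` is
    set, the killed-control filter DPM is subtracted from ``dpm_poc``
    first (floored at zero) to remove abiotic tracer adsorption.

    Raises
    ------
    ValueError
        If the (effective) filter DPM reaches the total tracer DPM, where
        the logarithm is undefined.
    """
    dpm_poc = record.dpm_poc
    if subtract_control and record.control_dpm is not None:
        dpm_poc = max(dpm_poc - record.control_dpm, 0.0)
    if dpm_poc >= record.dpm_dic:
        raise ValueError(
            f"{record.label or 'record'}: filter DPM ({dpm_poc:g}) must be "
            f"below total tracer DPM ({record.dpm_dic:g})"
        )
    return -math.log1p(-dpm_poc / record.dpm_dic) / record.t_days


def assim_rate(
    record: IncubationRecord,
    k: Optional[float] = None,
    subtract_control: bool = False,
) -> float:
    """DIC assimilation rate in nmol C·day⁻¹ at per-clam scale.

    ``rate = k × [DIC] × 10⁶ × V × norm_factor`` with [DIC] in mmol·L⁻¹
    and V in litres; 10⁶ converts mmol to nmol.  ``k`` is computed from
    the record unless supplied.
    """
    if record.dic_mmol_per_l is None:
        raise ValueError(f"{record.label or 'record'}: DIC concentration missing")
    if k is None:
        k = turnover_k(record, subtract_control=subtract_control)
    return k * record.dic_mmol_per_l * NMOL_PER_MMOL * record.volume_l * record.norm_factor


def seawater_rate(
    record: IncubationRecord,
    k: Optional[float] = None,
    per_ml: float = 100.0,
    subtract_control: bool = False,
) -> float:
    """DIC assimilation of an organism-free seawater incubation.

    Normalised to ``per_ml`` millilitres of incubation water (default
    100 ml, giving nmol C·100 ml⁻¹·day⁻¹).
    """
    if record.dic_mmol_per_l is None:
        raise ValueError(f"{record.label or 'record'}: DIC concentration missing")
    if record.volume_l <= 0:
        raise ValueError("volume_l must be > 0")
    if k is None:
        k = turnover_k(record, subtract_control=subtract_control)
    return k * record.dic_mmol_per_l * NMOL_PER_MMOL * (per_ml / 1000.0)


def equivalence_volume(clam_rate: float, seawater_rate_100ml: float) -> float:
    """Seawater volume (ml) whose DIC fixation matches one clam.

    ``ml = 100 × clam_rate / seawater_rate`` with the clam rate in
    nmol·clam⁻¹·day⁻¹ and the seawater rate in nmol·100 ml⁻¹·day⁻¹.
    """
    if seawater_rate_100ml <= 0:
        raise ValueError("seawater rate must be > 0")
    return 100.0 * clam_rate / seawater_rate_100ml


@dataclass
class TemperatureResponse:
    """(temperature °C, k day⁻¹) observations, replicate- or mean-level."""

    temperatures: np.ndarray
    k_values: np.ndarray

    def __init__(self, observations: Sequence[tuple[float, float]]):
        obs = np.asarray(list(observations), dtype=float)
        if obs.ndim != 2 or obs.shape[1] != 2:
            raise ValueError("observations must be (temperature, k) pairs")
        self.temperatures = obs[:, 0]
        self.k_values = obs[:, 1]

    @property
    def n_distinct_temperatures(self) -> int:
        return np.unique(self.temperatures).size


@dataclass
class PolyFit:
    """An ordinary least-squares polynomial fit of k against temperature."""

    degree: int
    coefficients: np.ndarray  # ascending order: c0 + c1*T + ...
    r2: float
    adjusted_r2: float
    aicc: float
    residuals: np.ndarray = field(repr=False)

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(t, self.coefficients)


def fit_polynomial(data: TemperatureResponse, degree: int) -> PolyFit:
    """Least-squares polynomial fit of the temperature response.

    Reports R², adjusted R² and the small-sample-corrected Akaike
    information criterion (AICc) for comparing the quadratic and cubic
    models.  Requires more distinct temperatures than the degree.
    """
    if degree not in (2, 3):
        raise ValueError("degree must be 2 or 3")
    if data.n_distinct_temperatures <= degree:
        raise ValueError(
            f"need > {degree} distinct temperatures for a degree-{degree} fit"
        )
    t, y = data.temperatures, data.k_values
    coefs = np.polynomial.polynomial.polyfit(t, y, degree)
    fitted = np.polynomial.polynomial.polyval(t, coefs)
    resid = y - fitted
    n, p = y.size, degree + 1
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if n - p - 1 > 0:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        adj = float("nan")
    # Gaussian log-likelihood AIC with small-sample correction
    if ss_res > 0 and n - p - 1 > 0:
        aic = n * math.log(ss_res / n) + 2 * p
        aicc = aic + 2 * p * (p + 1) / (n - p - 1)
    else:
        aicc = float("-inf")
    return PolyFit(degree=degree, coefficients=coefs, r2=r2,
                   adjusted_r2=adj, aicc=aicc, residuals=resid)


def peak_temperature(fit: PolyFit, t_range: tuple[float, float]) -> float:
    """Interior stationary maximum of a cubic fit, in closed form.

    The derivative of the cubic is a quadratic whose real roots are the
    stationary points; the root with negative second derivative inside
    ``t_range`` is the optimum temperature.

    Raises
    ------
    ValueError
        If the fit is not cubic or no interior maximum exists in range.
    """
    if fit.degree != 3:
        raise ValueError("peak_temperature requires a cubic fit")
    c = fit.coefficients
    # derivative: c1 + 2 c2 T + 3 c3 T²
    d0, d1, d2 = c[1], 2 * c[2], 3 * c[3]
    t_min, t_max = t_range
    if d2 == 0:
        # degenerate cubic: the derivative is linear
        if d1 == 0:
            raise ValueError("no interior maximum in range")
        roots: tuple[float, ...] = (-d0 / d1,)
    else:
        disc = d1 * d1 - 4 * d2 * d0
        if disc < 0:
            raise ValueError("no interior maximum in range")
        # Citardauq-stable form: avoids cancellation when |d2| is tiny
        q = -0.5 * (d1 + math.copysign(math.sqrt(disc), d1))
        roots = (q / d2, d0 / q) if q != 0 else (0.0, 0.0)
    candidates = [
        t for t in roots
        if t_min < t < t_max and (2 * c[2] + 6 * c[3] * t) < 0
    ]
    if not candidates:
        raise ValueError("no interior maximum in range")
    return max(candidates, key=lambda t: float(fit.predict(t)))


def ratio_to_max(data: TemperatureResponse) -> dict[float, int]:
    """Each mean k as an integer percentage of the maximum mean k.

    Observations are averaged per distinct temperature first, so the
    function accepts replicate-level input.
    """
    temps = np.unique(data.temperatures)
    if temps.size < 2:
        raise ValueError("need at least 2 temperatures")
    means = np.array([data.k_values[data.temperatures == t].mean() for t in temps])
    top = means.max()
    if top <= 0:
        raise ValueError("all mean rate constants are zero")
    return {float(t): int(round(100.0 * m / top)) for t, m in zip(temps, means)}


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = [
    "label", "dpm_poc", "dpm_dic", "t_days", "dic_mmol_per_l",
    "volume_l", "norm_factor", "control_dpm", "temperature_c",
]


def read_incubations(path) -> list[IncubationRecord]:
    """Read incubation records from a tab-delimited table with a header."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(IncubationRecord(
            label=str(d.get("label", "")),
            dpm_poc=float(d["dpm_poc"]),
            dpm_dic=float(d["dpm_dic"]),
            t_days=float(d["t_days"]),
            dic_mmol_per_l=_opt(d.get("dic_mmol_per_l")),
            volume_l=float(d.get("volume_l", LIVE_CLAM_VOLUME_L)),
            norm_factor=float(d.get("norm_factor", 1.0)),
            control_dpm=_opt(d.get("control_dpm")),
            temperature_c=_opt(d.get("temperature_c")),
        ))
    return records


def write_rates(records: Sequence[IncubationRecord], ks: Sequence[float],
                rates: Sequence[float], path) -> None:
    """Write per-record k and assimilation rate as a tab-delimited table."""
    pd.DataFrame({
        "label": [r.label for r in records],
        "temperature_c": [r.temperature_c for r in records],
        "k_per_day": ks,
        "assim_nmol_per_day": rates,
    }).to_csv(path, sep="\t", index=False)


def _opt(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)
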