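"""Rayleigh fractionation model and biodegradation diagnostics.

Anaerobic propane oxidisers (the only characterised isolate is the
sulfate-reducing bacterium BuS5) activate propane at the central carbon,
so the central 13C-isotopologue reacts more slowly and the residual pool
enriches at the central position.  With pure-culture fractionation factors
eps_central = 33 permil and eps_terminal = 3 permil, and assuming
unbiodegraded thermogenic propane starts with no central excess
(D13C_central = 0), the central-position excess of a field sample can be
inverted for the fraction of propane remaining f and hence the extent of
biodegradation B = 1 - f.

Residual-substrate Rayleigh convention used throughout:

    delta(f) = (delta0 + 1000) * f**(-eps/1000) - 1000      (eps > 0)

The inversion applies eps_central to the measured offset directly, treating
the terminal position (eps = 3 permil) as a quasi-conservative reference.

The module also carries the correlation diagnostics that sit around the
inversion: ethane/propane co-degradation (concentration-concentration OLS
slope), isotope co-trends, and a qualitative secondary-methanogenesis
indicator (13C-enriched residual CO2, methane d13C falling and methane
fraction rising with biodegradation extent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .records import BDL, Bdl, Measurement, SampleRecord, is_value

__all__ = [
    "RayleighParams",
    "ExtentEstimate",
    "rayleigh_forward",
    "rayleigh_invert",
    "extent_from_offset",
    "extents_for_records",
    "codegradation_slope",
    "isotope_cotrend",
    "secondary_methane_indicator",
    "SecondaryMethaneReport",
    "paired_series",
]

#: isotope label under which the measured central-position excess is stored
OFFSET_LABEL = "delta13c_central"


@dataclass(frozen=True)
class RayleighParams:
    """Fractionation factors (permil, residue-enriching convention) and priors."""

    eps_central: float = 33.0
    eps_terminal: float = 3.0
    delta0_offset: float = 0.0
    convention: str = "residual-substrate"

    def __post_init__(self) -> None:
        if self.eps_central < 0 or self.eps_terminal < 0:
            raise ValueError("eps must be >= 0 (normal isotope effect: residue enriches)")
        if not math.isfinite(self.delta0_offset):
            raise ValueError("delta0_offset must be finite")


@dataclass(frozen=True)
class ExtentEstimate:
    sample_id: str
    fraction_remaining: float
    extent_percent: float
    offset_used: float


def rayleigh_forward(f: float, eps: float, delta0: float) -> float:
    """Residual-substrate delta after a fraction f of the pool remains."""
    if not 0.0 < f <= 1.0:
        raise ValueError(f"fraction remaining must be in (0, 1], got {f}")
    return (delta0 + 1000.0) * f ** (-eps / 1000.0) - 1000.0


def rayleigh_invert(delta: float, eps: float, delta0: float) -> float:
    """Fraction remaining that produces `delta` from `delta0` under eps."""
    if eps <= 0:
        raise ValueError("inversion requires eps > 0")
    if delta < delta0:
        raise ValueError(
            f"observed delta {delta} below initial {delta0}: would imply negative extent"
        )
    return ((1000.0 + delta0) / (1000.0 + delta)) ** (1000.0 / eps)


def extent_from_offset(
    delta_central_offset: Measurement,
    params: RayleighParams | None = None,
    sample_id: str = "",
) -> ExtentEstimate | None:
    """Invert the central-position excess for biodegradation extent.

    Returns None when the offset is bdl or missing (estimate unavailable,
    e.g. M-3 whose offset is below detection).
    """
    params = params or RayleighParams()
    if delta_central_offset is None or isinstance(delta_central_offset, Bdl):
        return None
    f = rayleigh_invert(float(delta_central_offset), params.eps_central, params.delta0_offset)
    return ExtentEstimate(sample_id, f, 100.0 * (1.0 - f), float(delta_central_offset))


def extents_for_records(
    records: Sequence[SampleRecord], params: RayleighParams | None = None
) -> list[ExtentEstimate]:
    """Extent estimates for every record with a measured central excess."""
    out = []
    for r in records:
        est = extent_from_offset(r.isotope_value(OFFSET_LABEL), params, sample_id=r.id)
        if est is not None:
            out.append(est)
    return out


def _value_for(record: SampleRecord, key: str) -> Measurement:
    """Resolve a series key: 'pct:<species>' for mole %, else an isotope label."""
    if key.startswith("pct:"):
        return record.composition.get(key[4:])
    if key in ("offset", "delta_central_offset"):
        key = OFFSET_LABEL
    return record.isotope_value(key) if key in record.isotopes else None


def paired_series(
    records: Sequence[SampleRecord], x_key: str, y_key: str
) -> tuple[np.ndarray, np.ndarray]:
    """Paired present values of two series; bdl and missing rows are dropped."""
    xs, ys = [], []
    for r in records:
        x = _value_for(r, x_key)
        y = _value_for(r, y_key)
        if is_value(x) and is_value(y):
            xs.append(float(x))
            ys.append(float(y))
    return np.asarray(xs), np.asarray(ys)


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> TrendFit:
    if x.size < 2:
        raise ValueError("need at least 2 paired points")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    return TrendFit(float(res.slope), float(res.intercept), float(res.rvalue), int(x.size))


def codegradation_slope(records: Sequence[SampleRecord]) -> TrendFit:
    """OLS of propane mole % on ethane mole %.

    A linear co-depletion of the two gases during biodegradation shows up
    as a straight concentration-concentration trend; its slope compares
    how fast the two pools shrink.
    """
    x, y = paired_series(records, "pct:c2h6", "pct:c3h8")
    if x.size < 3:
        raise ValueError("need >= 3 records with both ethane and propane present")
    return _ols(x, y)


def isotope_cotrend(
    records: Sequence[SampleRecord], x_key: str, y_key: str
) -> TrendFit:
    """OLS slope and Pearson r of series y against series x (bdl-aware)."""
    x, y = paired_series(records, x_key, y_key)
    if x.size < 3:
        raise ValueError(f"need >= 3 paired values for {x_key!r} vs {y_key!r}")
    return _ols(x, y)


@dataclass(frozen=True)
class SecondaryMethaneReport:
    co2_all_above_threshold: bool | None
    co2_threshold: float
    r_offset_vs_d13c_ch4: float | None
    r_offset_vs_pct_ch4: float | None
    verdict: str
    notes: tuple[str, ...] = ()


def secondary_methane_indicator(
    records: Sequence[SampleRecord], co2_threshold: float = 15.0
) -> SecondaryMethaneReport:
    """Qualitative test for secondary microbial methanogenesis.

    Three lines of evidence: (a) residual CO2 is 13C-enriched above the
    threshold in every sample, (b) methane d13C falls as the propane
    central excess rises (addition of 13C-depleted microbial methane),
    (c) the methane fraction rises with the central excess.  The verdict
    is "consistent" only when all three hold; missing inputs degrade to
    "indeterminate".
    """
    notes: list[str] = []

    co2 = [r.isotope_value("d13c_co2") for r in records]
    co2_present = [v for v in co2 if is_value(v)]
    if co2_present:
        co2_flag: bool | None = all(v > co2_threshold for v in co2_present)
    else:
        co2_flag = None
        notes.append("no d13C_CO2 values available")

    def _trend_r(y_key: str) -> float | None:
        try:
            return isotope_cotrend(records, OFFSET_LABEL, y_key).r
        except ValueError as exc:
            notes.append(f"trend vs {y_key}: {exc}")
            return None

    r_ch4 = _trend_r("d13c_ch4")
    r_pct = _trend_r("pct:ch4")

    if co2_flag is None or r_ch4 is None or r_pct is None:
        verdict = "indeterminate"
    elif co2_flag and r_ch4 < 0 and r_pct > 0:
        verdict = "consistent with secondary methanogenesis"
    else:
        verdict = "not consistent"
    return SecondaryMethaneReport(
        co2_flag, co2_threshold, r_ch4, r_pct, verdict, tuple(notes)
    )
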