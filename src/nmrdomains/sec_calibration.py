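"""Analytical size-exclusion chromatography calibration and oligomer state.

A gel-filtration column is calibrated with standards of known mass: the
partition coefficient of each peak,

    Kav = (Ve - V0) / (Vc - V0),

is linear in log10(MW) over the column's separation range.  Sample
masses are read off the inverted fit, and the apparent-to-theoretical
mass ratio classifies the oligomeric state (monomer below 1.4, dimer or
larger from 1.75, in between an exchanging monomer-dimer mixture or a
non-globular species).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy import stats

log = logging.getLogger(__name__)

MONOMER_BELOW = 1.4
DIMER_FROM = 1.75


@dataclass(frozen=True)
class SECStandard:
    name: str
    mw_kda: float
    elution_volume_ml: float

    def __post_init__(self) -> None:
        if self.mw_kda <= 0:
            raise ValueError(f"standard {self.name}: non-positive MW")


@dataclass
class SECCalibration:
    v0_ml: float
    vc_ml: float
    slope: float       # Kav per log10(kDa)
    intercept: float
    r_squared: float
    mw_range_kda: tuple[float, float] = (0.0, math.inf)

    def to_dict(self) -> dict:
        return {
            "v0_ml": self.v0_ml,
            "vc_ml": self.vc_ml,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "mw_range_kda": list(self.mw_range_kda),
        }


def compute_kav(ve: float, v0: float, vc: float) -> float:
    """Partition coefficient (Ve - V0)/(Vc - V0); warns outside [0, 1]."""
    if vc <= v0:
        raise ValueError(f"column volume {vc} must exceed void volume {v0}")
    kav = (ve - v0) / (vc - v0)
    if not (-0.05 <= kav <= 1.05):
        log.warning("Kav = %.3f outside [0, 1]: check volumes", kav)
    return kav


def fit_calibration(
    standards: list[SECStandard], v0: float, vc: float
) -> SECCalibration:
    """Ordinary least squares of Kav on log10(MW) over >= 2 standards."""
    if len({s.mw_kda for s in standards}) < 2:
        raise ValueError("need >= 2 standards with distinct MWs")
    x = [math.log10(s.mw_kda) for s in standards]
    y = [compute_kav(s.elution_volume_ml, v0, vc) for s in standards]
    fit = stats.linregress(x, y)
    return SECCalibration(
        v0_ml=v0,
        vc_ml=vc,
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.rvalue**2,
        mw_range_kda=(min(s.mw_kda for s in standards), max(s.mw_kda for s in standards)),
    )


def estimate_mw(kav: float, cal: SECCalibration) -> float:
    """Apparent MW (kDa) by inverting the calibration line."""
    if cal.slope == 0:
        raise ValueError("calibration slope is zero: cannot invert")
    mw = 10.0 ** ((kav - cal.intercept) / cal.slope)
    lo, hi = cal.mw_range_kda
    if not (lo <= mw <= hi):
        log.warning(
            "apparent MW %.2f kDa extrapolates beyond the standards range "
            "[%.2f, %.2f]", mw, lo, hi,
        )
    return mw


@dataclass
class OligomerCall:
    ratio: float
    state: str  # monomer | monomer_dimer_intermediate | dimer_or_larger

    def to_dict(self) -> dict:
        return {"ratio": self.ratio, "state": self.state}


def classify_oligomer(apparent_mw: float, monomer_mw: float) -> OligomerCall:
    """Classify apparent/theoretical mass ratio into oligomeric states.

    The thresholds partition (0, inf): below 1.4 monomer, from 1.75 dimer
    or larger, in between an intermediate (monomer-dimer mix or
    non-globular retention behaviour).
    """
    if apparent_mw <= 0 or monomer_mw <= 0:
        raise ValueError("masses must be positive")
    ratio = apparent_mw / monomer_mw
    if ratio < MONOMER_BELOW:
        state = "monomer"
    elif ratio >= DIMER_FROM:
        state = "dimer_or_larger"
    else:
        state = "monomer_dimer_intermediate"
    return OligomerCall(ratio=ratio, state=state)


@dataclass
class SECSampleReport:
    name: str
    kav: float
    apparent_mw_kda: float
    oligomer: OligomerCall

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kav": self.kav,
            "apparent_mw_kda": self.apparent_mw_kda,
            **self.oligomer.to_dict(),
        }


def analyze_samples(
    samples: list[tuple[str, float, float]],  # (name, ve_ml, monomer_mw_kda)
    cal: SECCalibration,
) -> list[SECSampleReport]:
    reports = []
    for name, ve, monomer_mw in samples:
        kav = compute_kav(ve, cal.v0_ml, cal.vc_ml)
        mw = estimate_mw(kav, cal)
        reports.append(
            SECSampleReport(name, kav, mw, classify_oligomer(mw, monomer_mw))
        )
    return reports
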