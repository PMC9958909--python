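"""15N relaxation analysis: decay fitting, tau_c and apparent MW.

Longitudinal (T1), transverse (T2) and rotating-frame (T1rho) series are
mono-exponential intensity decays I(t) = I0 * exp(-R t); rates are the
fitted decay constants (the reciprocal relaxation times).

The rotational correlation time is estimated per residue from the R2/R1
ratio, which for a rigid isotropic tumbler is a monotonic function of
tau_c.  Two algebraic readings of the estimator are provided:

    threehalves (default):  tau_c = 1/(2 pi nuN) * sqrt(3/2 * R2/R1 - 7/6)
    classical:              tau_c = 1/(4 pi nuN) * sqrt(6 * R2/R1 - 7)

with nuN the 15N Larmor frequency.  Both are valid only outside extreme
narrowing (R2/R1 above the root boundary).  The domain average tau_c
converts to an apparent molecular weight through the empirical ~0.6 ns
per kDa rule for globular proteins near 298 K, so a tau_c of 6 ns reads
as ~10 kDa.  A large relative spread of R2 across a domain (> 50 %)
flags microsecond-millisecond chemical exchange contaminating R2.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError
from .flexibility import HetNOEProfile, classify_flexibility

NS_PER_KDA = 0.6  # empirical tau_c-to-MW slope near 298 K

_ROOT_BOUNDARY = {"threehalves": 7.0 / 9.0, "classical": 7.0 / 6.0}


@dataclass
class RelaxationSeries:
    """Intensity-vs-delay curves for one experiment type."""

    experiment: str  # "T1" | "T2" | "T1rho"
    field_proton_mhz: float
    curves: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    # residue -> [(delay_ms, intensity), ...]

    def __post_init__(self) -> None:
        if self.experiment not in ("T1", "T2", "T1rho"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        for resnum, curve in self.curves.items():
            delays = [d for d, _ in curve]
            if any(d < 0 for d in delays):
                raise ValueError(f"residue {resnum}: negative delay")
            if len(set(delays)) < 4:
                raise ValueError(
                    f"residue {resnum}: need >= 4 distinct delays, "
                    f"got {len(set(delays))}"
                )


@dataclass(frozen=True)
class RateEntry:
    residue_number: int
    rate: float        # s^-1
    error: float       # s^-1, from fit covariance
    fit_quality: float  # 1 - SSR/SST
    flagged: bool = False  # non-positive rate etc.; exclude downstream


@dataclass
class RateProfile:
    experiment: str
    entries: list[RateEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries.sort(key=lambda e: e.residue_number)

    def valid(self) -> list[RateEntry]:
        return [e for e in self.entries if not e.flagged]

    def rates(self) -> dict[int, float]:
        return {e.residue_number: e.rate for e in self.valid()}

    def to_records(self) -> list[dict]:
        return [
            {
                "residue_number": e.residue_number,
                "rate": e.rate,
                "error": e.error,
                "fit_quality": e.fit_quality,
                "flagged": e.flagged,
            }
            for e in self.entries
        ]


def fit_monoexponential(
    curve: list[tuple[float, float]],
) -> tuple[float, float, float, float]:
    """Least-squares fit of I(t) = I0 * exp(-R t) to (delay_ms, intensity).

    Returns ``(rate_s, amplitude, rate_error_s, fit_quality)`` with the
    rate in s^-1 (delays are milliseconds).  A non-positive fitted rate
    is returned as-is; callers flag and exclude it.  fit_quality is
    1 - SSR/SST.
    """
    if len(curve) < 4 or len({d for d, _ in curve}) < 3:
        raise ValueError("need >= 4 points over >= 3 distinct delays")
    t = np.asarray([d for d, _ in curve], dtype=float) * 1e-3  # s
    y = np.asarray([i for _, i in curve], dtype=float)

    # log-linear start values; fall back to crude guesses for noisy data
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = y > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
            p0 = (math.exp(intercept), max(-slope, 1e-3))
        else:
            p0 = (float(y.max()), 1.0)

    def model(tt, i0, r):
        return i0 * np.exp(-r * tt)

    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"mono-exponential fit did not converge: {exc}")
    i0, rate = popt
    err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("inf")
    resid = y - model(t, *popt)
    sst = float(np.sum((y - y.mean()) ** 2))
    quality = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    return float(rate), float(i0), err, quality


def fit_rate_profile(series: RelaxationSeries) -> RateProfile:
    """Fit every residue of a relaxation series; non-positive rates flagged."""
    entries = []
    for resnum, curve in sorted(series.curves.items()):
        rate, _, err, quality = fit_monoexponential(curve)
        # a vanishing or negative decay constant means no decay was observed
        entries.append(
            RateEntry(resnum, rate, err, quality, flagged=rate <= 1e-6)
        )
    return RateProfile(series.experiment, entries)


def tauc_from_ratio(
    r2: float, r1: float, nu_n_hz: float, estimator: str = "threehalves"
) -> float:
    """Rotational correlation time (ns) from an R2/R1 ratio.

    Valid only above the root boundary of the chosen reading (outside
    extreme narrowing); below it a ValueError is raised.
    """
    if r1 <= 0:
        raise ValueError(f"R1 must be positive, got {r1}")
    if estimator not in _ROOT_BOUNDARY:
        raise ValueError(f"estimator must be one of {sorted(_ROOT_BOUNDARY)}")
    ratio = r2 / r1
    if ratio < _ROOT_BOUNDARY[estimator]:
        raise ValueError(
            f"R2/R1 = {ratio:.4g} < {_ROOT_BOUNDARY[estimator]:.4g}: "
            "extreme narrowing; estimator invalid"
        )
    if estimator == "threehalves":
        arg = 1.5 * ratio - 7.0 / 6.0
        tau_s = math.sqrt(max(arg, 0.0)) / (2 * math.pi * nu_n_hz)
    else:
        arg = 6.0 * ratio - 7.0
        tau_s = math.sqrt(max(arg, 0.0)) / (4 * math.pi * nu_n_hz)
    return tau_s * 1e9


@dataclass
class TauCResult:
    per_residue: dict[int, float]       # ns
    domain_tau_c: float                 # ns, mean over included residues
    domain_tau_c_sd: float              # ns
    nu_n_hz: float
    apparent_mw_kda: float
    exchange_flag: bool
    included_residues: list[int] = field(default_factory=list)
    r2_source: str = "R2"               # "R2" or "R1rho"

    def to_dict(self) -> dict:
        return {
            "per_residue_tau_c_ns": {str(k): v for k, v in sorted(self.per_residue.items())},
            "domain_tau_c_ns": self.domain_tau_c,
            "domain_tau_c_sd_ns": self.domain_tau_c_sd,
            "nu_n_hz": self.nu_n_hz,
            "apparent_mw_kda": self.apparent_mw_kda,
            "exchange_flag": self.exchange_flag,
            "included_residues": self.included_residues,
            "r2_source": self.r2_source,
        }


def domain_tauc(
    rates_r1: RateProfile,
    rates_r2: RateProfile,
    nu_n_hz: float,
    estimator: str = "threehalves",
    hetnoe: HetNOEProfile | None = None,
    include: list[int] | None = None,
    trim: float = 0.0,
) -> TauCResult:
    """Domain-average tau_c (mean +- SD) and apparent MW.

    Included residues: an explicit ``include`` list; otherwise the
    residues classified rigid from a supplied hetNOE profile (excluding
    flexible termini from the tumbling estimate); otherwise all residues
    with valid rates.  Residues whose ratio falls below the estimator's
    root boundary are dropped.  ``trim`` (fraction per tail) enables
    trimmed statistics for exchange-contaminated profiles; plain mean is
    the default.  The R1rho profile may be passed as ``rates_r2`` (its
    experiment label is propagated to the report).
    """
    r1 = rates_r1.rates()
    r2 = rates_r2.rates()
    shared = sorted(set(r1) & set(r2))
    if include is not None:
        shared = [r for r in shared if r in set(include)]
    elif hetnoe is not None:
        rigid = set(classify_flexibility(hetnoe).rigid_residues())
        shared = [r for r in shared if r in rigid]
    per_residue = {}
    for resnum in shared:
        try:
            per_residue[resnum] = tauc_from_ratio(
                r2[resnum], r1[resnum], nu_n_hz, estimator
            )
        except ValueError:
            continue
    if not per_residue:
        raise ValueError("no residues with valid rates for tau_c estimation")
    values = sorted(per_residue.values())
    if trim > 0:
        k = int(len(values) * trim)
        values = values[k:len(values) - k] or values
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    diag = exchange_diagnostic(rates_r2) if len(rates_r2.valid()) >= 3 else None
    return TauCResult(
        per_residue=per_residue,
        domain_tau_c=mean,
        domain_tau_c_sd=sd,
        nu_n_hz=nu_n_hz,
        apparent_mw_kda=mw_from_tauc(mean),
        exchange_flag=diag.flagged if diag else False,
        included_residues=sorted(per_residue),
        r2_source="R1rho" if rates_r2.experiment == "T1rho" else "R2",
    )


def mw_from_tauc(tau_c_ns: float, ns_per_kda: float = NS_PER_KDA) -> float:
    """Apparent molecular weight (kDa) from tau_c via the 0.6 ns/kDa rule."""
    if tau_c_ns < 0:
        raise ValueError(f"tau_c must be non-negative, got {tau_c_ns}")
    return tau_c_ns / ns_per_kda


@dataclass
class ExchangeDiagnostic:
    relative_sd: float
    flagged: bool

    def to_dict(self) -> dict:
        return {"relative_sd": self.relative_sd, "flagged": self.flagged}


def exchange_diagnostic(r2_profile: RateProfile, threshold: float = 0.5) -> ExchangeDiagnostic:
    """Flag chemical exchange when SD/mean of R2 exceeds 50 %."""
    rates = [e.rate for e in r2_profile.valid()]
    if len(rates) < 3:
        raise ValueError("need >= 3 residues for an exchange diagnostic")
    mean = statistics.fmean(rates)
    sd = statistics.pstdev(rates)
    rel = sd / mean
    return ExchangeDiagnostic(relative_sd=rel, flagged=rel > threshold)
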