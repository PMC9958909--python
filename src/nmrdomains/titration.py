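"""Chemical shift perturbation (CSP) analysis of HSQC titrations.

In the fast-exchange regime a ligand titration moves each affected amide
peak continuously along a straight trajectory from its free toward its
bound position; the combined perturbation per residue is

    CSP = sqrt((dN / 5)^2 + dH^2)

with the 15N change down-weighted by 5 to put both nuclei on a common
ppm scale.  Binding-site mapping selects residues whose endpoint CSP
exceeds a profile-derived threshold (mean, 2*SD, or mean + 2*SD of all
CSPs).  Trajectory comparison between ligands or protein variants uses
the per-residue cosine between (dH, dN/5) vectors: identical directions
with different extents indicate the same binding mode with different
affinities.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field

from .io import Peak, PeakList

log = logging.getLogger(__name__)

N_SCALE = 5.0  # 15N down-weighting in the combined CSP

SIGNIFICANCE_MODES = ("mean", "two_sd", "mean_plus_two_sd")


def _scaled_distance(d_h: float, d_n: float) -> float:
    return math.sqrt((d_n / N_SCALE) ** 2 + d_h ** 2)


@dataclass
class TitrationSeries:
    """Ordered ligand:protein titration, first point apo (ratio 0)."""

    ligand_id: str
    protein_conc_mm: float
    points: list[tuple[float, PeakList]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.points:
            ratios = [r for r, _ in self.points]
            if ratios[0] != 0:
                raise ValueError("first titration point must be apo (ratio 0)")
            if any(b <= a for a, b in zip(ratios, ratios[1:])):
                raise ValueError("molar ratios must be strictly increasing")

    @property
    def ratios(self) -> list[float]:
        return [r for r, _ in self.points]

    @property
    def apo(self) -> PeakList:
        return self.points[0][1]

    @property
    def endpoint(self) -> PeakList:
        return self.points[-1][1]


@dataclass(frozen=True)
class CSPEntry:
    residue_number: int
    d_h: float
    d_n: float
    csp: float


@dataclass
class CSPProfile:
    entries: list[CSPEntry] = field(default_factory=list)
    endpoint_ratio: float = 0.0

    def __post_init__(self) -> None:
        self.entries.sort(key=lambda e: e.residue_number)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, residue_number: int) -> CSPEntry | None:
        for e in self.entries:
            if e.residue_number == residue_number:
                return e
        return None

    def csps(self) -> dict[int, float]:
        return {e.residue_number: e.csp for e in self.entries}

    def to_records(self) -> list[dict]:
        return [
            {
                "residue_number": e.residue_number,
                "d_h": e.d_h,
                "d_n": e.d_n,
                "csp": e.csp,
                "endpoint_ratio": self.endpoint_ratio,
            }
            for e in self.entries
        ]


@dataclass
class SignificanceResult:
    mode: str
    threshold: float
    significant_residues: list[int]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "threshold": self.threshold,
            "significant_residues": self.significant_residues,
        }


@dataclass
class MatchResult:
    pairs: dict[int, tuple[Peak, Peak]]
    jumps: list[int]          # paired residues moving farther than tol
    only_a: list[int]
    only_b: list[int]


def match_peaks(a: PeakList, b: PeakList, tol: float = 0.15) -> MatchResult:
    """Pair peaks of two assigned lists by residue number.

    Pairs whose combined-scaled distance exceeds ``tol`` are still paired
    but flagged as jumps (peak moved suspiciously far between points).
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if not a.peaks or not b.peaks:
        raise ValueError("peak lists must be non-empty")
    res_a, res_b = set(a.residues()), set(b.residues())
    pairs, jumps = {}, []
    for resnum in sorted(res_a & res_b):
        pa, pb = a.get(resnum), b.get(resnum)
        pairs[resnum] = (pa, pb)
        if _scaled_distance(pb.h_ppm - pa.h_ppm, pb.n_ppm - pa.n_ppm) > tol:
            jumps.append(resnum)
    return MatchResult(
        pairs=pairs,
        jumps=jumps,
        only_a=sorted(res_a - res_b),
        only_b=sorted(res_b - res_a),
    )


def match_peaks_nearest(a: PeakList, b: PeakList, tol: float = 0.15) -> MatchResult:
    """Nearest-neighbour pairing for unassigned endpoints.

    Each peak of ``a`` takes the closest peak of ``b`` within ``tol``
    (combined-scaled distance); ties break by smallest distance, then by
    lowest residue number of the ``b`` candidate.  Greedy, one-to-one.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    candidates = []
    for pa in a.peaks:
        for pb in b.peaks:
            d = _scaled_distance(pb.h_ppm - pa.h_ppm, pb.n_ppm - pa.n_ppm)
            if d <= tol:
                candidates.append((d, pa.residue_number, pb.residue_number, pa, pb))
    candidates.sort(key=lambda c: (c[0], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = {}
    for d, ra, rb, pa, pb in candidates:
        if ra in used_a or rb in used_b:
            continue
        pairs[ra] = (pa, pb)
        used_a.add(ra)
        used_b.add(rb)
    return MatchResult(
        pairs=pairs,
        jumps=[],
        only_a=sorted(set(a.residues()) - used_a),
        only_b=sorted(set(b.residues()) - used_b),
    )


def compute_csp(apo: PeakList, bound: PeakList, endpoint_ratio: float = 0.0) -> CSPProfile:
    """Per-residue combined 1H/15N perturbation between two peak lists."""
    shared = sorted(set(apo.residues()) & set(bound.residues()))
    if not shared:
        raise ValueError("no shared residues between apo and bound lists")
    entries = []
    for resnum in shared:
        pa, pb = apo.get(resnum), bound.get(resnum)
        d_h = pb.h_ppm - pa.h_ppm
        d_n = pb.n_ppm - pa.n_ppm
        entries.append(CSPEntry(resnum, d_h, d_n, _scaled_distance(d_h, d_n)))
    return CSPProfile(entries, endpoint_ratio=endpoint_ratio)


def significance(profile: CSPProfile, mode: str = "mean_plus_two_sd") -> SignificanceResult:
    """Residues with CSP strictly above a profile-derived threshold.

    Threshold by mode: ``mean`` — mean CSP; ``two_sd`` — 2*SD;
    ``mean_plus_two_sd`` — mean + 2*SD (population SD over all residues).
    """
    if mode not in SIGNIFICANCE_MODES:
        raise ValueError(f"mode must be one of {SIGNIFICANCE_MODES}")
    if len(profile) < 3:
        raise ValueError("need at least 3 residues for a significance threshold")
    values = [e.csp for e in profile.entries]
    mean = statistics.fmean(values)
    sd = statistics.pstdev(values)  # population SD: the profile is the full population of observed residues
    threshold = {
        "mean": mean,
        "two_sd": 2 * sd,
        "mean_plus_two_sd": mean + 2 * sd,
    }[mode]
    if mode != "mean" and sd == 0:
        # a zero-variance profile supports no outlier claim
        significant: list[int] = []
    else:
        significant = [e.residue_number for e in profile.entries if e.csp > threshold]
    return SignificanceResult(mode=mode, threshold=threshold, significant_residues=significant)


@dataclass
class TrajectoryComparison:
    cosines: dict[int, float]
    summary: float | None  # median cosine over residues significant in either

    def to_dict(self) -> dict:
        return {
            "cosines": {str(k): v for k, v in sorted(self.cosines.items())},
            "summary": self.summary,
        }


def _cosine(u: tuple[float, float], v: tuple[float, float]) -> float:
    nu = math.hypot(*u)
    nv = math.hypot(*v)
    return (u[0] * v[0] + u[1] * v[1]) / (nu * nv)


def trajectory_similarity(a: CSPProfile, b: CSPProfile) -> TrajectoryComparison:
    """Per-residue cosine between (dH, dN/5) shift vectors of two profiles.

    Cosine 1 means identical trajectory direction (same binding mode,
    possibly different extent); residues with a zero vector in either
    profile are skipped with a notice.  The summary is the median cosine
    over residues significant in either profile (falling back to all
    shared residues when neither profile supports a threshold).
    """
    shared = sorted(set(a.csps()) & set(b.csps()))
    if not shared:
        raise ValueError("profiles share no residues")
    cosines: dict[int, float] = {}
    for resnum in shared:
        ea, eb = a.get(resnum), b.get(resnum)
        va = (ea.d_h, ea.d_n / N_SCALE)
        vb = (eb.d_h, eb.d_n / N_SCALE)
        if math.hypot(*va) == 0 or math.hypot(*vb) == 0:
            log.info("residue %d: zero shift vector, skipped", resnum)
            continue
        cosines[resnum] = _cosine(va, vb)
    if not cosines:
        raise ValueError("no residues with nonzero shift vectors in both profiles")
    sig: set[int] = set()
    for prof in (a, b):
        if len(prof) >= 3:
            sig |= set(significance(prof).significant_residues)
    pool = [c for r, c in cosines.items() if r in sig] or list(cosines.values())
    return TrajectoryComparison(cosines=cosines, summary=statistics.median(pool))


@dataclass
class FoldAssessment:
    verdict: str  # "folded" | "collapsed"
    h_range: float
    h_sd: float

    def to_dict(self) -> dict:
        return {"verdict": self.verdict, "h_range": self.h_range, "h_sd": self.h_sd}


def assess_fold(
    peaks: PeakList,
    range_threshold: float = 1.5,
    sd_threshold: float = 0.35,
) -> FoldAssessment:
    """Judge foldedness from amide 1H dispersion.

    A folded domain shows well-dispersed amide protons; a collapsed
    (unfolded) species piles up near random-coil positions (~7.9-8.5
    ppm).  Folded iff the 1H shift range exceeds ``range_threshold`` AND
    the 1H SD exceeds ``sd_threshold``.
    """
    if len(peaks) < 10:
        raise ValueError("need at least 10 peaks to assess dispersion")
    hs = [p.h_ppm for p in peaks.peaks]
    h_range = max(hs) - min(hs)
    h_sd = statistics.pstdev(hs)
    folded = h_range > range_threshold and h_sd > sd_threshold
    return FoldAssessment("folded" if folded else "collapsed", h_range, h_sd)


@dataclass
class VariantComparison:
    extent_ratio: float
    trajectory_summary: float | None
    verdict: str  # wt_like | reduced | abolished | nonspecific

    def to_dict(self) -> dict:
        return {
            "extent_ratio": self.extent_ratio,
            "trajectory_summary": self.trajectory_summary,
            "verdict": self.verdict,
        }


def compare_variant_binding(
    wt_profile: CSPProfile,
    variant_profile: CSPProfile,
    mode: str = "mean_plus_two_sd",
) -> VariantComparison:
    """Compare a variant's binding response against wild type.

    ``extent_ratio`` sums the variant's CSPs over the WT-significant
    residues and divides by the WT sum over the same residues.  Verdicts:
    < 0.1 abolished; [0.1, 0.7) with matching trajectories (summary
    cosine > 0.8) reduced; >= 0.7 with matching trajectories wt_like;
    anything else nonspecific.
    """
    wt_sig = significance(wt_profile, mode).significant_residues
    if not wt_sig:
        raise ValueError("wild-type profile has no significant residues")
    wt_sum = sum(wt_profile.get(r).csp for r in wt_sig)
    var_sum = sum(
        (variant_profile.get(r).csp if variant_profile.get(r) else 0.0)
        for r in wt_sig
    )
    extent_ratio = var_sum / wt_sum
    try:
        summary = trajectory_similarity(wt_profile, variant_profile).summary
    except ValueError:
        summary = None
    if extent_ratio < 0.1:
        verdict = "abolished"
    elif 0.1 <= extent_ratio < 0.7 and summary is not None and summary > 0.8:
        verdict = "reduced"
    elif extent_ratio >= 0.7 and summary is not None and summary > 0.8:
        verdict = "wt_like"
    else:
        verdict = "nonspecific"
    return VariantComparison(extent_ratio, summary, verdict)
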