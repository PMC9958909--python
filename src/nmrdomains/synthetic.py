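"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a seed, and each
attaches the ground truth it planted, so that every analysis stage can
be tested without experimental data:

* single-site fast-exchange titrations (quadratic binding isotherm,
  population-weighted peak positions),
* 15N relaxation rates from a Lipari-Szabo model-free spectral density
  (the physical oracle behind the R2/R1 -> tau_c estimator) and
  mono-exponential decay curves at the standard delay lists,
* secondary-shift tables with planted helix/strand offsets,
* hetNOE profiles with a rigid plateau and flexible termini,
* SEC calibration standards and samples on a known Kav / log10(MW) line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flexibility import HetNOEEntry, HetNOEProfile
from .io import Peak, PeakList
from .random_coil import RandomCoilTable
from .relaxation import RelaxationSeries
from .sec_calibration import SECStandard
from .secondary_structure import SSEAnnotation
from .titration import TitrationSeries

# ---------------------------------------------------------------------------
# Binding isotherm

@dataclass
class BindingModel:
    """Single-site binder: per-residue endpoint shifts scale with the
    bound fraction from the quadratic isotherm."""

    kd_mm: float
    protein_conc_mm: float
    endpoint_shifts: dict[int, tuple[float, float]] = field(default_factory=dict)
    # residue -> (d_h_max ppm, d_n_max ppm)

    def __post_init__(self) -> None:
        if self.kd_mm <= 0 or self.protein_conc_mm <= 0:
            raise ValueError("kd and protein concentration must be positive")


def fraction_bound(p_mm: float, l_mm: float, kd_mm: float) -> float:
    """Bound protein fraction for single-site binding (exact quadratic).

    f_b = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / (2 P)
    """
    if p_mm <= 0:
        raise ValueError("protein concentration must be positive")
    if l_mm < 0:
        raise ValueError("ligand concentration must be non-negative")
    if kd_mm <= 0:
        raise ValueError("Kd must be positive")
    s = p_mm + l_mm + kd_mm
    disc = s * s - 4.0 * p_mm * l_mm
    fb = (s - math.sqrt(max(disc, 0.0))) / (2.0 * p_mm)
    return min(max(fb, 0.0), 1.0)


def gen_titration(
    base_peaks: PeakList,
    model: BindingModel,
    ratios: list[float],
    noise_ppm: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Simulate a fast-exchange titration over the given molar ratios.

    At each point, binding residues move by f_b x endpoint vector
    (population-weighted average of free and bound positions); all peaks
    are jittered with Gaussian noise of ``noise_ppm`` on both axes (the
    15N axis jitter is scaled x5, keeping noise isotropic in combined-CSP
    space).  Ground truth is attached as ``series.ground_truth``.
    """
    if not ratios or ratios[0] != 0:
        raise ValueError("ratios must start at 0 (apo point)")
    missing = set(model.endpoint_shifts) - set(base_peaks.residues())
    if missing:
        raise ValueError(f"binding residues absent from base peaks: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    points = []
    fbs = []
    for ratio in ratios:
        l_mm = ratio * model.protein_conc_mm
        fb = fraction_bound(model.protein_conc_mm, l_mm, model.kd_mm) if l_mm > 0 else 0.0
        fbs.append(fb)
        peaks = []
        for p in base_peaks.peaks:
            d_h, d_n = model.endpoint_shifts.get(p.residue_number, (0.0, 0.0))
            h = p.h_ppm + fb * d_h
            n = p.n_ppm + fb * d_n
            if noise_ppm > 0:
                h += rng.normal(0.0, noise_ppm)
                n += rng.normal(0.0, noise_ppm * 5.0)
            peaks.append(Peak(p.residue_number, p.residue_type, h, n, p.height))
        points.append((ratio, PeakList(peaks)))
    series = TitrationSeries(
        ligand_id="synthetic", protein_conc_mm=model.protein_conc_mm, points=points
    )
    series.ground_truth = {
        "binding_residues": sorted(model.endpoint_shifts),
        "fraction_bound": dict(zip(ratios, fbs)),
        "kd_mm": model.kd_mm,
    }
    return series


# ---------------------------------------------------------------------------
# Spin physics oracle

GAMMA_H = 2.6752218744e8   # rad s^-1 T^-1
GAMMA_N = -2.7116e7        # rad s^-1 T^-1 (negative gyromagnetic ratio)
HBAR = 1.054571817e-34     # J s
MU0 = 4e-7 * math.pi


@dataclass
class SpinPhysicsModel:
    """Model-free description of a backbone 15N-1H spin pair."""

    tau_c_ns: float
    s2: float = 1.0
    tau_e_ps: float = 0.0
    rex: float = 0.0
    field_proton_mhz: float = 600.0
    r_nh_angstrom: float = 1.02
    delta_sigma_ppm: float = -160.0

    def __post_init__(self) -> None:
        if self.tau_c_ns <= 0:
            raise ValueError("tau_c must be positive")
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError("order parameter S2 must lie in [0, 1]")


def _spectral_density(model: SpinPhysicsModel):
    """J(w) = 2/5 [S2 tc/(1+(w tc)^2) + (1-S2) t/(1+(w t)^2)],
    1/t = 1/tc + 1/te."""
    tau_c = model.tau_c_ns * 1e-9

    if model.tau_e_ps > 0 and model.s2 < 1.0:
        tau_e = model.tau_e_ps * 1e-12
        tau = 1.0 / (1.0 / tau_c + 1.0 / tau_e)
    else:
        tau = None

    def J(w: float) -> float:
        val = model.s2 * tau_c / (1.0 + (w * tau_c) ** 2)
        if tau is not None:
            val += (1.0 - model.s2) * tau / (1.0 + (w * tau) ** 2)
        return 0.4 * val

    return J


def simulate_relaxation_rates(model: SpinPhysicsModel) -> tuple[float, float, float]:
    """(R1, R2, NOE) for a backbone amide from dipolar + CSA relaxation.

    Standard expressions with the model-free spectral density; R2 gains
    the exchange term ``rex`` additively; NOE is the steady-state
    {1H}15N ratio.
    """
    J = _spectral_density(model)
    w_h = 2 * math.pi * model.field_proton_mhz * 1e6
    w_n = w_h * GAMMA_N / GAMMA_H  # signed
    wh, wn = abs(w_h), abs(w_n)

    r = model.r_nh_angstrom * 1e-10
    d = MU0 * HBAR * GAMMA_H * abs(GAMMA_N) / (4 * math.pi * r**3)
    c = wn * model.delta_sigma_ppm * 1e-6 / math.sqrt(3.0)
    d2, c2 = d * d, c * c

    j_hmn, j_n, j_hpn = J(wh - wn), J(wn), J(wh + wn)
    r1 = (d2 / 4.0) * (j_hmn + 3 * j_n + 6 * j_hpn) + c2 * j_n
    r2 = (
        (d2 / 8.0) * (4 * J(0.0) + j_hmn + 3 * j_n + 6 * J(wh) + 6 * j_hpn)
        + (c2 / 6.0) * (4 * J(0.0) + 3 * j_n)
        + model.rex
    )
    noe = 1.0 + (d2 / (4.0 * r1)) * (GAMMA_H / GAMMA_N) * (6 * j_hpn - j_hmn)
    return r1, r2, noe


# ---------------------------------------------------------------------------
# Relaxation decay curves

#: Delay lists (ms) of the standard interleaved pseudo-3D experiments.
DELAY_PRESETS: dict[str, list[float]] = {
    "paper_T1": [20, 40, 80, 100, 200, 400, 600, 1000, 1400],
    "paper_T2": [16.96, 33.92, 67.84, 101.76, 135.68, 169.6, 203.52, 271.36, 339.2],
    "paper_T1rho": [4, 8, 12, 24, 48, 72, 96, 120, 144],
    "paper_T1_rrm": [10, 50, 150, 250, 350, 500, 750, 1500, 2500],
    "paper_T2_rrm": [33.92, 50.88, 67.84, 84.8, 101.76, 118.72, 135.68,
                     152.64, 169.6, 203.52, 271.36],
}


def gen_relaxation_decays(
    rates: dict[int, float],
    delays_ms: list[float] | str,
    noise_frac: float = 0.0,
    seed: int = 0,
    experiment: str = "T2",
    field_proton_mhz: float = 600.0,
    amplitude: float = 100.0,
) -> RelaxationSeries:
    """Mono-exponential decays I(t) = A exp(-R t) with multiplicative noise.

    ``delays_ms`` may be a preset name from :data:`DELAY_PRESETS`.
    ``rates`` maps residue number to the true rate (s^-1); ground truth
    is attached as ``series.ground_truth``.
    """
    if isinstance(delays_ms, str):
        delays_ms = DELAY_PRESETS[delays_ms]
    if not delays_ms:
        raise ValueError("empty delay list")
    if any(r <= 0 for r in rates.values()):
        raise ValueError("all true rates must be positive")
    rng = np.random.default_rng(seed)
    curves = {}
    for resnum, rate in sorted(rates.items()):
        curve = []
        for d in delays_ms:
            i = amplitude * math.exp(-rate * d * 1e-3)
            if noise_frac > 0:
                i *= 1.0 + rng.normal(0.0, noise_frac)
            curve.append((float(d), i))
        curves[resnum] = curve
    series = RelaxationSeries(
        experiment=experiment, field_proton_mhz=field_proton_mhz, curves=curves
    )
    series.ground_truth = {"rates": dict(sorted(rates.items()))}
    return series


# ---------------------------------------------------------------------------
# Secondary-shift tables

#: Planted offsets (ppm): helices raise Ca and slightly lower Cb, strands
#: do the opposite; magnitudes sit inside accepted empirical ranges.
HELIX_OFFSETS = (2.8, -0.4)   # (dCa, dCb)
STRAND_OFFSETS = (-1.5, 2.0)


def gen_scs_dataset(
    sse_truth: SSEAnnotation,
    rc: RandomCoilTable,
    sequence: str,
    first_residue: int = 1,
    noise_ppm: float = 0.0,
    seed: int = 0,
):
    """Shift table = coil values + planted helix/strand offsets + noise.

    ``sequence`` supplies residue types from ``first_residue`` onward;
    planted elements must lie inside it (overlap is rejected by
    :class:`SSEAnnotation` itself).  Glycines get no CB entry.
    """
    from .io import ShiftEntry, ShiftTable

    last = first_residue + len(sequence) - 1
    for el in sse_truth.elements:
        if el.start < first_residue or el.end > last:
            raise ValueError(f"element {el} outside residues {first_residue}-{last}")
    kind_by_residue: dict[int, str] = {}
    for el in sse_truth.elements:
        for r in range(el.start, el.end + 1):
            kind_by_residue[r] = el.kind
    rng = np.random.default_rng(seed)
    entries = []
    for i, restype in enumerate(sequence):
        resnum = first_residue + i
        kind = kind_by_residue.get(resnum)
        off_ca, off_cb = {
            "helix": HELIX_OFFSETS,
            "strand": STRAND_OFFSETS,
            None: (0.0, 0.0),
        }[kind]
        ca = rc.ca[restype] + off_ca
        if noise_ppm > 0:
            ca += rng.normal(0.0, noise_ppm)
        entries.append(ShiftEntry(resnum, restype, "CA", float(ca)))
        if restype in rc.cb:
            cb = rc.cb[restype] + off_cb
            if noise_ppm > 0:
                cb += rng.normal(0.0, noise_ppm)
            entries.append(ShiftEntry(resnum, restype, "CB", float(cb)))
    table = ShiftTable(entries)
    table.ground_truth = {"elements": sse_truth.to_records()}
    return table


# ---------------------------------------------------------------------------
# hetNOE profiles

def gen_hetnoe_dataset(
    core: tuple[int, int],
    residues: tuple[int, int],
    plateau: float = 0.8,
    terminal_value: float = 0.1,
    noise: float = 0.0,
    seed: int = 0,
    ramp: int = 4,
    dips: list[tuple[int, int, float]] | None = None,
) -> HetNOEProfile:
    """hetNOE profile: rigid plateau on ``core``, termini decaying to
    ``terminal_value`` over ``ramp`` residues, optional planted dips
    (start, end, value) emulating mobile loops inside the core."""
    first, last = residues
    c0, c1 = core
    if not (first <= c0 <= c1 <= last):
        raise ValueError("core must lie inside the residue range")
    dip_value: dict[int, float] = {}
    for d0, d1, v in dips or []:
        for r in range(d0, d1 + 1):
            dip_value[r] = v
    rng = np.random.default_rng(seed)
    entries = []
    for resnum in range(first, last + 1):
        if resnum in dip_value:
            value = dip_value[resnum]
        elif c0 <= resnum <= c1:
            value = plateau
        else:
            dist = c0 - resnum if resnum < c0 else resnum - c1
            frac = min(dist, ramp) / ramp
            value = plateau - (plateau - terminal_value) * frac
        if noise > 0:
            value += rng.normal(0.0, noise)
        entries.append(HetNOEEntry(resnum, float(value), noise))
    profile = HetNOEProfile(entries)
    profile.ground_truth = {"core": [c0, c1], "plateau": plateau}
    return profile


# ---------------------------------------------------------------------------
# SEC runs

def gen_sec_run(
    standards_truth: list[tuple[str, float]],
    v0: float = 8.0,
    vc: float = 24.0,
    noise_ml: float = 0.0,
    seed: int = 0,
    slope: float = -0.4,
    intercept: float = 1.0,
    samples_truth: list[tuple[str, float, float]] | None = None,
):
    """Standards (and optional samples) on a known Kav/log10(MW) line.

    ``standards_truth`` is (name, mw_kda); ``samples_truth`` is
    (name, true_apparent_mw_kda, monomer_mw_kda).  Elution volumes get
    Gaussian jitter of ``noise_ml``.  Returns (standards, samples,
    ground_truth).
    """
    rng = np.random.default_rng(seed)

    def ve_of(mw: float) -> float:
        kav = slope * math.log10(mw) + intercept
        ve = v0 + kav * (vc - v0)
        if noise_ml > 0:
            ve += rng.normal(0.0, noise_ml)
        return float(ve)

    standards = [SECStandard(name, mw, ve_of(mw)) for name, mw in standards_truth]
    samples = [
        (name, ve_of(apparent_mw), monomer_mw)
        for name, apparent_mw, monomer_mw in (samples_truth or [])
    ]
    ground_truth = {
        "slope": slope,
        "intercept": intercept,
        "v0": v0,
        "vc": vc,
        "standards": dict(standards_truth),
    }
    return standards, samples, ground_truth
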