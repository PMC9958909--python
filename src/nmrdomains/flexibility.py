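"""Backbone flexibility from steady-state {1H}15N heteronuclear NOEs.

The hetNOE ratio I_sat/I_ref per amide reports on ps-ns motion: low
ratios mark flexible residues, high ratios rigid ones.  Classification
thresholds: ratio < 0.5 flexible, ratio > 0.65 rigid, in between
"intermediate" (a band the thresholds themselves leave unlabelled).

``rigid_core`` turns per-residue labels into a domain-boundary
suggestion: the longest rigid stretch in which short interruptions are
tolerated, mirroring how a folded core is read off a hetNOE profile that
may dip briefly in a mobile loop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .io import PeakList

log = logging.getLogger(__name__)

FLEXIBLE_BELOW = 0.5
RIGID_ABOVE = 0.65


@dataclass(frozen=True)
class HetNOEEntry:
    residue_number: int
    ratio: float
    error: float = 0.0


@dataclass
class HetNOEProfile:
    entries: list[HetNOEEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if not math.isfinite(e.ratio):
                raise ValueError(f"non-finite ratio at residue {e.residue_number}")
            if e.error < 0:
                raise ValueError(f"negative error at residue {e.residue_number}")
        self.entries.sort(key=lambda e: e.residue_number)

    def __len__(self) -> int:
        return len(self.entries)

    def ratios(self) -> dict[int, float]:
        return {e.residue_number: e.ratio for e in self.entries}

    def to_records(self) -> list[dict]:
        return [
            {"residue_number": e.residue_number, "ratio": e.ratio, "error": e.error}
            for e in self.entries
        ]


@dataclass
class FlexibilityCall:
    labels: dict[int, str] = field(default_factory=dict)  # residue -> label
    rigid_core_range: tuple[int, int] | None = None

    def rigid_residues(self) -> list[int]:
        return sorted(r for r, lab in self.labels.items() if lab == "rigid")

    def to_records(self) -> list[dict]:
        return [
            {"residue_number": r, "label": lab}
            for r, lab in sorted(self.labels.items())
        ]

    def to_dict(self) -> dict:
        return {
            "labels": {str(k): v for k, v in sorted(self.labels.items())},
            "rigid_core": list(self.rigid_core_range) if self.rigid_core_range else None,
        }


def compute_hetnoe(
    sat: PeakList,
    ref: PeakList,
    sigma_sat: float = 0.0,
    sigma_ref: float = 0.0,
) -> HetNOEProfile:
    """Per-residue I_sat/I_ref from two intensity-bearing peak lists.

    Errors propagate per-list noise estimates (spectral noise floors):
    sigma_ratio = |ratio| * sqrt((sigma_sat/I_sat)^2 + (sigma_ref/I_ref)^2);
    with the default sigma = 0 the reported error is 0.  Residues with a
    zero reference intensity are skipped with a warning.
    """
    shared = sorted(set(sat.residues()) & set(ref.residues()))
    if not shared:
        raise ValueError("peak lists share no residues")
    entries = []
    for resnum in shared:
        ps, pr = sat.get(resnum), ref.get(resnum)
        if ps.height is None or pr.height is None:
            raise ValueError(f"residue {resnum} lacks an intensity")
        if pr.height == 0:
            log.warning("residue %d: reference intensity 0, skipped", resnum)
            continue
        ratio = ps.height / pr.height
        err = 0.0
        if (sigma_sat or sigma_ref) and ps.height != 0:
            err = abs(ratio) * math.sqrt(
                (sigma_sat / ps.height) ** 2 + (sigma_ref / pr.height) ** 2
            )
        entries.append(HetNOEEntry(resnum, ratio, err))
    return HetNOEProfile(entries)


def classify_flexibility(profile: HetNOEProfile) -> FlexibilityCall:
    """Label each residue flexible (<0.5), rigid (>0.65) or intermediate."""
    if not profile.entries:
        raise ValueError("empty hetNOE profile")
    labels = {}
    for e in profile.entries:
        if e.ratio < FLEXIBLE_BELOW:
            labels[e.residue_number] = "flexible"
        elif e.ratio > RIGID_ABOVE:
            labels[e.residue_number] = "rigid"
        else:
            labels[e.residue_number] = "intermediate"
    call = FlexibilityCall(labels)
    call.rigid_core_range = rigid_core(call)
    return call


def rigid_core(call: FlexibilityCall, max_gap: int = 3) -> tuple[int, int] | None:
    """Longest rigid stretch tolerating interruptions of <= max_gap residues.

    An interruption is a run of consecutive residue numbers that are
    non-rigid or missing from the profile.  The returned range starts and
    ends on rigid residues; ``None`` if there are none.  The default gap
    of 3 tolerates a short mobile loop inside an otherwise rigid domain.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    rigid = call.rigid_residues()
    if not rigid:
        return None
    best = (rigid[0], rigid[0])
    start = prev = rigid[0]
    for r in rigid[1:]:
        if r - prev - 1 > max_gap:
            if prev - start > best[1] - best[0]:
                best = (start, prev)
            start = r
        prev = r
    if prev - start > best[1] - best[0]:
        best = (start, prev)
    return best
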