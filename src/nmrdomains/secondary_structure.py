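"""Secondary-structure calling from carbon secondary chemical shifts.

The combined Cα/Cβ secondary chemical shift of a residue is

    SCS = (δCα_obs − δCα_coil) − (δCβ_obs − δCβ_coil)

Helix formation shifts Cα downfield and Cβ upfield, so the difference
amplifies both contributions into a single trace: sustained positive
values mark α-helix, sustained negative values mark β-strand.  For
glycine (no Cβ) and residues with an unassigned Cβ the combined value is
ΔδCα alone.

Element calling uses consecutive-residue rules: at least three
consecutive residues with SCS strictly above +threshold make a helix, at
least four consecutive residues strictly below −threshold make a strand
(default threshold 1 ppm).  Residues absent from the profile break runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import NmrDomainsError
from .io import ShiftTable
from .random_coil import RandomCoilTable

log = logging.getLogger(__name__)

MIN_HELIX_LEN = 3
MIN_STRAND_LEN = 4


@dataclass(frozen=True)
class SCSEntry:
    residue_number: int
    residue_type: str
    delta_ca: float
    delta_cb: float | None  # None for Gly / unassigned CB
    combined: float


@dataclass
class SCSProfile:
    entries: list[SCSEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries.sort(key=lambda e: e.residue_number)

    def combined_by_residue(self) -> dict[int, float]:
        return {e.residue_number: e.combined for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def to_records(self) -> list[dict]:
        return [
            {
                "residue_number": e.residue_number,
                "residue_type": e.residue_type,
                "delta_ca": e.delta_ca,
                "delta_cb": e.delta_cb,
                "combined_scs": e.combined,
            }
            for e in self.entries
        ]


@dataclass(frozen=True)
class SSElement:
    kind: str  # "helix" | "strand"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SSEAnnotation:
    elements: list[SSElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.elements.sort(key=lambda e: e.start)
        for a, b in zip(self.elements, self.elements[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping elements {a} and {b}"
                )
        for e in self.elements:
            min_len = MIN_HELIX_LEN if e.kind == "helix" else MIN_STRAND_LEN
            if e.length < min_len:
                raise ValueError(f"{e.kind} {e.start}-{e.end} shorter than {min_len}")

    def to_records(self) -> list[dict]:
        return [
            {"kind": e.kind, "start": e.start, "end": e.end}
            for e in self.elements
        ]


class CoilLookupError(NmrDomainsError, KeyError):
    """A residue type has no entry in the random-coil table."""


def compute_scs(shifts: ShiftTable, rc: RandomCoilTable) -> SCSProfile:
    """Combined Cα/Cβ secondary shifts for every residue with a Cα entry."""
    entries: list[SCSEntry] = []
    for resnum in shifts.residues():
        ca = shifts.get(resnum, "CA")
        if ca is None:
            continue
        restype = ca.residue_type
        if restype not in rc.ca:
            raise CoilLookupError(
                f"residue type {restype!r} (residue {resnum}) missing from "
                f"coil table {rc.table_id!r}"
            )
        delta_ca = ca.shift - rc.ca[restype]
        cb = shifts.get(resnum, "CB")
        if cb is not None and restype in rc.cb:
            delta_cb: float | None = cb.shift - rc.cb[restype]
            combined = delta_ca - delta_cb
        else:
            delta_cb = None
            combined = delta_ca
        entries.append(SCSEntry(resnum, restype, delta_ca, delta_cb, combined))
    if not entries:
        log.warning("no CA shifts found: empty SCS profile")
    return SCSProfile(entries)


def _runs(profile: SCSProfile, predicate) -> list[tuple[int, int]]:
    """Maximal runs of consecutive residue numbers satisfying predicate."""
    runs: list[tuple[int, int]] = []
    start: int | None = None
    run_end = prev = 0
    for e in profile.entries:
        contiguous = start is not None and e.residue_number == prev + 1
        if predicate(e.combined):
            if start is None or not contiguous:
                if start is not None:
                    runs.append((start, run_end))
                start = e.residue_number
            run_end = e.residue_number
        elif start is not None:
            runs.append((start, run_end))
            start = None
        prev = e.residue_number
    if start is not None:
        runs.append((start, run_end))
    return runs


def call_sse(profile: SCSProfile, threshold: float = 1.0) -> SSEAnnotation:
    """Call helices and strands from a combined-SCS profile.

    Helix: >= 3 consecutive residues with SCS > +threshold.
    Strand: >= 4 consecutive residues with SCS < -threshold.
    Strictly greater/less than; gaps in residue numbering break runs.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    elements = [
        SSElement("helix", s, e)
        for s, e in _runs(profile, lambda v: v > threshold)
        if e - s + 1 >= MIN_HELIX_LEN
    ] + [
        SSElement("strand", s, e)
        for s, e in _runs(profile, lambda v: v < -threshold)
        if e - s + 1 >= MIN_STRAND_LEN
    ]
    return SSEAnnotation(elements)
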