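"""Readers and writers for on-disk NMR data formats.

Two tabular container types travel through the whole pipeline:

``ShiftTable``
    Assigned chemical shifts, one row per (residue, atom).  Read from a
    simple TSV dialect or from the chemical-shift loop of an NMR-STAR v3
    deposition (the dialect used by the BMRB).

``PeakList``
    Assigned amide (1H, 15N) peak positions, optionally with intensities,
    one peak per residue.  TSV only.

The TSV dialect is tab-separated with a mandatory header row; lines
starting with ``#`` are comments.  Keyed tables are canonically sorted on
load so that reader output does not depend on on-disk row order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Plausible amide ranges (ppm) used by strict peak-list validation.
H_RANGE = (5.0, 13.0)
N_RANGE = (95.0, 140.0)


@dataclass(frozen=True)
class ShiftEntry:
    residue_number: int
    residue_type: str  # one-letter code
    atom_name: str     # e.g. "CA", "CB", "H", "N"
    shift: float       # ppm


@dataclass
class ShiftTable:
    """Per-residue, per-atom chemical shifts in full-length numbering."""

    entries: list[ShiftEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for e in self.entries:
            key = (e.residue_number, e.atom_name)
            if key in seen:
                raise ValidationError(
                    f"duplicate shift entry for residue {e.residue_number} "
                    f"atom {e.atom_name}"
                )
            if not math.isfinite(e.shift):
                raise ValidationError(
                    f"non-finite shift for residue {e.residue_number} "
                    f"atom {e.atom_name}"
                )
            seen.add(key)
        self.entries.sort(key=lambda e: (e.residue_number, e.atom_name))

    def get(self, residue_number: int, atom_name: str) -> ShiftEntry | None:
        for e in self.entries:
            if e.residue_number == residue_number and e.atom_name == atom_name:
                return e
        return None

    def residues(self) -> list[int]:
        return sorted({e.residue_number for e in self.entries})

    def residue_types(self) -> dict[int, str]:
        return {e.residue_number: e.residue_type for e in self.entries}

    def to_records(self) -> list[dict]:
        return [
            {
                "residue_number": e.residue_number,
                "residue_type": e.residue_type,
                "atom_name": e.atom_name,
                "shift": e.shift,
            }
            for e in self.entries
        ]


@dataclass(frozen=True)
class Peak:
    residue_number: int
    residue_type: str
    h_ppm: float
    n_ppm: float
    height: float | None = None


@dataclass
class PeakList:
    """Assigned amide peaks, at most one per residue."""

    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p in self.peaks:
            if p.residue_number in seen:
                raise ValidationError(
                    f"duplicate peak for residue {p.residue_number}"
                )
            seen.add(p.residue_number)
        self.peaks.sort(key=lambda p: p.residue_number)

    def get(self, residue_number: int) -> Peak | None:
        for p in self.peaks:
            if p.residue_number == residue_number:
                return p
        return None

    def residues(self) -> list[int]:
        return [p.residue_number for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)

    def to_records(self) -> list[dict]:
        recs = []
        for p in self.peaks:
            r = {
                "residue_number": p.residue_number,
                "residue_type": p.residue_type,
                "h_ppm": p.h_ppm,
                "n_ppm": p.n_ppm,
            }
            if p.height is not None:
                r["height"] = p.height
            recs.append(r)
        return recs


# ---------------------------------------------------------------------------
# TSV primitives

def _read_tsv_rows(path: str | Path, required: Sequence[str]) -> list[dict]:
    path = Path(path)
    rows: list[dict] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in required if c not in header]
                if missing:
                    raise FormatError(
                        f"{path}:{lineno}: missing required column(s) "
                        f"{', '.join(missing)}"
                    )
                continue
            if len(fields) < len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            rows.append(
                {h: v.strip() for h, v in zip(header, fields)}
            )
    if header is None:
        raise FormatError(f"{path}: empty file, header row required")
    return rows


def _parse_float(value: str, path: Path, context: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise FormatError(f"{path}: non-numeric value {value!r} for {context}")


def _parse_int(value: str, path: Path, context: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path}: non-integer value {value!r} for {context}")


# ---------------------------------------------------------------------------
# Shift tables

def read_shift_table(path: str | Path, fmt: str | None = None) -> ShiftTable:
    """Read a :class:`ShiftTable` from TSV or an NMR-STAR v3 file.

    ``fmt`` is ``"tsv"``, ``"nmrstar"`` or ``None`` (detect: files whose
    first non-blank character sequence contains ``data_`` or ``loop_`` are
    treated as NMR-STAR).
    """
    path = Path(path)
    if fmt is None:
        head = path.read_text()[:4096]
        fmt = "nmrstar" if ("loop_" in head or head.lstrip().startswith("data_")) else "tsv"
    if fmt == "tsv":
        return _read_shift_table_tsv(path)
    if fmt == "nmrstar":
        return _read_shift_table_star(path)
    raise ValueError(f"unknown shift-table format {fmt!r}")


def _read_shift_table_tsv(path: Path) -> ShiftTable:
    rows = _read_tsv_rows(
        path, ["residue_number", "residue_type", "atom_name", "shift"]
    )
    entries = [
        ShiftEntry(
            residue_number=_parse_int(r["residue_number"], path, "residue_number"),
            residue_type=r["residue_type"],
            atom_name=r["atom_name"],
            shift=_parse_float(r["shift"], path, "shift"),
        )
        for r in rows
    ]
    return ShiftTable(entries)


def _star_tokens(text: str) -> Iterable[str]:
    """Tokenize STAR syntax: whitespace-separated, quoted strings, comments."""
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c in " \t\r\n":
            i += 1
            continue
        if c == "#":
            while i < n and text[i] != "\n":
                i += 1
            continue
        if c in "'\"":
            j = text.find(c, i + 1)
            if j == -1:
                raise FormatError("unterminated quoted string in NMR-STAR file")
            yield text[i + 1:j]
            i = j + 1
            continue
        if c == ";" and (i == 0 or text[i - 1] == "\n"):
            j = text.find("\n;", i + 1)
            if j == -1:
                raise FormatError("unterminated semicolon block in NMR-STAR file")
            yield text[i + 1:j]
            i = j + 2
            continue
        j = i
        while j < n and text[j] not in " \t\r\n":
            j += 1
        yield text[i:j]
        i = j


def _read_shift_table_star(path: Path) -> ShiftTable:
    """Extract the ``_Atom_chem_shift`` loop of an NMR-STAR v3 entry.

    Everything outside that loop is ignored (a notice is logged).  The
    residue index is taken from ``Comp_index_ID`` (falling back to
    ``Seq_ID``), the type from ``Comp_ID`` and the value from ``Val``.
    """
    tokens = list(_star_tokens(path.read_text()))
    entries: list[ShiftEntry] = []
    i = 0
    found_loop = False
    while i < len(tokens):
        if tokens[i] != "loop_":
            i += 1
            continue
        i += 1
        tags: list[str] = []
        while i < len(tokens) and tokens[i].startswith("_"):
            tags.append(tokens[i])
            i += 1
        values: list[str] = []
        while i < len(tokens) and tokens[i] != "stop_":
            values.append(tokens[i])
            i += 1
        i += 1  # consume stop_
        if not tags or not tags[0].startswith("_Atom_chem_shift."):
            continue
        found_loop = True
        names = [t.split(".", 1)[1] for t in tags]

        def col(*candidates: str) -> int:
            for c in candidates:
                if c in names:
                    return names.index(c)
            raise FormatError(
                f"{path}: chemical-shift loop lacks tag(s) {candidates}"
            )

        i_res = col("Comp_index_ID", "Seq_ID")
        i_typ = col("Comp_ID")
        i_atm = col("Atom_ID")
        i_val = col("Val")
        ncol = len(tags)
        if len(values) % ncol:
            raise FormatError(
                f"{path}: chemical-shift loop has ragged rows "
                f"({len(values)} values across {ncol} tags)"
            )
        for r in range(0, len(values), ncol):
            row = values[r:r + ncol]
            comp = row[i_typ].upper()
            restype = THREE_TO_ONE.get(comp, comp if len(comp) == 1 else "X")
            entries.append(
                ShiftEntry(
                    residue_number=_parse_int(row[i_res], path, "Comp_index_ID"),
                    residue_type=restype,
                    atom_name=row[i_atm],
                    shift=_parse_float(row[i_val], path, "Val"),
                )
            )
    if not found_loop:
        raise FormatError(f"{path}: no _Atom_chem_shift loop found")
    log.info("%s: read %d shifts; non-shift content ignored", path, len(entries))
    return ShiftTable(entries)


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("residue_number\tresidue_type\tatom_name\tshift\n")
        for e in table.entries:
            fh.write(
                f"{e.residue_number}\t{e.residue_type}\t{e.atom_name}\t"
                f"{e.shift!r}\n"
            )


# ---------------------------------------------------------------------------
# Peak lists

def read_peaklist(path: str | Path, strict: bool = False) -> PeakList:
    """Read a TSV peak list.

    Columns: ``residue_number``, ``residue_type``, ``h_ppm``, ``n_ppm`` and
    optionally ``height``.  Out-of-range amide positions (1H outside 5–13
    ppm, 15N outside 95–140 ppm) are warnings by default and errors under
    ``strict`` — folded/aliased peaks do occur in practice.
    """
    path = Path(path)
    rows = _read_tsv_rows(path, ["residue_number", "residue_type", "h_ppm", "n_ppm"])
    peaks = []
    for r in rows:
        h = _parse_float(r["h_ppm"], path, "h_ppm")
        n = _parse_float(r["n_ppm"], path, "n_ppm")
        num = _parse_int(r["residue_number"], path, "residue_number")
        if not (H_RANGE[0] < h < H_RANGE[1]) or not (N_RANGE[0] < n < N_RANGE[1]):
            msg = (
                f"{path}: residue {num} peak ({h}, {n}) ppm outside the "
                f"typical amide region"
            )
            if strict:
                raise ValidationError(msg)
            log.warning(msg)
        height = r.get("height")
        peaks.append(
            Peak(
                residue_number=num,
                residue_type=r["residue_type"],
                h_ppm=h,
                n_ppm=n,
                height=_parse_float(height, path, "height") if height not in (None, "") else None,
            )
        )
    return PeakList(peaks)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    has_height = any(p.height is not None for p in peaklist.peaks)
    with open(path, "w") as fh:
        cols = ["residue_number", "residue_type", "h_ppm", "n_ppm"]
        if has_height:
            cols.append("height")
        fh.write("\t".join(cols) + "\n")
        for p in peaklist.peaks:
            row = [str(p.residue_number), p.residue_type, repr(p.h_ppm), repr(p.n_ppm)]
            if has_height:
                row.append(repr(p.height) if p.height is not None else "")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Reports

def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if hasattr(obj, "to_records") and not isinstance(obj, Mapping):
        return [_jsonable(r) for r in obj.to_records()]
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return float(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_report(record, path: str | Path, fmt: str = "json") -> None:
    """Serialize an analysis result to JSON or TSV.

    ``record`` may be a plain dict/list or any result object exposing
    ``to_dict()``/``to_records()``.  Floats keep full repr precision
    (well beyond 6 significant digits).
    """
    path = Path(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(record), fh, indent=2)
            fh.write("\n")
        return
    if fmt == "tsv":
        if hasattr(record, "to_records"):
            records = record.to_records()
        elif isinstance(record, Mapping):
            records = [record]
        else:
            records = list(record)
        if not records:
            raise ValueError("nothing to write: empty record list")
        cols = list(records[0].keys())
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in records:
                fh.write(
                    "\t".join(
                        repr(r[c]) if isinstance(r[c], float) else str(r[c])
                        for c in cols
                    )
                    + "\n"
                )
        return
    raise ValueError(f"unknown report format {fmt!r}")


# ---------------------------------------------------------------------------
# CSV inputs (relaxation curves, SEC tables)

def read_relaxation_csv(
    path: str | Path, experiment: str, field_proton_mhz: float
):
    """Read an intensity-vs-delay CSV with columns
    ``residue_number, delay_ms, intensity`` into a RelaxationSeries."""
    import pandas as pd

    from .relaxation import RelaxationSeries

    df = pd.read_csv(path)
    required = {"residue_number", "delay_ms", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    curves: dict[int, list[tuple[float, float]]] = {}
    for resnum, group in df.groupby("residue_number"):
        curves[int(resnum)] = list(
            zip(group["delay_ms"].astype(float), group["intensity"].astype(float))
        )
    return RelaxationSeries(
        experiment=experiment, field_proton_mhz=field_proton_mhz, curves=curves
    )


def read_sec_standards_csv(path: str | Path):
    """Read a standards CSV with columns ``name, mw_kda, ve_ml``."""
    import pandas as pd

    from .sec_calibration import SECStandard

    df = pd.read_csv(path)
    missing = {"name", "mw_kda", "ve_ml"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        SECStandard(str(r["name"]), float(r["mw_kda"]), float(r["ve_ml"]))
        for _, r in df.iterrows()
    ]


def read_sec_samples_csv(path: str | Path) -> list[tuple[str, float, float]]:
    """Read a samples CSV with columns ``name, ve_ml, monomer_mw_kda``."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"name", "ve_ml", "monomer_mw_kda"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        (str(r["name"]), float(r["ve_ml"]), float(r["monomer_mw_kda"]))
        for _, r in df.iterrows()
    ]
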