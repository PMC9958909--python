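"""Expression-construct bookkeeping and theoretical masses.

Expression constructs keep the full-length (UniProt) residue numbering of
their parent protein.  Cloning artifacts — e.g. the Gly-Ala-Met scar left
by a TEV cleavage site — are modelled as an artificial N-terminal prefix
whose residues are numbered consecutively so that the first native residue
keeps its full-length number (a "GAM" prefix before native residue 21 is
numbered 18, 19, 20).

Masses are *average* (isotope-abundance-weighted) masses of the unmodified
chain with free termini and reduced cysteines, i.e. the "theoretical"
molecular weight quoted for an unlabelled construct.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AlphabetError, BoundsError, NumberingError

#: Average residue masses (Da) for chain-internal residues; add one water
#: for the free N/C termini of an intact chain.
RESIDUE_AVERAGE_DA = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_DA = 18.01528


@dataclass(frozen=True)
class ProteinConstruct:
    parent_id: str
    native_start: int
    native_end: int
    prefix: str
    sequence: str  # prefix + native span

    @property
    def prefix_numbers(self) -> list[int]:
        return list(range(self.native_start - len(self.prefix), self.native_start))

    @property
    def numbering(self) -> list[int]:
        """Residue numbers of ``sequence``, prefix included."""
        first = self.native_start - len(self.prefix)
        return list(range(first, self.native_end + 1))

    def __len__(self) -> int:
        return len(self.sequence)

    def to_dict(self) -> dict:
        return {
            "parent_id": self.parent_id,
            "native_start": self.native_start,
            "native_end": self.native_end,
            "prefix": self.prefix,
            "sequence": self.sequence,
            "first_number": self.native_start - len(self.prefix),
        }


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    bad = sorted(set(sequence) - set(RESIDUE_AVERAGE_DA))
    if bad:
        raise AlphabetError(f"unknown residue code(s): {', '.join(bad)}")


def assemble_construct(
    full_sequence: str,
    start: int,
    end: int,
    prefix: str = "",
    parent_id: str = "",
) -> ProteinConstruct:
    """Cut ``[start, end]`` (1-based, inclusive) out of a full-length
    sequence and prepend an artificial N-terminal ``prefix``.

    The prefix residues take the numbers immediately preceding ``start``,
    which therefore must leave room for them (prefix length < start).
    """
    if not (1 <= start <= end <= len(full_sequence)):
        raise BoundsError(
            f"range {start}..{end} outside sequence of length {len(full_sequence)}"
        )
    if len(prefix) >= start:
        raise NumberingError(
            f"prefix of {len(prefix)} residues cannot be numbered before "
            f"native start {start}"
        )
    sequence = prefix + full_sequence[start - 1:end]
    _check_sequence(sequence)
    return ProteinConstruct(
        parent_id=parent_id,
        native_start=start,
        native_end=end,
        prefix=prefix,
        sequence=sequence,
    )


def average_mass(sequence: str) -> float:
    """Theoretical average mass of an intact chain, in kDa.

    Sum of residue masses plus one water; full precision is returned,
    display rounding to 2 decimals is left to callers.
    """
    _check_sequence(sequence)
    da = sum(RESIDUE_AVERAGE_DA[c] for c in sequence) + WATER_DA
    return da / 1000.0


def count_non_proline(full_sequence: str, start: int, end: int) -> int:
    """Number of non-proline positions in ``[start, end]`` (1-based)."""
    if not (1 <= start <= end <= len(full_sequence)):
        raise BoundsError(
            f"range {start}..{end} outside sequence of length {len(full_sequence)}"
        )
    return sum(1 for c in full_sequence[start - 1:end] if c != "P")


def oligomer_mass(monomer_mass: float, n: int) -> float:
    """Mass of an n-mer in kDa (no interface chemistry, plain multiple)."""
    if n < 1:
        raise ValueError(f"oligomer count must be >= 1, got {n}")
    return n * monomer_mass
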