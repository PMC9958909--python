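"""Random-coil Cα/Cβ reference shifts.

A secondary chemical shift is only defined relative to a random-coil
reference set.  One published set is bundled; additional tables can be
registered at run time.  Glycine has no Cβ.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RandomCoilTable:
    table_id: str
    citation: str
    ca: dict[str, float] = field(default_factory=dict)  # ppm per one-letter code
    cb: dict[str, float] = field(default_factory=dict)  # no entry for G

    def __post_init__(self) -> None:
        missing = sorted(set("ACDEFGHIKLMNPQRSTVWY") - set(self.ca))
        if missing:
            raise ValueError(f"coil table lacks CA for: {', '.join(missing)}")


#: Random-coil shifts for Xaa in GGXAGG-type peptides, neutral pH, 25 C.
_WISHART_CA = {
    "A": 52.5, "R": 56.0, "N": 52.8, "D": 54.2, "C": 58.2,
    "Q": 56.6, "E": 56.6, "G": 45.1, "H": 55.0, "I": 61.1,
    "L": 55.1, "K": 56.2, "M": 55.4, "F": 57.7, "P": 63.3,
    "S": 58.3, "T": 61.8, "W": 57.5, "Y": 57.9, "V": 62.2,
}
_WISHART_CB = {
    "A": 19.1, "R": 30.9, "N": 37.9, "D": 41.1, "C": 28.0,
    "Q": 29.4, "E": 29.9, "H": 29.0, "I": 38.8,
    "L": 42.4, "K": 33.1, "M": 32.9, "F": 39.6, "P": 31.7,
    "S": 63.8, "T": 69.8, "W": 29.6, "Y": 38.8, "V": 32.9,
}

WISHART_1995 = RandomCoilTable(
    table_id="wishart1995",
    citation=(
        "Wishart, Bigam, Holm, Hodges & Sykes (1995) J. Biomol. NMR 5, "
        "67-81: 1H, 13C and 15N random coil NMR chemical shifts of the "
        "common amino acids"
    ),
    ca=_WISHART_CA,
    cb=_WISHART_CB,
)

_REGISTRY: dict[str, RandomCoilTable] = {WISHART_1995.table_id: WISHART_1995}


def get_table(table_id: str = "wishart1995") -> RandomCoilTable:
    try:
        return _REGISTRY[table_id]
    except KeyError:
        raise KeyError(
            f"unknown random-coil table {table_id!r}; "
            f"available: {sorted(_REGISTRY)}"
        )


def register_table(table: RandomCoilTable) -> None:
    _REGISTRY[table.table_id] = table
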