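import pytest

from nmrdomains.io import Peak, PeakList


@pytest.fixture
def make_peaklist():
    """Factory: PeakList from (residue, type, h, n[, height]) tuples."""

    def _make(rows):
        peaks = []
        for row in rows:
            resnum, restype, h, n = row[:4]
            height = row[4] if len(row) > 4 else None
            peaks.append(Peak(resnum, restype, h, n, height))
        return PeakList(peaks)

    return _make


@pytest.fixture
def dispersed_peaks(make_peaklist):
    """A deterministic, well-dispersed 50-residue amide peak list."""
    rows = []
    for i in range(50):
        rows.append(
            (
                18 + i,
                "ARNDCQEGHILKMFSTWYVA"[i % 20],
                7.0 + 2.5 * ((i * 7) % 50) / 50,
                105.0 + 25.0 * ((i * 13) % 50) / 50,
                1.0,
            )
        )
    return make_peaklist(rows)
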