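import itertools
from pathlib import Path

import numpy as np
import pytest

from sibz.energetics import default_table, encode

#: user-supplied pBR322 plasmid (GenBank J01749); not distributed with the
#: package — plasmid-dependent checks fail with instructions when absent
PBR322_PATH = Path(__file__).parent / "data" / "pBR322.fasta"


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def pbr322():
    """The pBR322 sequence, or a hard failure explaining how to supply it."""
    if not PBR322_PATH.exists():
        pytest.fail(
            "requires the user-supplied pBR322 sequence (GenBank J01749) at "
            f"{PBR322_PATH}; it is not distributed with this package"
        )
    from sibz.io import read_sequence

    return read_sequence(PBR322_PATH, circular=True)


def brute_min_energy(window: str, table) -> float:
    """Independent oracle: minimum transition energy over every valid label
    vector (one anti and one syn per dinucleotide unit)."""
    codes = encode(window)
    L = len(codes)
    b = codes.astype(int)
    best = np.inf
    for combo in itertools.product(((0, 1), (1, 0)), repeat=L // 2):
        lab = [x for pair in combo for x in pair]
        e = 0.0
        for k in range(L // 2):
            i, j = 2 * k, 2 * k + 1
            e += table.energy_as[b[i], b[j]] if lab[i] == 0 else table.energy_sa[b[i], b[j]]
        for k in range(L // 2 - 1):
            i, j = 2 * k + 1, 2 * k + 2
            if lab[i] == lab[j]:
                e += table.energy_zz[b[i], b[j]]
        best = min(best, e)
    return float(best)
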