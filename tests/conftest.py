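import numpy as np
import pytest

from emkit import Column, Table
from emkit.table import MISSING


@pytest.fixture
def rng():
    return np.random.default_rng(20140)


def random_table(rng, n_rows=100, with_missing=False):
    """Typed random table used by stats/sort/filter tests."""
    cols = [Column("id", "int"), Column("defocus", "float"),
            Column("name", "string")]
    rows = []
    for i in range(n_rows):
        d = float(np.round(rng.uniform(0.5, 4.0), 4))
        if with_missing and rng.random() < 0.15:
            d = MISSING
        rows.append((int(i + 1), d, f"mic_{int(rng.integers(0, 5))}"))
    return Table(cols, rows)
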