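import numpy as np
import pandas as pd
import pytest

from bmpcrep import SimConfig, simulate_repertoire


@pytest.fixture(scope="session")
def small_sim():
    """A 600-cell repertoire with full VDJ coverage for recovery tests."""
    return simulate_repertoire(SimConfig(n_cells=600, seed=11, vdj_dropout=0.0))


@pytest.fixture(scope="session")
def default_sim():
    """A 1,500-cell repertoire at the default generative conditions."""
    return simulate_repertoire(SimConfig(n_cells=1500, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_airr(rows):
    """Build a minimal AIRR-dialect frame from (cell, v, j, cdr3) tuples
    or full dicts."""
    out = []
    for r in rows:
        if isinstance(r, dict):
            d = {"cell_id": "", "v_call": "IGHV1-1*01", "j_call": "IGHJ1*01",
                 "junction_aa": "CARDYW", "sequence": "ATGC",
                 "germline_alignment": "ATGC", "c_call": None}
            d.update(r)
        else:
            cell, v, j, cdr3 = r
            d = {"cell_id": cell, "v_call": v, "j_call": j,
                 "junction_aa": cdr3, "sequence": "ATGC",
                 "germline_alignment": "ATGC", "c_call": None}
        out.append(d)
    return pd.DataFrame(out)
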