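import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from evcargo.nanostring import CountMatrix
from evcargo.ratios import QuantTable, RatioMatrix

settings.register_profile("default", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("default")


def make_ratio_matrix(data: dict[tuple[str, str], dict[str, float]]) -> RatioMatrix:
    """Merged ratio matrix from {(cell_line, fraction): {protein: log2 ratio}}."""
    df = pd.DataFrame(data)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["cell_line", "fraction"])
    return RatioMatrix(df, pd.Series(1, index=df.index))


@pytest.fixture
def toy_quant() -> QuantTable:
    """Two plexes, one cell line each plus references; hand-checkable values."""
    values = pd.DataFrame(
        {
            "A_EV": [5.0, 1.0, 0.0],
            "A_CL": [4.0, np.nan, 0.0],
            "ref1": [3.0, 2.0, np.nan],
            "B_EV": [2.0, 4.0, 5.0],
            "ref2": [1.0, 4.0, 2.0],
        },
        index=pd.Index(["p1", "p2", "p3"], name="protein"),
    )
    design = pd.DataFrame(
        {
            "cell_line": ["A", "A", "pooled_reference", "B", "pooled_reference"],
            "fraction": ["EV", "CL", "REF", "EV", "REF"],
            "plex": ["plex1", "plex1", "plex1", "plex2", "plex2"],
            "is_reference": [False, False, True, False, True],
        },
        index=pd.Index(["A_EV", "A_CL", "ref1", "B_EV", "ref2"], name="channel"),
    )
    return QuantTable(values, design)


@pytest.fixture
def toy_counts() -> CountMatrix:
    """4 endogenous + 3 positive + 3 negative probes, 3 samples of 2 cell lines."""
    probes = pd.Index(
        ["g1", "g2", "g3", "g4", "POS_A", "POS_B", "POS_C", "NEG_1", "NEG_2", "NEG_3"],
        name="probe",
    )
    counts = pd.DataFrame(
        {
            "X_r1": [100, 200, 50, 400, 1000, 250, 60, 4, 6, 8],
            "X_r2": [120, 180, 55, 380, 980, 260, 64, 5, 5, 5],
            "Y_r1": [300, 40, 90, 500, 2000, 500, 120, 10, 12, 8],
        },
        index=probes,
        dtype=int,
    )
    probe_class = pd.Series(
        ["endogenous"] * 4 + ["positive"] * 3 + ["negative"] * 3, index=probes
    )
    samples = pd.DataFrame(
        {"cell_line": ["X", "X", "Y"], "replicate": [1, 2, 1]},
        index=pd.Index(["X_r1", "X_r2", "Y_r1"], name="sample"),
    )
    return CountMatrix(counts, probe_class, samples)
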