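import numpy as np
import pandas as pd
import pytest

from otomir.io import CountMatrix
from otomir.normalize import NormalizedMatrix


def make_count_matrix(counts: dict[str, list[int]], meta: pd.DataFrame | None = None,
                      neg_prefix: str = "ANT") -> CountMatrix:
    """Build a CountMatrix from a {probe: row} mapping; sample ids s1, s2, ..."""
    frame = pd.DataFrame(counts).T
    frame.columns = [f"s{i+1}" for i in range(frame.shape[1])]
    cls = ["negative_control" if p.startswith(neg_prefix) else "miRNA"
           for p in frame.index]
    if meta is None:
        meta = pd.DataFrame(
            {"tissue": ["T"] * frame.shape[1],
             "stage": ["13"] * frame.shape[1],
             "replicate": list(range(1, frame.shape[1] + 1))},
            index=frame.columns,
        )
    return CountMatrix(counts=frame, probe_class=pd.Series(cls, index=frame.index),
                       meta=meta)


def wrap_normalized(values: pd.DataFrame, source: CountMatrix,
                    method: str = "median") -> NormalizedMatrix:
    return NormalizedMatrix(values=values, method=method, source=source)


@pytest.fixture
def toy_counts() -> CountMatrix:
    return make_count_matrix({
        "miR-a": [10, 20, 30, 40],
        "miR-b": [5, 5, 5, 5],
        "ANT-001": [1, 2, 1, 2],
    })


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared across tests (read-only)."""
    from otomir.simulate import SimulationConfig, generate_counts

    cfg = SimulationConfig(seed=7, n_mirna=300)
    return cfg, generate_counts(cfg)
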