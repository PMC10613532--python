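import numpy as np
import pandas as pd
import pytest

from lagnet.panel import PanelDataset
from lagnet.random_networks import random_binary_network  # re-export for tests

__all__ = ["make_panel", "random_binary_network"]


def make_panel(values: dict, unit_ids=None) -> PanelDataset:
    """Panel from {(variable, time): column} mapping."""
    frame = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()})
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["variable", "time"])
    if unit_ids is not None:
        frame.index = pd.Index(unit_ids, name="id")
    return PanelDataset(frame=frame)


@pytest.fixture
def tiny_panel() -> PanelDataset:
    return make_panel(
        {
            ("a", 2015): [0.1, 0.2, 0.3, 0.4],
            ("b", 2015): [1.0, 0.9, 0.8, 0.7],
            ("a", 2016): [0.2, 0.3, 0.4, 0.5],
            ("b", 2016): [0.5, 0.6, 0.7, 0.8],
            ("y", 2017): [0.0, 1.0, 2.0, 3.0],
        },
        unit_ids=["u1", "u2", "u3", "u4"],
    )


@pytest.fixture(scope="session")
def study_panel_small():
    """One modest study-like panel shared by selection/pipeline tests."""
    from lagnet.synthetic import generate_panel, study_like_spec

    return generate_panel(study_like_spec(1200, seed=4))
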