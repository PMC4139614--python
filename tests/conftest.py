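import numpy as np
import pandas as pd
import pytest

import geobirth as gb
from geobirth.survey import Dataset, default_codebook


@pytest.fixture(scope="session")
def drc_graph():
    return gb.default_drc_graph()


@pytest.fixture(scope="session")
def preset_dataset(drc_graph):
    """One paper-scale simulated survey with its ground truth."""
    cfg = gb.default_survey_config(n=7172, seed=101)
    return gb.generate(cfg, drc_graph)


@pytest.fixture()
def tiny_dataset():
    """Six hand-written records over two provinces."""
    df = pd.DataFrame(
        {
            "id": [f"w{i}" for i in range(6)],
            "province": ["KIN", "KIN", "KIN", "SKV", "SKV", "SKV"],
            "age_years": pd.array([15, 24, 25, 30, 49, 18], dtype="Int64"),
            "short_interval": pd.array([1, 0, 0, 1, 1, 0], dtype="Int64"),
            "residence": ["urban", "urban", "rural", "rural", "rural", "urban"],
            "wealth": ["high", "middle", "low", "low", "middle", "high"],
            "education": ["secondary_plus", "primary", "none", "none", "primary", "secondary_plus"],
            "contraception": ["modern", "none", "none", "traditional", "none", "modern"],
            "breastfeeding": ["mixed", "never", "exclusive", "mixed", "exclusive", "never"],
        }
    )
    return Dataset(df, default_codebook())


def path_graph(codes=("A", "B", "C")):
    return gb.AdjacencyGraph.from_edges(codes, [(codes[i], codes[i + 1]) for i in range(len(codes) - 1)])


@pytest.fixture()
def abc_path():
    return path_graph()
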