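"""Shared fixtures: small trees and synthetic tables built at test time."""

import numpy as np
import pandas as pd
import pytest

from trophoguild import core_data, synthetic_data
from trophoguild.core_data import PREY_GROUPS


@pytest.fixture(scope="session")
def small_tree():
    """((A:1,B:1):1,C:2); — 3 tips, patristic d(A,B)=2, d(A,C)=4."""
    return core_data.tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule64():
    """Fixed 64-tip unit-depth Yule tree used across signal/model tests."""
    return synthetic_data.simulate_tree(64, seed=20240)


@pytest.fixture()
def gut_records():
    """Two species, two individuals each, canonical prey groups."""
    rows = [
        ("i1", "spA", "loc1", "Decapoda", 0.6),
        ("i1", "spA", "loc1", "benthic autotroph", 0.4),
        ("i2", "spA", "loc1", "Decapoda", 1.0),
        ("i3", "spB", "loc2", "Actinopterygii", 0.5),
        ("i3", "spB", "loc2", "Decapoda", 0.5),
        ("i4", "spB", "loc2", "Actinopterygii", 1.0),
    ]
    return pd.DataFrame(rows, columns=list(core_data.GUT_RECORD_COLUMNS))


@pytest.fixture(scope="session")
def sharp_profiles():
    """Three well-separated guild profiles over disjoint focal prey."""
    prof = np.full((3, len(PREY_GROUPS)), 0.02 / len(PREY_GROUPS))
    for g in range(3):
        for i in range(g * 3, g * 3 + 3):
            prof[g, i] += 0.98 / 3
    prof = prof / prof.sum(axis=1, keepdims=True)
    return pd.DataFrame(prof, index=[1, 2, 3], columns=list(PREY_GROUPS))
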