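import numpy as np
import pandas as pd
import pytest

from allomod.datatypes import MoleculeRecord, RankedLibrary
from allomod.synthetic_data import gen_molecule_table


@pytest.fixture(scope="session")
def molecule_set():
    """Small deterministic molecule library with poses for triage tests."""

    molecules, poses = gen_molecule_table(60, seed=42, hbond_prob=0.5)
    return molecules, poses


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_library(scores, labels, ids=None) -> RankedLibrary:
    ids = ids if ids is not None else [f"m{i:03d}" for i in range(len(scores))]
    return RankedLibrary(
        frame=pd.DataFrame({"molecule_id": ids, "score": scores, "label": labels})
    )


@pytest.fixture()
def toy_library():
    """5-molecule ranking: actives at ranks 1, 2, 4 (ascending score)."""

    return make_library(
        [-30.0, -25.0, -20.0, -15.0, -10.0],
        ["active", "active", "decoy", "active", "decoy"],
    )
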