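import numpy as np
import pandas as pd
import pytest

from myxopan import PresenceAbsenceMatrix
from myxopan.io import read_newick


@pytest.fixture
def toy_matrix():
    """4 genomes x 6 orthogroups with a known tier structure."""
    data = pd.DataFrame(
        {
            "g1": [1, 1, 1, 0, 1, 0],
            "g2": [1, 1, 0, 1, 0, 0],
            "g3": [1, 1, 1, 0, 0, 0],
            "g4": [1, 0, 1, 1, 0, 1],
        },
        index=[f"og{i}" for i in range(1, 7)],
    ).astype(bool)
    return PresenceAbsenceMatrix(data)


@pytest.fixture
def balanced_tree():
    """8-leaf balanced tree with unit branch lengths (well resolved)."""
    return read_newick("(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
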