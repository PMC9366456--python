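import numpy as np
import pytest

from charsat import synthetic as syn
from charsat.matrix import CharacterMatrix, MISSING, INAPPLICABLE
from charsat.trees import read_annotated_tree, read_changes_tree


TINY_NEXUS = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=3;
FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;
MATRIX
A 01?
B 0{12}-
;
END;
"""


@pytest.fixture
def tiny_nexus(tmp_path):
    p = tmp_path / "tiny.nex"
    p.write_text(TINY_NEXUS)
    return p


@pytest.fixture
def quartet_time_tree():
    return read_annotated_tree(data="((A:3,B:5):4,(C:2,D:6):3);", root_age=10)


@pytest.fixture
def quartet_changes_tree():
    return read_changes_tree(data="((A:1,B:2):3,(C:4,D:5):6);")


def make_matrix(rows, taxa=None, ordered=None):
    """Rows given as lists of ints / sets / MISSING / INAPPLICABLE."""
    taxa = taxa or [f"T{i}" for i in range(len(rows))]
    cells = []
    for row in rows:
        out = []
        for c in row:
            if c is MISSING or c is INAPPLICABLE:
                out.append(c)
            elif isinstance(c, (set, frozenset)):
                out.append(frozenset(c))
            else:
                out.append(frozenset({c}))
        cells.append(out)
    return CharacterMatrix(taxa=taxa, cells=cells, ordered=ordered)


@pytest.fixture(scope="session")
def constrained_dataset():
    """60-tip tree with a k=2 constrained clade against a k=6 background."""
    sc = syn.SyntheticScenario(
        seed=7,
        tree=syn.TreeConfig(n_tips=60),
        characters=syn.CharacterConfig(
            n_chars=300, k_background=6, clade_k={"Reptilia": 2},
            base_rate=0.03, rate_profile="constant"),
        missingness=syn.MissingnessConfig(fraction=0.3),
    )
    tt = syn.simulate_tree(sc)
    groups = syn.assign_clades(tt)
    matrix, changes, truth = syn.simulate_constrained_matrix(tt, sc, tip_groups=groups)
    return dict(scenario=sc, time_tree=tt, groups=groups, matrix=matrix,
                changes_tree=changes, truth=truth)
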