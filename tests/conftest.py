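import numpy as np
import pytest

from grndiff.preprocess import ExpressionMatrix, GroupDesign
from grndiff.priors import PriorMap

# printed out-degree counts of the ten most extreme TFs (GR, PR)
TABLE2_COUNTS = {
    "MXD1": (582, 185),
    "NFYB": (430, 142),
    "E2F6": (621, 212),
    "CREM": (828, 290),
    "RFX2": (590, 209),
    "ID3": (235, 662),
    "HOXA1": (279, 818),
    "JUNB": (268, 823),
    "PROX1": (205, 678),
    "SMAD7": (57, 323),
}

TABLE2_EES = {
    "MXD1": 1.653,
    "NFYB": 1.598,
    "E2F6": 1.551,
    "CREM": 1.514,
    "RFX2": 1.497,
    "ID3": -1.494,
    "HOXA1": -1.552,
    "JUNB": -1.619,
    "PROX1": -1.726,
    "SMAD7": -2.503,
}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """10 genes x 8 samples of positive expression values."""
    genes = tuple(f"g{i}" for i in range(10))
    samples = tuple(f"s{j}" for j in range(8))
    return ExpressionMatrix(genes, samples, rng.gamma(2.0, 2.0, size=(10, 8)))


@pytest.fixture
def toy_prior():
    """2 TFs x 3 target genes."""
    W0 = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
    return PriorMap(("tfA", "tfB"), ("g1", "g2", "g3"), W0)


@pytest.fixture
def toy_expression(rng):
    """Expression covering the toy prior's TFs and targets, 6 samples."""
    genes = ("tfA", "tfB", "g1", "g2", "g3")
    samples = tuple(f"s{j}" for j in range(6))
    return ExpressionMatrix(genes, samples, rng.normal(size=(5, 6)))


@pytest.fixture
def two_group_design():
    return GroupDesign(
        {**{f"a{i}": "GR" for i in range(6)}, **{f"b{i}": "PR" for i in range(5)}}
    )
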