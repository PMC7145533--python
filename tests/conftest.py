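import numpy as np
import pytest

from mtblot.model import ClassifierConfig, DepthProfile, GeneModel, NormalizationFactor


@pytest.fixture
def cfg():
    return ClassifierConfig()


@pytest.fixture
def control_trio():
    """Three control genes with constant depth 40, plus their factor."""
    profiles = {
        g: DepthProfile(g, "rs1", np.full(1800, 40)) for g in ("matR", "nad7", "nad4")
    }
    factor = NormalizationFactor(
        "rs1", {g: 40.0 for g in profiles}, 40.0
    )
    return profiles, factor


def make_profile(gene_id, depths, readset_id="rs1"):
    return DepthProfile(gene_id, readset_id, np.asarray(depths))


def make_factor(value, readset_id="rs1"):
    return NormalizationFactor(readset_id, {"matR": value, "nad7": value, "nad4": value}, value)


@pytest.fixture
def toy_models():
    return [
        GeneModel("matR", "chrM", ((0, 300),), "+", "control", True),
        GeneModel("nad7", "chrM", ((400, 700),), "+", "control", True),
        GeneModel("nad4", "chrM", ((800, 1100),), "+", "control", True),
        GeneModel("rps14", "chrM", ((1200, 1500),), "+", "query", True),
    ]
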