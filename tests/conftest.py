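import hypothesis
import numpy as np
import pytest

from mutnet.simulate import SimConfig, simulate

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("suite")


SMALL_SIM = SimConfig(
    n_genes=300,
    n_samples=12,
    pa_edges_per_node=2,
    module_size=8,
    module_fraction=0.4,
    n_extra_anchors=15,
    master_seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic cohort shared by the slower integration tests."""
    return simulate(SMALL_SIM)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


TOY_MAF = """\
Tumor_Sample_Barcode\tHugo_Symbol\tChromosome\tStart_Position\tVariant_Classification\tSIFT\tPolyPhen2
S1\tTP53\tchr17\t7578406\tMissense_Mutation\t0.01\t
S1\tTTN\tchr2\t179400000\tSilent\t\t
S2\tKRAS\tchr12\t25398284\tFrame_Shift_Del\t\t
"""


@pytest.fixture
def toy_maf(tmp_path):
    path = tmp_path / "toy.maf.tsv"
    path.write_text(TOY_MAF)
    return path
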