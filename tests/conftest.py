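import numpy as np
import pytest

from fsneo.epitopes import MockPredictor
from fsneo.sequence import Transcript
from fsneo.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def mock_predictor():
    return MockPredictor(seed=0, background_size=2000)


@pytest.fixture()
def toy_transcript():
    # ATG + 9 sense codons + stop, with a short flank
    return Transcript(
        "TOY1",
        cds="ATG" + "GAAGCCAAGAATGGCCTGCATAAAGTC" + "TGA",
        gene_symbol="TOYGENE",
        three_prime_flank="CCTTGGAACCTTGGAACC",
    )


@pytest.fixture(scope="session")
def cohort_seed7(tmp_path_factory):
    """Seeded synthetic cohort shared across tests (written once)."""
    outdir = tmp_path_factory.mktemp("cohort7")
    cfg = SimConfig(seed=7, n_patients=100)
    return generate_cohort(cfg, outdir)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
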