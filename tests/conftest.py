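import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from primewindow.editor_model import builtin_profile
from primewindow.synthetic_data import make_genome, plant_sites


@pytest.fixture(scope="session")
def sp():
    return builtin_profile("SpPE")


@pytest.fixture(scope="session")
def fn():
    return builtin_profile("FnPE")


@pytest.fixture(scope="session")
def rha():
    return builtin_profile("RHA-FnPE")


@pytest.fixture()
def rng():
    return np.random.default_rng(20220411)


@pytest.fixture(scope="session")
def toy_contig():
    """30-nt contig with a single plus-strand NGG PAM at 0-based 20..22."""
    return "T" * 20 + "AGG" + "T" * 7


@pytest.fixture(scope="session")
def planted_fn_genome(fn):
    """Small genome with FnPE sites planted on both strands."""
    genome, _ = make_genome(n_contigs=2, lengths=[2000, 1500], gc=0.45, seed=11)
    genome, truth = plant_sites(genome, fn, n_sites=8, min_spacing=60, seed=11)
    return genome, truth


def random_dna(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))
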