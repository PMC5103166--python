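import numpy as np
import pytest

from nirseed import synthetic as syn
from nirseed.io import GeneticMap, SpectraSet, WavenumberGrid


@pytest.fixture(scope="session")
def small_study():
    """120-sample synthetic study shared across read-only tests."""
    refs, conc_truth = syn.simulate_concentrations(120, seed=11)
    spectra, spec_truth = syn.simulate_spectra(refs, seed=12)
    return {"refs": refs, "spectra": spectra, "conc": conc_truth, "truth": spec_truth}


@pytest.fixture
def tiny_grid():
    return WavenumberGrid(np.arange(4000.0, 4000.0 + 8 * 40, 8.0), 8.0)


@pytest.fixture
def tiny_spectra(tiny_grid):
    rng = np.random.default_rng(7)
    a = 0.5 + 0.05 * rng.standard_normal((6, len(tiny_grid)))
    return SpectraSet(tiny_grid, a, [f"S{i}" for i in range(6)])


@pytest.fixture
def two_chrom_map():
    return GeneticMap(
        ["1", "2"],
        {"1": ["m1a", "m1b", "m1c"], "2": ["m2a", "m2b"]},
        {"1": np.array([0.0, 10.0, 30.0]), "2": np.array([0.0, 20.0])},
    )
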