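import numpy as np
import pytest

from rhizoepc import barcode, synth


@pytest.fixture(scope="session")
def small_panel() -> synth.StrainPanel:
    return synth.simulate_panel(n_strains=8, seed=42)


@pytest.fixture(scope="session")
def collision_panel() -> synth.StrainPanel:
    """32 strains, one two-strain collision group (31 distinct alleles)."""
    return synth.simulate_panel(
        n_strains=32, collision_spec={"grp1": ["S01", "S02"]}, seed=7)


@pytest.fixture(scope="session")
def tiny_experiment() -> synth.SyntheticExperiment:
    """Two hosts x two replicates at modest depth, error-free reads."""
    return synth.simulate_experiment(
        hosts=["H1", "H2"], n_replicates=2, n_strains=12, n_collisions=1,
        depth=600, error_rate=0.0, n_genes=6, n_planted=1, seed=5)


@pytest.fixture(scope="session")
def tiny_reference(tiny_experiment) -> barcode.BarcodeReference:
    return barcode.reference_from_panel(tiny_experiment.panel)


def group_truth(panel: synth.StrainPanel, reference: barcode.BarcodeReference,
                mixture: synth.TruthMixture) -> dict[str, float]:
    """True proportion per count-table row label (collision groups summed)."""
    labels = reference.row_labels()
    return {labels[a]: sum(mixture.proportions[s] for s in members)
            for a, members in reference.membership.items()}


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
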