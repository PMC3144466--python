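import numpy as np
import pytest

from plugprot.simulate import (
    ExperimentDesign,
    Protein,
    ProteomeFixture,
    generate_proteome,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def default_fixture() -> ProteomeFixture:
    return generate_proteome(seed=1)


@pytest.fixture(scope="session")
def default_simulation(default_fixture):
    return simulate_experiment(default_fixture, ExperimentDesign(seed=7))


@pytest.fixture(scope="session")
def small_fixture() -> ProteomeFixture:
    """Tiny handcrafted proteome with one shared peptide (GENE_A/GENE_B)."""
    shared = "TTTTTTK"
    proteins = [
        Protein("GENE_A", "male_seminal", "AAAAAAK" + shared + "CCCCCCR"),
        Protein("GENE_B", "male_seminal", "DDDDDDK" + shared + "EEEEEER"),
        Protein("GENE_C", "female", "FFFFFFK" + "GGGGGGR" + "HHHHHHK"),
    ]
    family_map = {"GENE_A": "FAM1", "GENE_B": "FAM1", "GENE_C": "GENE_C"}
    return ProteomeFixture(proteins=proteins, family_map=family_map)


def naive_isotope_expansion(comp, n15_fraction, n_bins):
    """Independent oracle: sequential per-atom polynomial expansion of the
    isotopologue distribution, one atom at a time."""
    from plugprot.constants import ISOTOPES

    dist = np.zeros(n_bins)
    dist[0] = 1.0
    for element, count in comp.as_dict().items():
        isotopes = []
        for shift, _offset, abundance in ISOTOPES[element]:
            if element == "N":
                abundance = (
                    n15_fraction if shift == 1 else 1.0 - n15_fraction
                )
            isotopes.append((shift, abundance))
        for _ in range(count):
            nxt = np.zeros(n_bins)
            for shift, abundance in isotopes:
                if shift == 0:
                    nxt += dist * abundance
                else:
                    nxt[shift:] += dist[:-shift] * abundance
            dist = nxt
    return dist
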