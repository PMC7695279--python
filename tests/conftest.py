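import numpy as np
import pandas as pd
import pytest

from phycodyn.community import OtuTable


@pytest.fixture
def toy_otu_table() -> OtuTable:
    """3 samples x 4 OTUs with full lineages."""
    counts = pd.DataFrame(
        [[50, 30, 20, 0], [10, 60, 20, 10], [0, 0, 80, 20]],
        index=["s1", "s2", "s3"],
        columns=["otu1", "otu2", "otu3", "otu4"],
    )
    lineages = pd.Series(
        {
            "otu1": "k__Bacteria;p__Proteobacteria;c__Gamma;o__Pseudomonadales;f__Pseudomonadaceae;g__Pseudomonas;s__Pseudomonas veronii",
            "otu2": "k__Bacteria;p__Proteobacteria;c__Alpha;o__Rhodobacterales;f__Rhodobacteraceae;g__Rhodobacter;s__Rhodobacter sp",
            "otu3": "k__Bacteria;p__Bacteroidetes;c__Sphingobacteriia;o__Sphingobacteriales;f__Sphingobacteriaceae;g__Pedobacter;s__Pedobacter sp",
            "otu4": "k__Bacteria;p__Cyanobacteria",
        }
    )
    return OtuTable(counts=counts, lineages=lineages, marker="16S")


@pytest.fixture(scope="session")
def small_forcing():
    from phycodyn.simulate import generate_forcing

    return generate_forcing(horizon=60.0, seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def pbr_campaign():
    """A full-length deterministic-forcing PBR simulation, shared across tests."""
    from phycodyn.simulate import generate_forcing, scenario_params, simulate_reactor

    forcing = generate_forcing(seed=7)
    return simulate_reactor(scenario_params("pbr"), forcing)


def random_otu_counts(rng: np.random.Generator, n_samples=4, n_otus=6) -> pd.DataFrame:
    counts = rng.integers(0, 40, size=(n_samples, n_otus))
    # guarantee no all-zero sample
    counts[:, 0] += 1
    return pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"otu{j}" for j in range(n_otus)],
    )
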