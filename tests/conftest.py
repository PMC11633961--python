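import pytest

from gscover import SyntheticConfig, simulate_dataset
from gscover.community import delta_cover, mean_cover_recent, pretreatment_cover
from gscover.phylo import read_newick


@pytest.fixture(scope="session")
def small_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_sites=5, blocks_per_site=2, n_species_pool=40,
        species_per_site=10, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


def species_delta_table(ds):
    """Full chain from a synthetic dataset to the species-level change
    table, using the true genome sizes."""
    pre = pretreatment_cover(ds.cover)
    rec = mean_cover_recent(ds.cover)
    resolved = (
        ds.gs_true.rename("c_value_1C").reset_index()
        .rename(columns={"index": "species"})
    )
    needed = ds.cover[["species", "site"]].drop_duplicates()
    res = needed.merge(resolved, on="species")
    return delta_cover(rec, pre, resolved_gs=res).dropna(subset=["log_gs"])


@pytest.fixture(scope="session")
def small_species_delta(small_dataset):
    return species_delta_table(small_dataset)
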