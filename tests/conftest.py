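import numpy as np
import pandas as pd
import pytest

from nichepart.profile_io import ProfileCollection
from nichepart.synthetic import (
    default_genome_config,
    default_profile_config,
    simulate_genomes,
    simulate_profiles,
)


@pytest.fixture(scope="session")
def small_collection():
    """70 datasets (10 per habitat) x 5 planted taxa."""
    return simulate_profiles(default_profile_config(seed=7))


@pytest.fixture(scope="session")
def genome_sim():
    """Full unbalanced 1930-genome simulation plus its truth record."""
    return simulate_genomes(default_genome_config(seed=7))


@pytest.fixture()
def tiny_collection():
    """Hand-built collection with exactly known counts.

    3 soil + 2 marine + 1 host-associated dataset; taxon A detected in both
    soil datasets S1, S2 and marine M1; taxon B only in the host dataset.
    """
    records = pd.DataFrame(
        {
            "dataset": ["S1", "S2", "M1", "H1"],
            "lineage": [
                "d__Bacteria; p__Acidobacteriota; c__A",
                "d__Bacteria; p__Acidobacteriota; c__A",
                "d__Bacteria; p__Acidobacteriota; c__A",
                "d__Bacteria; p__Acidobacteriota; c__B",
            ],
            "abundance": [10.0, 20.0, 2.0, 5.0],
        }
    )
    habitat_of = pd.Series(
        {
            "S1": "soil",
            "S2": "soil",
            "S3": "soil",
            "M1": "marine",
            "M2": "marine",
            "H1": "host-associated",
        }
    )
    return ProfileCollection(records, habitat_of)


def write_profile_files(tmp_path, records, habitats):
    """Write profile/habitat TSVs for read_profiles tests."""
    ppath = tmp_path / "profiles.tsv"
    hpath = tmp_path / "habitats.tsv"
    pd.DataFrame(records, columns=["dataset", "lineage", "relative_abundance_pct"]).to_csv(
        ppath, sep="\t", index=False
    )
    pd.DataFrame(habitats, columns=["dataset", "habitat"]).to_csv(
        hpath, sep="\t", index=False
    )
    return ppath, hpath
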