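import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hornetdiet.taxonomy import Taxon, Taxonomy


@pytest.fixture(scope="session")
def small_tax() -> Taxonomy:
    """Two families, three genera, five species — enough for every LCA case."""
    return Taxonomy(
        [
            Taxon("root", "root", "root", "root"),
            Taxon("k1", "root", "kingdom", "Animalia"),
            Taxon("o1", "k1", "order", "Diptera"),
            Taxon("fam_calli", "o1", "family", "Calliphoridae"),
            Taxon("fam_musc", "o1", "family", "Muscidae"),
            Taxon("gen_calli", "fam_calli", "genus", "Calliphora"),
            Taxon("gen_luci", "fam_calli", "genus", "Lucilia"),
            Taxon("gen_musca", "fam_musc", "genus", "Musca"),
            Taxon("sp_vicina", "gen_calli", "species", "Calliphora vicina"),
            Taxon("sp_vomit", "gen_calli", "species", "Calliphora vomitoria"),
            Taxon("sp_seric", "gen_luci", "species", "Lucilia sericata"),
            Taxon("sp_dom", "gen_musca", "species", "Musca domestica"),
            Taxon("sp_autum", "gen_musca", "species", "Musca autumnalis"),
        ]
    )


@pytest.fixture(scope="session")
def mini_dataset():
    """A small but complete simulated nest used by several integration tests."""
    from hornetdiet.simulate import SimParams, simulate_nest

    sp = SimParams(
        n_species=8, n_genera=4, n_families=2,
        n_larvae=2, reads_per_larva=150, seed=11,
    )
    return simulate_nest(sp, nest_id="mini")
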