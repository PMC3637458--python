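"""Shared fixtures: the five-taxon worked-example trees and small models."""

import pytest

from rankedcoal import SpeciesTreeModel, parse_ranked_newick


@pytest.fixture(scope="session")
def fig_species_topology():
    """The five-taxon ranked species topology used in the worked examples."""
    return parse_ranked_newick("(((A,B)4,C)2,(D,E)3)1;")


@pytest.fixture(scope="session")
def fig_model(fig_species_topology):
    """The same topology with (arbitrary, strictly decreasing) times."""
    return SpeciesTreeModel(
        fig_species_topology, {1: 4.0, 2: 2.0, 3: 1.7, 4: 1.0}
    )


@pytest.fixture(scope="session")
def gene_rank_swapped():
    """Same unranked shape as the species tree, but the AB and DE
    coalescences are swapped in time (the 'ancient coalescence' case)."""
    return parse_ranked_newick("(((A,B)3,C)2,(D,E)4)1;")


@pytest.fixture(scope="session")
def gene_deep_coalescence():
    """B and C coalesce before A joins: a deep-coalescence (ILS) case."""
    return parse_ranked_newick("((A,(B,C)3)2,(D,E)4)1;")


@pytest.fixture(scope="session")
def gene_matching(fig_species_topology):
    """Gene tree ranked-identical to the species tree."""
    return parse_ranked_newick(fig_species_topology.newick())


@pytest.fixture(scope="session")
def three_taxon_model():
    """((A,B)2,C)1 with internal interval length s_1 - s_2 = 1."""
    return SpeciesTreeModel(parse_ranked_newick("((A,B)2,C)1;"), {1: 2.0, 2: 1.0})
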