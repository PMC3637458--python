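"""Unranked gene tree probabilities by summation over rankings.

The probability of an unranked gene tree topology is the sum of the
probabilities of every ranking of that topology.  Caterpillar-like shapes
have one or few rankings, making this exact summation cheap; balanced
shapes have super-polynomially many, so a hard cap refuses rather than
silently truncating the sum.
"""

from __future__ import annotations

from typing import NamedTuple, Union

from .coalescent_prob import PairAnalysis
from .ranked_trees import (
    RankedTopology,
    RankingCapError,
    UnrankedTopology,
    count_rankings,
    enumerate_rankings,
)
from .species_model import SpeciesTreeModel

__all__ = ["UnrankedResult", "unranked_probability"]


class UnrankedResult(NamedTuple):
    probability: float
    n_rankings: int


def unranked_probability(
    G: Union[UnrankedTopology, RankedTopology],
    T: SpeciesTreeModel,
    cap: int = 10**6,
) -> UnrankedResult:
    """Probability of the unranked topology of ``G`` given ``T``.

    Sums the ranked probability over every ranking (linear extension) of
    the shape of ``G``; ranks on the input, if any, are ignored.  Raises
    :class:`RankingCapError` with the offending count when the number of
    rankings exceeds ``cap``.
    """
    if isinstance(G, RankedTopology):
        G = G.unranked()
    if G.labels != T.labels:
        raise ValueError("gene tree and species tree leaf sets differ")
    total = count_rankings(G)
    if total > cap:
        raise RankingCapError(
            f"topology has {total} rankings, exceeding the cap of {cap}"
        )
    gaps = T.gaps
    prob = 0.0
    count = 0
    for ranking in enumerate_rankings(G, cap=cap):
        prob += PairAnalysis(ranking, T.topology).probability(gaps)
        count += 1
    assert count == total
    return UnrankedResult(probability=min(prob, 1.0), n_rankings=count)
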