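"""Parsimony-style criteria: Minimize Ancient Coalescence (MAC) and MDC.

MAC scores a ranked gene tree against a ranked species tree by the total
number of *extra* lineages per inter-divergence interval,

    sum_{i=1}^{n-1} ( g_i - (i + 1) ),

where ``g_i`` is the minimum number of gene lineages at divergence time
``s_i``.  It is zero exactly when the ranked topologies match, and counts
coalescences forced into more ancient intervals than the species ranking
allows ("ancient coalescence") -- a finer notion than MDC's deep
coalescence, which only reacts to unranked topology mismatch.

MDC is included as the classical comparison baseline: for each internal
edge of the (unranked) species tree it counts the minimal number of gene
lineages exiting that edge, minus one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple, Union

from .coalescent_prob import compute_g
from .ranked_trees import RankedTopology, UnrankedTopology

__all__ = ["mac_cost", "mdc_cost", "mac_rank_species_trees", "MacRanking"]


def mac_cost(G: RankedTopology, T) -> int:
    """Total extra lineages over intervals (the MAC score).

    ``T`` needs only a ranked topology; divergence times are irrelevant.
    Zero iff ``G`` and ``T`` have identical ranked topologies.
    """
    profile = compute_g(G, T)
    n = profile.n
    cost = sum(profile.g[i] - (i + 1) for i in range(1, n))
    assert cost >= 0
    return cost


def _shape(t: Union[RankedTopology, UnrankedTopology]) -> UnrankedTopology:
    return t.unranked() if isinstance(t, RankedTopology) else t


def mdc_cost(G, T) -> int:
    """Classical minimize-deep-coalescence score of ``G`` against ``T``.

    For every internal non-root node of the species tree, the minimal
    number of gene lineages exiting the edge above it equals the number of
    maximal subtrees of the gene tree whose leaves fall within that
    species clade; each lineage beyond the first is an extra (deep)
    coalescence.  Ranks on either input are ignored.
    """
    g = _shape(G)
    s = _shape(T)
    if g.labels != s.labels:
        raise ValueError("gene tree and species tree leaf sets differ")

    def maximal_subtrees_within(clade: frozenset) -> int:
        count = 0
        stack = [g.root]
        while stack:
            nd = stack.pop()
            if nd.clade <= clade:
                count += 1
            elif not nd.is_leaf:
                stack.extend(nd.children)
        return count

    cost = 0
    for nd in s.internal_nodes():
        if nd is s.root:
            continue
        cost += maximal_subtrees_within(nd.clade) - 1
    assert cost >= 0
    return cost


@dataclass(frozen=True)
class MacRanking:
    """Candidates grouped by total weighted MAC score, best first.

    ``groups`` is a list of ``(score, [candidates])``; a group with more
    than one member is a tie, which is reported as such rather than broken
    arbitrarily.
    """

    groups: Tuple[Tuple[float, Tuple[RankedTopology, ...]], ...]

    @property
    def best_score(self) -> float:
        return self.groups[0][0]

    @property
    def best(self) -> Tuple[RankedTopology, ...]:
        """All candidates attaining the best score (>1 entry on a tie)."""
        return self.groups[0][1]

    @property
    def has_tie(self) -> bool:
        return any(len(members) > 1 for _, members in self.groups)


def mac_rank_species_trees(
    observed: Iterable, candidates: Sequence[RankedTopology]
) -> MacRanking:
    """Rank candidate ranked species topologies by total MAC cost.

    ``observed`` is an iterable of ranked gene trees or ``(tree, weight)``
    pairs with weights >= 0 (fractional weights admit posterior-weighted
    gene tree counts).  The score of a candidate is the weight-summed MAC
    cost over the observations.
    """
    obs: List[Tuple[RankedTopology, float]] = []
    for item in observed:
        if isinstance(item, RankedTopology):
            obs.append((item, 1.0))
        else:
            tree, weight = item
            weight = float(weight)
            if weight < 0:
                raise ValueError(f"negative weight {weight}")
            obs.append((tree, weight))
    candidates = list(candidates)
    if not obs:
        raise ValueError("no observed gene trees")
    if not candidates:
        raise ValueError("no candidate species trees")

    scored: List[Tuple[float, RankedTopology]] = []
    for cand in candidates:
        score = sum(w * mac_cost(g, cand) for g, w in obs)
        scored.append((score, cand))
    scored.sort(key=lambda sc: (sc[0], sc[1].newick()))
    groups: List[Tuple[float, Tuple[RankedTopology, ...]]] = []
    for score, cand in scored:
        if groups and groups[-1][0] == score:
            groups[-1] = (score, groups[-1][1] + (cand,))
        else:
            groups.append((score, (cand,)))
    return MacRanking(groups=tuple(groups))
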