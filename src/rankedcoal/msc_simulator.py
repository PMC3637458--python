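"""Multispecies-coalescent simulator of ranked gene trees.

One gene copy is sampled per species.  Backward in time, within every
population of every inter-divergence interval, each pair of lineages
coalesces independently at rate 1 (coalescent units); above the root a
single population holds all remaining lineages until one is left.  The
simulator draws the waiting time to the next event from the total rate
(competing exponentials across populations), picks the population
proportionally to its pair count and the pair uniformly within it.

Besides generating synthetic ranked gene trees, the recorded event traces
reconstruct the per-interval lineage counts, which makes the simulator an
independent Monte-Carlo oracle for the dynamic-programming probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .ranked_trees import Node, RankedTopology
from .species_model import SpeciesTreeModel

__all__ = [
    "SimEvent",
    "SimReplicate",
    "simulate",
    "estimate_distribution",
    "FrequencyTable",
    "random_species_tree",
]


@dataclass(frozen=True)
class SimEvent:
    """One coalescence: interval index, host population, merged pair, time.

    ``interval = 1`` is the (unbounded) interval above the species root.
    """

    interval: int
    population: frozenset
    pair: Tuple[frozenset, frozenset]
    time: float


@dataclass(frozen=True)
class SimReplicate:
    """A simulated ranked gene tree plus its event trace.

    The trace is chronological (increasing time, i.e. most recent event
    first) and suffices to reconstruct the lineage counts ``ell_i``, the
    per-interval event counts ``m_i`` and the per-population counts
    ``k_{i,j,z}``.
    """

    tree: RankedTopology
    events: Tuple[SimEvent, ...]

    def lineage_counts(self) -> Dict[int, int]:
        """``ell_i``: number of gene lineages at each divergence time."""
        n = self.tree.n
        counts = {}
        done = 0
        ev = sorted(self.events, key=lambda e: e.time)
        for i in range(n - 1, 0, -1):
            # events more recent than s_i are those in intervals > i
            done = sum(1 for e in ev if e.interval > i)
            counts[i] = n - done
        return counts


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate(T: SpeciesTreeModel, seed=None) -> SimReplicate:
    """Draw one ranked gene tree from the multispecies coalescent on ``T``.

    ``seed`` may be an integer, a seed sequence, or a ``numpy`` Generator;
    a given integer seed reproduces the replicate exactly.
    """
    rng = _rng(seed)
    n = T.n
    bead = T.bead()
    # current lineages as (clade, build-record) pairs
    cur: List[Tuple[frozenset, tuple]] = [
        (frozenset([l]), ("leaf", l)) for l in sorted(T.labels)
    ]
    events: List[SimEvent] = []
    merges: List[tuple] = []  # chronological records ("node", left, right)
    for i in range(n - 1, 0, -1):
        pops = bead.row(i)
        leaf_to_z = {}
        for z, pop in enumerate(pops):
            for leaf in pop:
                leaf_to_z[leaf] = z
        groups: List[List[Tuple[frozenset, tuple]]] = [[] for _ in range(i)]
        for clade, rec in cur:
            groups[leaf_to_z[next(iter(clade))]].append((clade, rec))
        t = T.time(i)
        t_end = T.time(i - 1)  # inf for i = 1
        while True:
            pair_counts = [len(g) * (len(g) - 1) // 2 for g in groups]
            lam = sum(pair_counts)
            if lam == 0:
                break
            t += rng.exponential(1.0 / lam)
            if t >= t_end:
                break
            # choose the population proportionally to its pair count
            u = rng.random() * lam
            z = 0
            acc = pair_counts[0]
            while u >= acc:
                z += 1
                acc += pair_counts[z]
            g = groups[z]
            a, b = rng.choice(len(g), size=2, replace=False)
            a, b = (a, b) if a < b else (b, a)
            (ca, ra), (cb, rb) = g[a], g[b]
            merged = (ca | cb, ("node", ra, rb))
            g[b:b + 1] = []
            g[a] = merged
            events.append(
                SimEvent(interval=i, population=pops[z], pair=(ca, cb), time=t)
            )
        cur = [lin for g in groups for lin in g]
    assert len(cur) == 1 and len(events) == n - 1

    # chronological event e (0-based, most recent first) created the node
    # of rank n-1-e; clades identify nodes uniquely within one tree.
    clade_rank: Dict[frozenset, int] = {}
    for e, ev in enumerate(events):
        clade_rank[ev.pair[0] | ev.pair[1]] = n - 1 - e

    def to_node(rec: tuple) -> Node:
        if rec[0] == "leaf":
            return Node(label=rec[1])
        left = to_node(rec[1])
        right = to_node(rec[2])
        clade = left.clade | right.clade
        return Node(rank=clade_rank[clade], children=[left, right])

    tree = RankedTopology(to_node(cur[0][1]))
    return SimReplicate(tree=tree, events=tuple(events))


@dataclass(frozen=True)
class FrequencyTable:
    """Observed ranked-topology frequencies with binomial standard errors."""

    counts: Dict[str, int]  # canonical ranked Newick -> count
    N: int

    def count(self, G: Union[RankedTopology, str]) -> int:
        key = G.newick() if isinstance(G, RankedTopology) else G
        return self.counts.get(key, 0)

    def freq(self, G: Union[RankedTopology, str]) -> float:
        return self.count(G) / self.N

    def se(self, G: Union[RankedTopology, str]) -> float:
        f = self.freq(G)
        return math.sqrt(f * (1.0 - f) / self.N)

    def items(self):
        return sorted(self.counts.items(), key=lambda kv: -kv[1])


def estimate_distribution(T: SpeciesTreeModel, N: int, seed=None) -> FrequencyTable:
    """Empirical distribution of ranked gene tree topologies from ``N`` draws.

    Each replicate uses its own RNG stream derived from ``(seed, index)``,
    so results are reproducible and independent of iteration order.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    counts: Dict[str, int] = {}
    for idx in range(N):
        rng = np.random.default_rng([0 if seed is None else seed, idx])
        rep = simulate(T, rng)
        key = rep.tree.newick()
        counts[key] = counts.get(key, 0) + 1
    return FrequencyTable(counts=counts, N=N)


def random_species_tree(
    n: int,
    birth_rate: float = 1.0,
    seed=None,
    labels: Optional[Sequence[str]] = None,
) -> SpeciesTreeModel:
    """Random ranked species tree under a Yule (pure-birth) process.

    The ranked labeled topology is drawn by merging a uniformly random
    pair of lineages at each backward step (Yule and coalescent agree on
    this uniform labeled-history distribution), and inter-divergence gaps
    are exponential: interval ``tau_i`` hosts ``i`` species branches, so
    its length is Exp(i * birth_rate); the most recent divergence time is
    Exp(n * birth_rate).
    """
    if n < 2:
        raise ValueError("need at least 2 species")
    rng = _rng(seed)
    if labels is None:
        labels = [_default_label(idx) for idx in range(n)]
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("label count does not match n")

    lineages: List[Node] = [Node(label=l) for l in labels]
    for rank in range(n - 1, 0, -1):
        a, b = rng.choice(len(lineages), size=2, replace=False)
        a, b = (a, b) if a < b else (b, a)
        merged = Node(rank=rank, children=[lineages[a], lineages[b]])
        lineages[b:b + 1] = []
        lineages[a] = merged
    topology = RankedTopology(lineages[0])

    s = [0.0] * n  # s[i] for i = 1..n-1
    t = rng.exponential(1.0 / (n * birth_rate))
    s[n - 1] = t
    for i in range(n - 1, 1, -1):
        t += rng.exponential(1.0 / (i * birth_rate))
        s[i - 1] = t
    times = {i: s[i] for i in range(1, n)}
    return SpeciesTreeModel(topology, times)


def _default_label(idx: int) -> str:
    # A, B, ..., Z, AA, AB, ...
    out = ""
    idx += 1
    while idx:
        idx, r = divmod(idx - 1, 26)
        out = chr(ord("A") + r) + out
    return out
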