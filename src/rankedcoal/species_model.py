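"""Species trees with divergence times and the beaded population grid.

A species tree on ``n`` species has ``n - 1`` divergence events at times
``s_1 > ... > s_{n-1} > 0`` (time 0 today, increasing into the past, in
coalescent units with a single constant population size).  Interval
``tau_i = [s_i, s_{i-1})`` lies immediately above the divergence of rank
``i``, with the sentinel ``s_0 = +inf`` so that ``tau_1`` is the interval
above the root.

The *beaded* tree inserts degree-one nodes at every divergence time so
that interval row ``i`` holds exactly ``i`` populations, one per species
branch crossing ``tau_i``.  Populations are identified by their species
(leaf-set) content; the numeric index ``z`` follows canonical order
(sorted by smallest leaf label).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

from .ranked_trees import (
    RankedTopology,
    TreeError,
    ranks_from_ultrametric,
)

__all__ = ["SpeciesTreeModel", "BeadedTree", "build_species_tree"]


class SpeciesTimesError(TreeError):
    """Divergence times are not strictly decreasing/positive or disagree
    with the rank order of the topology."""


@dataclass(frozen=True)
class BeadedTree:
    """Population grid of a species tree.

    ``rows[i]`` (``i = 1..n-1``) is the tuple of populations crossing
    interval ``tau_i``, each given by its frozenset of descendant species;
    row ``i`` has exactly ``i`` entries.  ``daughters`` maps a population
    ``(i, z)`` to the indices of its daughter populations in row ``i+1``
    (two daughters for the single splitting population of the row, one
    otherwise).  The leaf row (below ``s_{n-1}``) holds the ``n`` species,
    each carrying the single sampled lineage.
    """

    n: int
    rows: Tuple[Tuple[frozenset, ...], ...]  # rows[i], i = 1..n-1; rows[0] unused
    leaf_row: Tuple[frozenset, ...]
    daughters: Dict[Tuple[int, int], Tuple[int, ...]]

    def row(self, i: int) -> Tuple[frozenset, ...]:
        if not 1 <= i <= self.n - 1:
            raise ValueError(f"interval index {i} out of range 1..{self.n - 1}")
        return self.rows[i]

    def outdeg(self, i: int, z: int) -> int:
        return len(self.daughters[(i, z)])

    def population_index(self, i: int, d: frozenset) -> Optional[int]:
        """Index ``z`` of the row-``i`` population containing leaf set ``d``.

        Returns ``None`` when ``d`` spans multiple populations of the row
        (a value, not an error: such a lineage set cannot exist at that
        time, which callers may legitimately need to detect).
        """
        if not d:
            raise ValueError("empty leaf set")
        for z, pop in enumerate(self.rows[i]):
            if d <= pop:
                return z
        return None


class SpeciesTreeModel:
    """Ranked species topology plus strictly decreasing divergence times.

    Parameters
    ----------
    topology:
        The ranked species topology (rank 1 = root = oldest divergence).
    times:
        Mapping or sequence giving ``s_i`` for ``i = 1..n-1``, strictly
        decreasing and positive, in coalescent units.
    """

    def __init__(self, topology: RankedTopology, times):
        self._topology = topology
        n = topology.n
        if isinstance(times, dict):
            s = [float(times[i]) for i in range(1, n)]
        else:
            s = [float(x) for x in times]
            if len(s) != n - 1:
                raise SpeciesTimesError(
                    f"expected {n - 1} divergence times, got {len(s)}"
                )
        for a, b in zip(s, s[1:]):
            if not a > b:
                raise SpeciesTimesError(
                    f"divergence times must satisfy s_1 > ... > s_{n-1}; "
                    f"got {s}"
                )
        if s and not s[-1] > 0:
            raise SpeciesTimesError("the most recent divergence time must be > 0")
        self._s = s
        self._beaded: Optional[BeadedTree] = None

    # -- basic accessors ---------------------------------------------------

    @property
    def topology(self) -> RankedTopology:
        return self._topology

    @property
    def n(self) -> int:
        return self._topology.n

    @property
    def labels(self) -> frozenset:
        return self._topology.labels

    def time(self, i: int) -> float:
        """Divergence time ``s_i``; ``s_0 = +inf`` by convention."""
        if i == 0:
            return math.inf
        return self._s[i - 1]

    @property
    def times(self) -> Tuple[float, ...]:
        """``(s_1, ..., s_{n-1})``."""
        return tuple(self._s)

    def gap(self, i: int) -> float:
        """Interval length ``s_{i-1} - s_i`` of ``tau_i`` (inf for i=1)."""
        return self.time(i - 1) - self.time(i)

    @property
    def gaps(self) -> Tuple[float, ...]:
        """Finite interval lengths ``(s_1 - s_2, ..., s_{n-2} - s_{n-1})``.

        These are the only quantities, besides the ranked topologies, that
        the ranked gene tree probability depends on.
        """
        return tuple(self._s[i - 1] - self._s[i] for i in range(1, self.n - 1))

    def newick(self) -> str:
        """Ultrametric Newick with branch lengths derived from the times."""

        def fmt(nd, parent_age):
            if nd.is_leaf:
                from .ranked_trees import _quote

                return f"{_quote(nd.label)}:{parent_age:g}"
            age = self.time(nd.rank)
            inner = ",".join(fmt(c, age) for c in nd.children)
            bl = parent_age - age
            return f"({inner}):{bl:g}" if math.isfinite(bl) else f"({inner})"

        root = self._topology.root
        age = self.time(root.rank)
        return "(" + ",".join(fmt(c, age) for c in root.children) + ");"

    def with_times(self, times) -> "SpeciesTreeModel":
        """Same topology, new divergence times."""
        return SpeciesTreeModel(self._topology, times)

    def __repr__(self):
        return (
            f"SpeciesTreeModel({self._topology.newick()!r}, "
            f"times={tuple(round(x, 6) for x in self._s)})"
        )

    # -- beaded tree -------------------------------------------------------

    def bead(self) -> BeadedTree:
        """The population grid (rows of populations per interval)."""
        if self._beaded is None:
            self._beaded = _bead(self)
        return self._beaded

    def population_of(self, i: int, d: frozenset) -> Optional[int]:
        """Row-``i`` population index holding leaf set ``d`` (None if the
        set spans multiple populations)."""
        return self.bead().population_index(i, frozenset(d))


def _bead(model: SpeciesTreeModel) -> BeadedTree:
    top = model.topology
    n = model.n
    rows: list = [()]  # index 0 unused
    for i in range(1, n):
        # Branches crossing tau_i are the species lineages present once the
        # divergences of rank >= i have been undone going back in time.
        row = sorted(top.cut(i), key=min)
        assert len(row) == i
        rows.append(tuple(row))
    leaf_row = tuple(sorted((frozenset([l]) for l in top.labels), key=min))

    daughters: Dict[Tuple[int, int], Tuple[int, ...]] = {}
    for i in range(1, n):
        below = rows[i + 1] if i + 1 <= n - 1 else leaf_row
        index_below = {pop: z for z, pop in enumerate(below)}
        split = 0
        for z, pop in enumerate(rows[i]):
            if pop in index_below:
                daughters[(i, z)] = (index_below[pop],)
            else:
                # This is the splitting population: its node of rank i
                # divides it into the two child clades.
                kids = top.node(i).children
                daughters[(i, z)] = tuple(
                    index_below[c.clade] for c in kids
                )
                split += 1
        assert split == 1, "each beaded row must have exactly one split"
    return BeadedTree(n=n, rows=tuple(rows), leaf_row=leaf_row, daughters=daughters)


def build_species_tree(newick_ultrametric: str, rtol: float = 1e-6) -> SpeciesTreeModel:
    """Build a :class:`SpeciesTreeModel` from ultrametric Newick.

    Node ages are computed from the branch lengths; ranks are assigned by
    decreasing age (the oldest node, the root, gets rank 1).  Tied ages are
    an error: the model assumes almost-surely distinct divergence times.
    """
    topology, times = ranks_from_ultrametric(newick_ultrametric, rtol=rtol)
    if topology.n < 2:
        raise TreeError("a species tree needs at least 2 species")
    return SpeciesTreeModel(topology, times)
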