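"""Ranked tree topologies and their Newick dialects.

A *ranked* topology is a rooted binary leaf-labeled tree whose internal
nodes carry a total temporal order: rank 1 is the most ancient node (the
root) and rank n-1 the most recent, for n leaves.  Ranks discretize the
coalescence order of a gene tree, or the divergence order of a species
tree, without committing to real-valued node times.

The Newick dialect used here writes the rank as a plain integer label on
each internal node, e.g. ``(((A,B)4,C)2,(D,E)3)1;``.  Branch lengths are
permitted on input and ignored.  Ultrametric Newick (with branch lengths,
no rank labels) can be converted via :func:`ranks_from_ultrametric`.
"""

from __future__ import annotations

import itertools
import math
from functools import cached_property
from io import StringIO
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "DuplicateLeafError",
    "NonBinaryError",
    "RankLabelError",
    "RankOrderError",
    "UltrametricError",
    "AgeTieError",
    "RankingCapError",
    "Node",
    "UnrankedTopology",
    "RankedTopology",
    "parse_ranked_newick",
    "parse_unranked_newick",
    "write_ranked_newick",
    "ranks_from_ultrametric",
    "count_rankings",
    "enumerate_rankings",
    "enumerate_all_ranked_topologies",
    "num_ranked_topologies",
]


class TreeError(ValueError):
    """Base class for tree construction/validation errors."""


class NewickParseError(TreeError):
    """The input string is not syntactically valid Newick."""


class DuplicateLeafError(TreeError):
    """Two leaves carry the same label."""


class NonBinaryError(TreeError):
    """A node has a number of children other than 0 or 2."""


class RankLabelError(TreeError):
    """Internal-node rank labels are missing, duplicated or non-contiguous."""


class RankOrderError(TreeError):
    """A node's rank is not smaller than the ranks of its internal children."""


class UltrametricError(TreeError):
    """Root-to-leaf path lengths differ beyond tolerance."""


class AgeTieError(TreeError):
    """Two internal nodes have (numerically) identical ages.

    The coalescent model assumes almost-surely distinct event times, so a
    tie cannot be ranked; callers must perturb or re-estimate node ages.
    """


class RankingCapError(TreeError):
    """The number of rankings of a topology exceeds the configured cap."""


# Characters that force quoting of a label under the Newick standard.
_NEWICK_META = set("()[]{}/\\,;:=*'\"`<> \t\n")


def _quote(label: str) -> str:
    if label and not (_NEWICK_META & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


class Node:
    """A node of an (un)ranked topology.

    Leaves have a ``label`` and no children; internal nodes have exactly two
    children and, on a :class:`RankedTopology`, an integer ``rank``.
    ``clade`` is the frozenset of descendant leaf labels.
    """

    __slots__ = ("label", "rank", "children", "clade", "_min_leaf")

    def __init__(self, label=None, rank=None, children=()):
        self.label = label
        self.rank = rank
        self.children = tuple(children)
        if self.children:
            if len(self.children) != 2:
                raise NonBinaryError(
                    f"internal node has {len(self.children)} children; "
                    "only binary trees are supported"
                )
            self.clade = frozenset().union(*(c.clade for c in self.children))
            self._min_leaf = min(c._min_leaf for c in self.children)
        else:
            self.clade = frozenset([label])
            self._min_leaf = label

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _canonicalize(node: Node) -> Node:
    """Rebuild with children ordered by smallest descendant label."""
    if node.is_leaf:
        return node
    kids = sorted(
        (_canonicalize(c) for c in node.children), key=lambda c: c._min_leaf
    )
    return Node(rank=node.rank, children=kids)


class _TopologyBase:
    """Shared machinery for ranked and unranked topologies."""

    def __init__(self, root: Node):
        self._root = _canonicalize(root)
        labels = []
        self._collect_labels(self._root, labels)
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DuplicateLeafError(f"duplicate leaf label(s): {dupes}")
        self._labels = frozenset(labels)

    @staticmethod
    def _collect_labels(node: Node, out: list) -> None:
        if node.is_leaf:
            out.append(node.label)
        else:
            for c in node.children:
                _TopologyBase._collect_labels(c, out)

    @property
    def root(self) -> Node:
        return self._root

    @property
    def labels(self) -> frozenset:
        """The leaf label set."""
        return self._labels

    @property
    def n(self) -> int:
        """Number of leaves."""
        return len(self._labels)

    def internal_nodes(self) -> Iterator[Node]:
        stack = [self._root]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf:
                yield nd
                stack.extend(nd.children)

    def __eq__(self, other):
        return type(self) is type(other) and self.newick() == other.newick()

    def __hash__(self):
        return hash((type(self).__name__, self.newick()))

    def __repr__(self):
        return f"{type(self).__name__}({self.newick()!r})"


class UnrankedTopology(_TopologyBase):
    """A rooted binary leaf-labeled topology without node order."""

    @cached_property
    def _newick(self) -> str:
        def fmt(nd: Node) -> str:
            if nd.is_leaf:
                return _quote(nd.label)
            return "(" + ",".join(fmt(c) for c in nd.children) + ")"

        return fmt(self._root) + ";"

    def newick(self) -> str:
        """Canonical Newick string (children ordered by smallest label)."""
        return self._newick


class RankedTopology(_TopologyBase):
    """A rooted binary topology with totally ordered internal nodes.

    Ranks are a permutation of ``1..n-1``; every internal node's rank is
    strictly smaller than the ranks of its internal children (older nodes
    have smaller ranks), so the root always has rank 1.
    """

    def __init__(self, root: Node):
        super().__init__(root)
        self._validate_ranks()

    def _validate_ranks(self) -> None:
        n = self.n
        seen = {}
        for nd in self.internal_nodes():
            r = nd.rank
            if not isinstance(r, int):
                raise RankLabelError(
                    f"internal node {set(nd.clade)} has no integer rank label"
                )
            if r in seen:
                raise RankLabelError(f"duplicate rank {r}")
            seen[r] = nd
        if set(seen) != set(range(1, n)):
            raise RankLabelError(
                f"ranks {sorted(seen)} are not a permutation of 1..{n - 1}"
            )
        # temporal consistency: parent rank < child rank
        def check(nd: Node) -> None:
            for c in nd.children:
                if not c.is_leaf:
                    if nd.rank >= c.rank:
                        raise RankOrderError(
                            f"node rank {nd.rank} is not more ancient than "
                            f"child rank {c.rank}"
                        )
                    check(c)

        check(self._root)
        self._by_rank = seen

    @cached_property
    def _newick(self) -> str:
        def fmt(nd: Node) -> str:
            if nd.is_leaf:
                return _quote(nd.label)
            a, b = (fmt(c) for c in nd.children)
            return f"({a},{b}){nd.rank}"

        return fmt(self._root) + ";"

    def newick(self) -> str:
        """Canonical rank-labeled Newick string."""
        return self._newick

    def node(self, rank: int) -> Node:
        """The internal node with the given rank."""
        return self._by_rank[rank]

    def clade(self, rank: int) -> frozenset:
        """Leaf set below the internal node of the given rank."""
        return self._by_rank[rank].clade

    @cached_property
    def _cuts(self) -> list:
        """``_cuts[ell]`` = clades of the lineages present when the most
        recent ``n - ell`` coalescences have occurred (``ell`` lineages)."""
        n = self.n
        cuts: list = [None] * (n + 1)
        cur = {frozenset([l]) for l in self._labels}
        cuts[n] = frozenset(cur)
        for ell in range(n - 1, 0, -1):
            nd = self._by_rank[ell]
            cur -= {c.clade for c in nd.children}
            cur.add(nd.clade)
            cuts[ell] = frozenset(cur)
        return cuts

    def cut(self, ell: int) -> frozenset:
        """Lineages (as leaf-set frozensets) at a cut with ``ell`` lineages.

        Backward in time the nodes with ranks ``n-1, n-2, ...`` merge first;
        with ``ell`` lineages remaining the nodes of ranks ``ell..n-1`` have
        already coalesced.
        """
        if not 1 <= ell <= self.n:
            raise ValueError(f"cut size {ell} out of range 1..{self.n}")
        return self._cuts[ell]

    def lca_rank(self, leafset: frozenset) -> int:
        """Rank of the most recent node whose clade contains ``leafset``.

        For a single leaf this is conventionally ``n`` (the leaf row itself
        is more recent than every internal node) -- callers that place gene
        nodes only ever ask about clades of size >= 2.
        """
        if not leafset <= self._labels:
            raise ValueError("leafset is not a subset of the leaf labels")
        nd = self._root
        best = nd.rank
        while True:
            nxt = None
            for c in nd.children:
                if leafset <= c.clade:
                    nxt = c
                    break
            if nxt is None or nxt.is_leaf:
                return best
            nd = nxt
            best = nd.rank

    def unranked(self) -> UnrankedTopology:
        """Forget the ranks."""

        def strip(nd: Node) -> Node:
            if nd.is_leaf:
                return Node(label=nd.label)
            return Node(children=[strip(c) for c in nd.children])

        return UnrankedTopology(strip(self._root))


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------


def _dendropy_tree(text: str) -> dendropy.Tree:
    if not text.strip():
        raise NewickParseError("empty Newick string")
    if not text.rstrip().endswith(";"):
        text = text.rstrip() + ";"
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "DuplicateTaxon" in type(exc).__name__:
            raise DuplicateLeafError(f"duplicate leaf label: {exc}") from exc
        raise NewickParseError(f"could not parse Newick: {exc}") from exc


def _convert(nd: dendropy.Node, want_ranks: bool) -> Node:
    if nd.is_leaf():
        label = nd.taxon.label if nd.taxon is not None else nd.label
        if label is None:
            raise NewickParseError("leaf without a label")
        return Node(label=str(label))
    children = [_convert(c, want_ranks) for c in nd.child_nodes()]
    rank = None
    if want_ranks:
        if nd.label is None:
            raise RankLabelError(
                "internal node lacks a rank label "
                "(expected an integer internal-node label)"
            )
        try:
            rank = int(str(nd.label))
        except ValueError:
            raise RankLabelError(
                f"internal-node label {nd.label!r} is not an integer rank"
            ) from None
    return Node(rank=rank, children=children)


def parse_ranked_newick(text: str) -> RankedTopology:
    """Parse rank-labeled Newick, e.g. ``(((A,B)4,C)2,(D,E)3)1;``.

    Every internal node must carry an integer label; the labels must form a
    permutation of ``1..n-1`` that decreases toward the root.  Branch
    lengths, if present, are ignored.  The terminating semicolon is
    optional.
    """
    return RankedTopology(_convert(_dendropy_tree(text).seed_node, True))


def parse_unranked_newick(text: str) -> UnrankedTopology:
    """Parse plain Newick, ignoring any internal labels and branch lengths."""
    return UnrankedTopology(_convert(_dendropy_tree(text).seed_node, False))


def write_ranked_newick(t: RankedTopology) -> str:
    """Canonical rank-labeled Newick (inverse of :func:`parse_ranked_newick`)."""
    return t.newick()


def _node_ages(text: str, rtol: float = 1e-6):
    """Parse ultrametric Newick; return (dendropy tree, {node: age})."""
    tree = _dendropy_tree(text)
    depth = {}
    for nd in tree.preorder_node_iter():
        el = nd.edge.length if nd.edge.length is not None else 0.0
        depth[nd] = (depth[nd.parent_node] if nd.parent_node else 0.0) + el
    leaf_depths = [depth[lf] for lf in tree.leaf_node_iter()]
    dmax = max(leaf_depths)
    scale = dmax if dmax > 0 else 1.0
    if dmax - min(leaf_depths) > rtol * scale:
        raise UltrametricError(
            f"tree is not ultrametric: root-to-leaf depths span "
            f"[{min(leaf_depths):g}, {dmax:g}]"
        )
    ages = {
        nd: dmax - depth[nd]
        for nd in tree.preorder_internal_node_iter()
    }
    vals = sorted(ages.values(), reverse=True)
    for a, b in zip(vals, vals[1:]):
        if a - b <= rtol * scale:
            raise AgeTieError(
                f"two internal nodes have indistinguishable ages ({a:g}, {b:g}); "
                "distinct event times are required to rank the tree"
            )
    return tree, ages


def ranks_from_ultrametric(newick_with_lengths: str, rtol: float = 1e-6):
    """Rank an ultrametric tree by node age (oldest node gets rank 1).

    Returns ``(RankedTopology, times)`` where ``times[i]`` is the age of the
    node of rank ``i`` (a dict).  Raises :class:`UltrametricError` if
    root-to-leaf depths disagree beyond relative tolerance and
    :class:`AgeTieError` on tied ages.
    """
    tree, ages = _node_ages(newick_with_lengths, rtol)
    order = sorted(ages, key=ages.get, reverse=True)
    rank_of = {nd: i + 1 for i, nd in enumerate(order)}

    def conv(nd: dendropy.Node) -> Node:
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            return Node(label=str(label))
        return Node(
            rank=rank_of[nd], children=[conv(c) for c in nd.child_nodes()]
        )

    ranked = RankedTopology(conv(tree.seed_node))
    times = {rank_of[nd]: ages[nd] for nd in ages}
    return ranked, times


# ---------------------------------------------------------------------------
# Ranking combinatorics
# ---------------------------------------------------------------------------


def count_rankings(t) -> int:
    """Number of rankings (linear extensions) of a binary topology.

    Equals ``(n-1)! / prod_i (c_i - 1)`` over internal nodes ``i`` with
    ``c_i`` descendant leaves; exact integer arithmetic.  Accepts a ranked
    or unranked topology (ranks are ignored).
    """
    n = t.n
    num = math.factorial(n - 1)
    den = 1
    for nd in t.internal_nodes():
        den *= len(nd.clade) - 1
    q, r = divmod(num, den)
    assert r == 0, "ranking count is not an integer (invalid topology?)"
    return q


def enumerate_rankings(t, cap: int = 10**6) -> Iterator[RankedTopology]:
    """Yield every ranking of a binary topology as a :class:`RankedTopology`.

    The rankings are exactly the linear extensions of the ancestry partial
    order on internal nodes.  Refuses (with :class:`RankingCapError`) when
    :func:`count_rankings` exceeds ``cap``; the default cap reflects that
    balanced shapes have super-polynomially many rankings.
    """
    total = count_rankings(t)
    if total > cap:
        raise RankingCapError(
            f"topology has {total} rankings, exceeding the cap of {cap}"
        )

    internal = [nd for nd in t.internal_nodes()]
    children_of = {
        id(nd): [c for c in nd.children if not c.is_leaf] for nd in internal
    }
    root = t.root

    def extend(assigned: dict, available: list) -> Iterator[dict]:
        if not available:
            yield dict(assigned)
            return
        rank = len(assigned) + 1
        for idx, nd in enumerate(available):
            assigned[id(nd)] = rank
            nxt = available[:idx] + available[idx + 1 :] + children_of[id(nd)]
            yield from extend(assigned, nxt)
            del assigned[id(nd)]

    def rebuild(nd: Node, ranks: dict) -> Node:
        if nd.is_leaf:
            return Node(label=nd.label)
        return Node(
            rank=ranks[id(nd)], children=[rebuild(c, ranks) for c in nd.children]
        )

    for ranks in extend({}, [root] if not root.is_leaf else []):
        yield RankedTopology(rebuild(root, ranks))


def num_ranked_topologies(n: int) -> int:
    """Number of ranked labeled topologies on n leaves: n!(n-1)!/2^(n-1).

    This is the number of labeled histories of n lineages.
    """
    return math.factorial(n) * math.factorial(n - 1) // 2 ** (n - 1)


def enumerate_all_ranked_topologies(
    labels: Iterable[str], max_n: int = 7
) -> Iterator[RankedTopology]:
    """Yield all distinct ranked labeled topologies on the given leaf set.

    Each ranked topology corresponds bijectively to a sequence of pairwise
    merges of the leaf lineages (a labeled history), so enumeration walks
    every merge sequence.  Guarded at ``n <= max_n`` (default 7: 56 700
    topologies) because the count ``n!(n-1)!/2^(n-1)`` explodes.
    """
    labels = sorted(set(labels))
    n = len(labels)
    if not 2 <= n <= max_n:
        raise ValueError(
            f"enumeration supported for 2 <= n <= {max_n}; got n={n}"
        )

    def merge_all(lineages: list, next_rank: int) -> Iterator[Node]:
        if len(lineages) == 1:
            yield lineages[0]
            return
        for i, j in itertools.combinations(range(len(lineages)), 2):
            merged = Node(rank=next_rank, children=[lineages[i], lineages[j]])
            rest = [
                lineages[k] for k in range(len(lineages)) if k not in (i, j)
            ]
            yield from merge_all(rest + [merged], next_rank - 1)

    leaves = [Node(label=l) for l in labels]
    for root in merge_all(leaves, n - 1):
        yield RankedTopology(root)
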