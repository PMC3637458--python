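"""Probability of a ranked gene tree topology given a species tree.

The probability is assembled from three pieces, traversing the species
tree's inter-divergence intervals backward in time:

* a per-interval transition probability -- the chance that exactly the
  required coalescences happen within the interval, in the order dictated
  by the gene tree's ranks.  With ``lambda_j`` the total pairwise
  coalescence rate after the ``j``-th event of the interval (forward in
  time), this is the alternating-sign exponential mixture

      sum_j exp(-lambda_j * D) / prod_{k != j} (lambda_k - lambda_j),

  the hypoexponential CDF/density evaluated at the interval length ``D``;

* a dynamic program over ``(interval, lineage count)`` states.  Because a
  ranked gene tree fixes the order of coalescences, the lineage count in
  an interval determines the ancestral configuration uniquely, so the
  state space is polynomial (overall cost O(n^5));

* a root correction: the coalescences above the root must additionally
  occur in the gene tree's order, which for ``k`` entering lineages has
  probability ``1 / H_k`` with ``H_k = k!(k-1)!/2^(k-1)`` the number of
  labeled histories of ``k`` lineages.

Everything here operates on :class:`~rankedcoal.ranked_trees.RankedTopology`
and :class:`~rankedcoal.species_model.SpeciesTreeModel` instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .ranked_trees import RankedTopology
from .species_model import SpeciesTreeModel

__all__ = [
    "H",
    "EmbeddingProfile",
    "compute_g",
    "LineageSchedule",
    "compute_k",
    "compute_lambda",
    "interval_prob",
    "ProbabilityTable",
    "dp_recursion",
    "ranked_probability",
    "ranked_log_probability",
    "PairAnalysis",
]


def H(k: int) -> int:
    """Number of labeled histories of ``k`` lineages: ``k!(k-1)!/2^(k-1)``.

    Under the coalescent every labeled history is equally likely, so the
    probability that ``k`` lineages coalesce above the species-tree root in
    one prescribed order is ``1 / H(k)``.
    """
    if k < 1:
        raise ValueError(f"H(k) requires k >= 1, got {k}")
    return math.factorial(k) * math.factorial(k - 1) // 2 ** (k - 1)


def _species_topology(T) -> RankedTopology:
    if isinstance(T, SpeciesTreeModel):
        return T.topology
    if isinstance(T, RankedTopology):
        return T
    raise TypeError(
        "expected a SpeciesTreeModel or RankedTopology, got "
        f"{type(T).__name__}"
    )


# ---------------------------------------------------------------------------
# Minimum lineage counts g_i
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbeddingProfile:
    """How a ranked gene tree fits into a ranked species tree.

    ``g[i]`` (``i = 1..n-1``) is the minimum number of gene lineages at
    divergence time ``s_i`` compatible with the gene tree's ranking;
    ``lca_rank[r]`` is the rank of the most recent species node whose clade
    contains the gene node of rank ``r``.  The gene node of rank ``r`` can
    coalesce in species interval ``tau_j`` only if ``j <= lca_rank[r]``.
    """

    n: int
    g: Tuple[int, ...]  # g[0] unused; g[i] for i = 1..n-1
    lca_rank: Tuple[int, ...]  # lca_rank[0] unused; index by gene rank

    def min_lineages(self, i: int) -> int:
        return self.g[i]


def compute_g(G: RankedTopology, T) -> EmbeddingProfile:
    """Minimum gene lineage counts at each species divergence time.

    A gene node may sit more recently than ``s_i`` only if its species-side
    least common ancestor does; ``g_i`` counts how many of the most recent
    gene nodes can all be pushed below ``s_i``:

        g_i = n - #{ j > i : every gene node of rank >= j has
                            lca more recent than s_i }

    ``T`` may be a :class:`SpeciesTreeModel` or a bare ranked topology.
    """
    top = _species_topology(T)
    if G.labels != top.labels:
        raise ValueError(
            f"gene tree leaves {sorted(G.labels)} != species tree leaves "
            f"{sorted(top.labels)}"
        )
    n = G.n
    lca = [0] * n  # lca[r] for r = 1..n-1
    for r in range(1, n):
        lca[r] = top.lca_rank(G.clade(r))
    # M[j] = min lca rank over gene nodes of rank >= j
    M = [0] * (n + 1)
    M[n] = n + 1  # empty suffix
    for j in range(n - 1, 0, -1):
        M[j] = min(M[j + 1], lca[j])
    g = [0] * n
    for i in range(1, n):
        count = sum(1 for j in range(i + 1, n) if M[j] > i)
        g[i] = n - count
        assert i < g[i] <= n
    return EmbeddingProfile(n=n, g=tuple(g), lca_rank=tuple(lca))


# ---------------------------------------------------------------------------
# Per-interval lineage bookkeeping: k_{i,j,z} and rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineageSchedule:
    """Lineage counts for one DP transition through interval ``tau_i``.

    ``k[j][z]`` is the number of gene lineages in population ``z`` of the
    interval's row just after the ``j``-th coalescence, counted forward in
    time (``j = 0`` is the top of the interval, ``j = m`` the bottom, with
    ``m = ell_in - ell_out`` events inside).  ``rates[j]`` is the total
    coalescence rate ``sum_z C(k[j][z], 2)``.
    """

    i: int
    ell_in: int  # lineages entering at the bottom, at time s_i
    ell_out: int  # lineages exiting at the top, at time s_{i-1}
    populations: Tuple[frozenset, ...]
    k: Tuple[Tuple[int, ...], ...]  # (m+1) rows of length i
    rates: Tuple[int, ...]

    @property
    def m(self) -> int:
        return self.ell_in - self.ell_out


def _pop_index_map(populations) -> Dict[str, int]:
    leaf_to_z = {}
    for z, pop in enumerate(populations):
        for leaf in pop:
            leaf_to_z[leaf] = z
    return leaf_to_z


def compute_k(
    G: RankedTopology, T, i: int, ell_in: int, ell_out: int
) -> LineageSchedule:
    """Lineage counts ``k_{i,j,z}`` for one interval transition.

    The gene nodes of ranks ``ell_out .. ell_in - 1`` are the ``m``
    coalescences placed in ``tau_i``.  Bottom counts come from cutting the
    gene tree at ``ell_in`` lineages and assigning each lineage to the
    population of the beaded row containing its leaves; walking the events
    backward (in forward-time order) removes one lineage from the hosting
    population at each step.
    """
    top = _species_topology(T)
    profile = compute_g(G, top)
    n = G.n
    if not 2 <= i <= n - 1:
        raise ValueError(f"interval index {i} out of range 2..{n - 1}")
    if not profile.g[i] <= ell_in <= n:
        raise ValueError(
            f"ell_in={ell_in} outside [g_{i}={profile.g[i]}, {n}]"
        )
    if not profile.g[i - 1] <= ell_out <= ell_in:
        raise ValueError(
            f"ell_out={ell_out} outside [g_{i-1}={profile.g[i - 1]}, "
            f"ell_in={ell_in}]"
        )
    if isinstance(T, SpeciesTreeModel):
        populations = T.bead().row(i)
    else:
        populations = tuple(sorted(top.cut(i), key=min))
    leaf_to_z = _pop_index_map(populations)

    m = ell_in - ell_out
    bottom = [0] * i
    for lineage in G.cut(ell_in):
        z = leaf_to_z[next(iter(lineage))]
        if not lineage <= populations[z]:
            raise AssertionError(
                f"lineage {set(lineage)} spans multiple populations of "
                f"interval {i}: inconsistent preconditions"
            )
        bottom[z] += 1
    rows = [None] * (m + 1)
    rows[m] = tuple(bottom)
    cur = list(bottom)
    # Forward-time event j+1 (j = m-1 .. 0) is the gene node of rank
    # ell_out + j; undoing it removes one lineage from its population.
    for j in range(m - 1, -1, -1):
        clade = G.clade(ell_out + j)
        z = leaf_to_z[next(iter(clade))]
        if not clade <= populations[z]:
            raise AssertionError(
                f"coalescence {set(clade)} spans multiple populations of "
                f"interval {i}: inconsistent preconditions"
            )
        cur[z] -= 1
        assert cur[z] >= 1, "population emptied below its exiting lineage"
        rows[j] = tuple(cur)
    rates = tuple(
        sum(kz * (kz - 1) // 2 for kz in row) for row in rows
    )
    sched = LineageSchedule(
        i=i,
        ell_in=ell_in,
        ell_out=ell_out,
        populations=tuple(populations),
        k=tuple(rows),
        rates=rates,
    )
    compute_lambda(sched)  # asserts strict increase
    return sched


def compute_lambda(schedule: LineageSchedule) -> Tuple[int, ...]:
    """Total coalescence rates ``lambda_{i,j} = sum_z C(k_{i,j,z}, 2)``.

    The rates must strictly increase with ``j`` (each forward-time
    coalescence adds a lineage to a population that already holds one);
    violation indicates an internal inconsistency and raises.
    """
    rates = schedule.rates
    for a, b in zip(rates, rates[1:]):
        if not a < b:
            raise AssertionError(
                f"coalescence rates not strictly increasing: {rates}"
            )
    return rates


# ---------------------------------------------------------------------------
# Hypoexponential interval probability
# ---------------------------------------------------------------------------

_LD_EPS = float(np.finfo(np.longdouble).eps)
_REL_TOL = 1e-11  # internal accuracy demanded before a fast path is trusted


def _direct(rates: Sequence[int], delta: float):
    """Partial-fraction form in extended precision, with an error monitor.

    Denominators are exact integers; the alternating sum cancels badly when
    ``delta`` is small relative to the rate spread, so the estimated
    rounding error is checked against the result before it is trusted.
    """
    m = len(rates) - 1
    lam = np.array(rates, dtype=np.longdouble)
    terms = np.empty(m + 1, dtype=np.longdouble)
    for j in range(m + 1):
        den = 1
        rj = rates[j]
        for k in range(m + 1):
            if k != j:
                den *= rates[k] - rj
        terms[j] = np.exp(np.longdouble(-rates[j]) * np.longdouble(delta)) / np.longdouble(den)
    s = float(terms.sum())
    worst = float(np.max(np.abs(terms)))
    if s > 0 and worst * _LD_EPS * (m + 1) <= _REL_TOL * s:
        return min(s, 1.0), True
    return 0.0, False


def _series(rates: Sequence[int], delta: float):
    """Taylor expansion of the divided difference of ``exp(-lambda*delta)``.

    After shifting out the smallest rate, the value is
    ``exp(-lambda_0 D) * D^m/m! * S`` with
    ``S = sum_q (-1)^q h_q(mu*D) * m!/(m+q)!`` and ``h_q`` the complete
    homogeneous symmetric polynomials (via Newton's identities on power
    sums).  Accurate when ``D * (lambda_m - lambda_0)`` is small.
    """
    m = len(rates) - 1
    mu = [(r - rates[0]) * delta for r in rates]
    # power sums p_k of the scaled shifted rates, grown on demand
    p: List[float] = [0.0]
    h: List[float] = [1.0]
    S = 1.0
    fac = 1.0  # m!/(m+q)!
    worst = 1.0
    q = 0
    while q < 400:
        q += 1
        p.append(sum(x**q for x in mu))
        hq = sum(p[k] * h[q - k] for k in range(1, q + 1)) / q
        h.append(hq)
        fac /= m + q
        term = (-1) ** q * hq * fac
        S += term
        worst = max(worst, abs(term))
        if abs(term) <= 1e-18 * abs(S) and q >= 2:
            break
    if S > 0 and worst * 1e-16 * (q + 1) <= _REL_TOL * S:
        logv = (
            -rates[0] * delta
            + m * math.log(delta)
            - math.lgamma(m + 1)
            + math.log(S)
        )
        return math.exp(logv) if logv > -745.0 else 0.0, True
    return 0.0, False


def _uniformization(rates: Sequence[int], delta: float) -> float:
    """Exactly ordered coalescences as a pure-death chain, uniformized.

    States ``m, m-1, ..., 0`` with exit rate ``lambda_j`` from state ``j``
    (state 0 leaks onward at ``lambda_0``, which would contradict the
    required exit count, so only mass *sitting* in state 0 at time ``delta``
    counts).  All summands are positive, so this path is slow but free of
    cancellation; it backs up the fast paths when their error monitors
    trip.  The chain uses total rates, so the result is divided by
    ``prod_{j>=1} lambda_j`` to recover the single-pair event probability.
    """
    m = len(rates) - 1
    theta = float(rates[-1])
    x = theta * delta
    a = np.array(rates, dtype=float) / theta  # jump probabilities
    stay = 1.0 - a
    v = np.zeros(m + 1)
    v[m] = 1.0
    nsteps = int(x + 12.0 * math.sqrt(x) + 30.0)
    ps = np.arange(nsteps + 1, dtype=float)
    logw = -x + ps * math.log(x) - gammaln(ps + 1.0)
    w = np.exp(logw)
    acc = 0.0
    cw = 0.0
    for pstep in range(nsteps + 1):
        acc += w[pstep] * v[0]
        cw += w[pstep]
        if cw > 1.0 - 1e-17 and pstep > x:
            break
        prev = v
        v = prev * stay
        v[:m] += prev[1:] * a[1:]
    q = acc
    denom = 1
    for r in rates[1:]:
        denom *= r
    return min(q / float(denom), 1.0)


def interval_prob(rates: Sequence[int], delta: float) -> float:
    """Probability of the prescribed coalescence sequence in one interval.

    ``rates`` are the strictly increasing total coalescence rates
    ``lambda_{i,0} < ... < lambda_{i,m}`` (integers: sums of binomial
    coefficients ``C(k,2)``); ``delta`` is the interval length
    ``s_{i-1} - s_i``.  For ``m = 0`` this reduces to ``exp(-lambda_0 *
    delta)``; for ``delta = inf`` it converges to ``1 / prod_{j>=1}
    lambda_j`` when ``lambda_0 = 0`` and to 0 otherwise.

    Evaluation tries the partial-fraction form, then a Taylor form for
    small ``delta``, each guarded by a rounding-error monitor, and falls
    back to a cancellation-free uniformization of the underlying Markov
    chain, keeping the relative error around 1e-11 across the full
    parameter range met in likelihood optimization.
    """
    rates = [int(r) for r in rates]
    if not rates:
        raise ValueError("need at least one rate")
    for a, b in zip(rates, rates[1:]):
        if a == b:
            raise ValueError(f"repeated coalescence rate {a}: invalid schedule")
        if a > b:
            raise ValueError(f"rates must be strictly increasing, got {rates}")
    if rates[0] < 0:
        raise ValueError("rates must be non-negative")
    m = len(rates) - 1
    if math.isinf(delta):
        if m == 0:
            return 1.0 if rates[0] == 0 else 0.0
        if rates[0] != 0:
            return 0.0
        denom = 1
        for r in rates[1:]:
            denom *= r
        return 1.0 / denom
    if not delta > 0:
        raise ValueError(f"interval length must be positive, got {delta}")
    if m == 0:
        return math.exp(-rates[0] * delta)
    val, ok = _direct(rates, delta)
    if ok:
        return val
    if delta * (rates[-1] - rates[0]) <= 2.0:
        val, ok = _series(rates, delta)
        if ok:
            return val
    return _uniformization(rates, delta)


# ---------------------------------------------------------------------------
# The dynamic program
# ---------------------------------------------------------------------------


class PairAnalysis:
    """Time-independent structure of a (gene tree, species topology) pair.

    Precomputes the embedding profile and, for every interval row, the
    total coalescence rate as a function of the lineage count, so that the
    probability can be re-evaluated cheaply for many divergence-time
    vectors (as likelihood optimization requires).  The rate tables exist
    because cutting a ranked gene tree at ``c`` lineages yields a unique
    set of lineages -- the ranking pins down the ancestral configuration.
    """

    def __init__(self, G: RankedTopology, T):
        top = _species_topology(T)
        self.gene = G
        self.species_topology = top
        self.profile = compute_g(G, top)
        self.n = G.n
        n = self.n
        g = self.profile.g
        # lam[i][c]: total rate in row i with the cut-c gene lineages,
        # for i = 2..n-1 and c = g_{i-1}..n.
        self._lam: Dict[int, Dict[int, int]] = {}
        for i in range(2, n):
            pops = tuple(sorted(top.cut(i), key=min))
            leaf_to_z = _pop_index_map(pops)
            counts = [0] * i
            for pop_z, pop in enumerate(pops):
                counts[pop_z] = len(pop)
            lam_row: Dict[int, int] = {}
            rate = sum(c * (c - 1) // 2 for c in counts)
            lam_row[n] = rate
            for c in range(n - 1, g[i - 1] - 1, -1):
                z = leaf_to_z[next(iter(G.clade(c)))]
                kz = counts[z]
                rate += -(kz * (kz - 1) // 2) + (kz - 1) * (kz - 2) // 2
                counts[z] = kz - 1
                lam_row[c] = rate
            self._lam[i] = lam_row

    def rate(self, i: int, c: int) -> int:
        """Total coalescence rate in row ``i`` with ``c`` gene lineages."""
        return self._lam[i][c]

    def conditional(self, i: int, ell_out: int, ell_in: int, delta: float) -> float:
        """P[ell_out lineages exit tau_i | ell_in enter], interval length delta."""
        rates = [self._lam[i][c] for c in range(ell_out, ell_in + 1)]
        for a, b in zip(rates, rates[1:]):
            if not a < b:
                raise AssertionError(
                    f"rates not strictly increasing in interval {i}: {rates}"
                )
        return interval_prob(rates, delta)

    def table(self, gaps: Sequence[float]) -> "ProbabilityTable":
        """Run the DP for interval lengths ``gaps = (s_1-s_2, ..., s_{n-2}-s_{n-1})``."""
        n = self.n
        g = self.profile.g
        if len(gaps) != max(n - 2, 0):
            raise ValueError(f"expected {n - 2} interval lengths, got {len(gaps)}")
        entries: Dict[Tuple[int, int], float] = {(n - 1, n): 1.0}
        for i in range(n - 2, 0, -1):
            delta = gaps[i - 1]  # length of tau_{i+1} = s_i - s_{i+1}
            for ell in range(g[i], n + 1):
                total = 0.0
                for ell_next in range(max(ell, g[i + 1]), n + 1):
                    total += self.conditional(i + 1, ell, ell_next, delta) * entries[
                        (i + 1, ell_next)
                    ]
                entries[(i, ell)] = total
        prob = sum(entries[(1, ell)] / H(ell) for ell in range(g[1], n + 1))
        return ProbabilityTable(
            n=n, g=g, entries=entries, probability=min(prob, 1.0)
        )

    def probability(self, gaps: Sequence[float]) -> float:
        return self.table(gaps).probability


@dataclass(frozen=True)
class ProbabilityTable:
    """DP values ``P[G_{i,ell} | T]`` and the final ranked probability."""

    n: int
    g: Tuple[int, ...]
    entries: Dict[Tuple[int, int], float]
    probability: float

    def __post_init__(self):
        for key, val in self.entries.items():
            assert -1e-12 <= val <= 1 + 1e-12, f"P{key} = {val} outside [0,1]"

    def P(self, i: int, ell: int) -> float:
        """``P[G_{i,ell} | T]`` (0 for ``ell < g_i``, by convention)."""
        if ell < self.g[i]:
            return 0.0
        return self.entries[(i, ell)]

    @property
    def log_probability(self) -> float:
        if self.probability <= 0.0:
            return -math.inf
        return math.log(self.probability)


def dp_recursion(
    G: RankedTopology, T: SpeciesTreeModel, profile: Optional[EmbeddingProfile] = None
) -> ProbabilityTable:
    """Fill the DP table over ``(interval, lineage count)`` states.

    Traverses intervals from the most recent (``P[G_{n-1,n}|T] = 1``:
    all ``n`` sampled lineages are distinct at the most recent divergence)
    back to the root interval, combining per-interval transition
    probabilities; states with fewer than ``g_i`` lineages have probability
    zero and are never stored.
    """
    analysis = PairAnalysis(G, T)
    if profile is not None and profile != analysis.profile:
        raise ValueError("supplied profile does not match the tree pair")
    return analysis.table(T.gaps)


def ranked_probability(G: RankedTopology, T: SpeciesTreeModel) -> float:
    """P[G | T]: probability of the ranked gene tree topology ``G``.

    Orchestrates the full computation: embedding profile, per-interval
    rate schedules, hypoexponential transition probabilities, the DP over
    intervals, and the labeled-history correction ``1/H`` for coalescences
    above the root.  Always strictly positive: any ranked topology can be
    realized by pushing all coalescences above the root.
    """
    return dp_recursion(G, T).probability


def ranked_log_probability(G: RankedTopology, T: SpeciesTreeModel) -> float:
    """``log P[G | T]`` (−inf only on numerical underflow below ~1e-300)."""
    return dp_recursion(G, T).log_probability
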