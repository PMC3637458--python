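"""Maximum-likelihood species trees from collections of ranked gene trees.

With ``n_i`` the (possibly fractional, posterior-weighted) number of times
ranked topology ``G^(i)`` was observed among ``N`` loci, the likelihood of
a species tree ``T`` is multinomial,

    P[G_1, ..., G_N | T] = prod_i P[G^(i) | T]^{n_i},

maximized here over the internal interval lengths of a fixed ranked
species topology (:func:`fit_times`) and, for small ``n``, over all ranked
species topologies exhaustively (:func:`ml_species_tree`).

The likelihood is invariant to shifting all divergence times and to the
value of the most recent time ``s_{n-1}`` (with one sample per species no
coalescence can happen below it), so fitted trees are anchored at
``s_{n-1} = 1`` and only the ``n - 2`` gaps ``d_i = s_{i-1} - s_i`` are
free, log-parametrized to stay positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize

from .coalescent_prob import PairAnalysis
from .ranked_trees import (
    RankedTopology,
    enumerate_all_ranked_topologies,
    parse_ranked_newick,
)
from .species_model import SpeciesTreeModel

__all__ = [
    "ObservedRankedSample",
    "log_likelihood",
    "fit_times",
    "FitResult",
    "ml_species_tree",
    "MLResult",
]


class ObservedRankedSample:
    """Distinct ranked gene tree topologies with nonnegative counts.

    Duplicate topologies (under canonical form) are merged by summing
    counts; fractional counts admit posterior-weighted observations.
    """

    def __init__(self, items: Iterable):
        merged: Dict[str, Tuple[RankedTopology, float]] = {}
        labels = None
        for item in items:
            if isinstance(item, RankedTopology):
                tree, cnt = item, 1.0
            else:
                tree, cnt = item
                cnt = float(cnt)
            if cnt < 0:
                raise ValueError(f"negative count {cnt}")
            if labels is None:
                labels = tree.labels
            elif tree.labels != labels:
                raise ValueError("observed gene trees have differing leaf sets")
            key = tree.newick()
            if key in merged:
                merged[key] = (merged[key][0], merged[key][1] + cnt)
            else:
                merged[key] = (tree, cnt)
        if not merged:
            raise ValueError("empty sample")
        self._items = tuple(merged.values())
        self._labels = labels

    @classmethod
    def from_newick_lines(cls, lines: Iterable[str]) -> "ObservedRankedSample":
        """Parse 'ranked-newick[<TAB>weight]' lines (blank/# lines skipped)."""
        items = []
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                tree = parse_ranked_newick(parts[0])
                weight = float(parts[1]) if len(parts) > 1 else 1.0
            except Exception as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            items.append((tree, weight))
        return cls(items)

    @property
    def labels(self) -> frozenset:
        return self._labels

    @property
    def n(self) -> int:
        return len(self._labels)

    @property
    def N(self) -> float:
        """Total (weighted) number of observations."""
        return sum(c for _, c in self._items)

    def items(self) -> Tuple[Tuple[RankedTopology, float], ...]:
        return self._items

    def __len__(self) -> int:
        return len(self._items)


def _as_sample(sample) -> ObservedRankedSample:
    if isinstance(sample, ObservedRankedSample):
        return sample
    return ObservedRankedSample(sample)


def log_likelihood(sample, T: SpeciesTreeModel) -> float:
    """``sum_i n_i log P[G^(i) | T]`` (multinomial constant omitted)."""
    sample = _as_sample(sample)
    if sample.labels != T.labels:
        raise ValueError("sample and species tree leaf sets differ")
    gaps = T.gaps
    total = 0.0
    for tree, cnt in sample.items():
        p = PairAnalysis(tree, T.topology).probability(gaps)
        if p <= 0.0:
            return -math.inf  # numerical underflow at extreme times
        total += cnt * math.log(p)
    return total


@dataclass(frozen=True)
class FitResult:
    """Fitted divergence times for a fixed ranked species topology."""

    model: SpeciesTreeModel
    log_likelihood: float
    gaps: Tuple[float, ...]
    converged: bool
    n_starts: int

    @property
    def topology(self) -> RankedTopology:
        return self.model.topology


def _times_from_gaps(n: int, gaps: Sequence[float]) -> Dict[int, float]:
    """Anchor s_{n-1} = 1 and stack the gaps (gaps[j] = s_{j+1} - s_{j+2})."""
    s = {n - 1: 1.0}
    for i in range(n - 2, 0, -1):
        s[i] = s[i + 1] + gaps[i - 1]
    return s


def fit_times(
    sample,
    topology: RankedTopology,
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> FitResult:
    """Maximize the likelihood over the internal interval lengths.

    Multi-start Nelder-Mead over the log-gaps (derivative-free: the
    objective is smooth but its gradient is not available in closed form).
    Starts are one unit-gap point plus seeded log-uniform perturbations.
    Reports the best optimum found; ``converged=False`` flags that no
    start terminated within tolerance, with the best value still returned.
    """
    sample = _as_sample(sample)
    n = topology.n
    if n < 3:
        raise ValueError(
            "fit_times requires n >= 3 (for n = 2 the likelihood is flat)"
        )
    if sample.labels != topology.labels:
        raise ValueError("sample and topology leaf sets differ")
    analyses = [
        (PairAnalysis(tree, topology), cnt) for tree, cnt in sample.items()
    ]
    ndim = n - 2

    def nll(x: np.ndarray) -> float:
        gaps = np.exp(np.clip(x, -35.0, 35.0))
        total = 0.0
        for analysis, cnt in analyses:
            p = analysis.probability(gaps)
            if p <= 0.0:
                return math.inf
            total -= cnt * math.log(p)
        return total

    rng = np.random.default_rng(seed)
    starts = [np.zeros(ndim)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(-1.5, 1.5, size=ndim))

    best = None
    converged = False
    for x0 in starts:
        res = minimize(
            nll,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": tol,
                "fatol": tol,
                "maxiter": max_iter * ndim,
                "maxfev": max_iter * ndim,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    gaps = tuple(float(g) for g in np.exp(np.clip(best.x, -35.0, 35.0)))
    model = SpeciesTreeModel(topology, _times_from_gaps(n, gaps))
    return FitResult(
        model=model,
        log_likelihood=-float(best.fun),
        gaps=gaps,
        converged=converged,
        n_starts=len(starts),
    )


@dataclass(frozen=True)
class MLResult:
    """Exhaustive ML species tree search over ranked topologies."""

    best: FitResult
    table: Tuple[FitResult, ...]  # all candidates, best first

    @property
    def topology(self) -> RankedTopology:
        return self.best.topology

    @property
    def model(self) -> SpeciesTreeModel:
        return self.best.model


def ml_species_tree(
    sample,
    max_n: int = 6,
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
) -> MLResult:
    """Maximum-likelihood ranked species tree by exhaustive enumeration.

    Fits divergence times for every ranked species topology on the sample's
    leaf set and returns the argmax with the full score table.  Guarded at
    ``n <= max_n`` (default 6) since the candidate count grows as
    ``n!(n-1)!/2^(n-1)``.  Note the ML ranked topology need not be the most
    frequent ranked gene tree topology in the sample.
    """
    sample = _as_sample(sample)
    n = sample.n
    if n > max_n:
        raise ValueError(
            f"exhaustive search supported only for n <= {max_n}; got n={n}"
        )
    if n < 3:
        raise ValueError("species-tree inference requires n >= 3")
    fits: List[FitResult] = []
    for k, cand in enumerate(enumerate_all_ranked_topologies(sample.labels)):
        fits.append(
            fit_times(
                sample, cand, n_starts=n_starts, seed=seed + 1000 * k, tol=tol
            )
        )
    fits.sort(key=lambda f: -f.log_likelihood)
    return MLResult(best=fits[0], table=tuple(fits))
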