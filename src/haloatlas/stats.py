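"""Enrichment and comparison statistics used across the pipeline.

Three tools recur throughout the atlas analysis: the hypergeometric test for
feature enrichment within a gene set, the Mann-Whitney U test for comparing
continuous features (half-lives, CAI, GC content, knockout fold changes)
between gene groups, and the multi-set intersection test that asks whether
the overlap of several gene sets exceeds what independent draws from a
common universe would give.

The default significance convention is a raw p-value below 0.05;
Benjamini-Hochberg adjustment is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class HypergeomResult:
    """Upper-tail hypergeometric enrichment of a feature in a query set.

    N genes in the universe, K of them feature-positive; a query set of n
    genes contains k feature-positive members. ``p_upper`` is
    P(X >= k) for X ~ Hypergeom(N, K, n).
    """

    N: int
    K: int
    n: int
    k: int
    p_upper: float

    @property
    def expected(self) -> float:
        return self.K * self.n / self.N

    @property
    def fold(self) -> float:
        return self.k / self.expected if self.expected > 0 else float("nan")


@dataclass(frozen=True)
class MsetResult:
    """Multi-set intersection enrichment over a common universe."""

    set_sizes: tuple[int, ...]
    N: int
    observed: int
    expected: float
    fold: float
    p: float
    seed: int | None = None  # recorded for Monte-Carlo p-values


def hypergeom_enrichment(k: int, K: int, n: int, N: int) -> HypergeomResult:
    """Exact upper-tail hypergeometric test P(X >= k).

    Parameters follow the sampling-without-replacement convention: the
    universe holds ``N`` genes of which ``K`` carry the feature; the query
    set holds ``n`` genes of which ``k`` carry it.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid bounds: K={K}, n={n} must lie in [0, N={N}]")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"observed overlap k={k} outside [0, min(K={K}, n={n})]")
    # sf(k-1) = P(X >= k); scipy evaluates the pmf in log space internally
    p_upper = float(sps.hypergeom.sf(k - 1, N, K, n))
    return HypergeomResult(N=N, K=K, n=n, k=k, p_upper=min(p_upper, 1.0))


def mset_test(
    sets: Sequence[Iterable],
    N: int,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> MsetResult:
    """Test whether the common intersection of gene sets is larger than
    expected for independent draws from a universe of size ``N``.

    Expected intersection size is N * prod(|s_i| / N). For two sets the
    p-value is the exact upper-tail hypergeometric probability; for more
    sets it is estimated by Monte-Carlo resampling of uniform random subsets
    of the observed sizes (the seed is recorded in the result).
    """
    frozen = [frozenset(s) for s in sets]
    if len(frozen) < 2:
        raise ValueError("need at least two sets")
    sizes = tuple(len(s) for s in frozen)
    if max(sizes) > N:
        raise ValueError(f"universe N={N} smaller than the largest set ({max(sizes)})")
    observed = len(frozenset.intersection(*frozen))
    expected = N * float(np.prod([s / N for s in sizes]))
    fold = observed / expected if expected > 0 else float("nan")
    if len(frozen) == 2:
        p = hypergeom_enrichment(observed, sizes[0], sizes[1], N).p_upper
        return MsetResult(sizes, N, observed, expected, fold, p, seed=None)
    rng = np.random.default_rng(seed)
    hits = 0
    universe = np.arange(N)
    for _ in range(n_mc):
        draws = [frozenset(rng.choice(universe, size=s, replace=False)) for s in sizes]
        if len(frozenset.intersection(*draws)) >= observed:
            hits += 1
    # add-one correction keeps the Monte-Carlo p strictly positive
    p = (hits + 1) / (n_mc + 1)
    return MsetResult(sizes, N, observed, expected, fold, p, seed=seed)


def _exact_mwu_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact Mann-Whitney p by complete enumeration of group labelings.

    Enumerates every way of assigning the pooled observations to the two
    groups and compares the resulting U statistics; valid with ties.
    Feasible for the small per-side sample sizes it is used for.
    """
    pooled = np.concatenate([x, y])
    n_x = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
    n_total = len(pooled)
    mean_u = n_x * (n_total - n_x) / 2
    count = 0
    total = 0
    for idx in combinations(range(n_total), n_x):
        u = ranks[list(idx)].sum() - n_x * (n_x + 1) / 2
        total += 1
        if alternative == "two-sided":
            if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
                count += 1
        elif alternative == "less":
            if u <= u_obs + 1e-12:
                count += 1
        else:  # greater
            if u >= u_obs - 1e-12:
                count += 1
    return count / total


def mannwhitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Mann-Whitney U test comparing the distributions of two samples.

    Returns ``(U, p)`` where U counts, over all (x_i, y_j) pairs, the cases
    with x_i > y_j (ties counting one half). For samples of at most
    ``exact_max_n`` per side the p-value is exact (complete enumeration of
    labelings, valid under ties); larger samples use the tie-corrected
    normal approximation with continuity correction. Two identical constant
    samples give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2)
    if np.all(pooled == pooled[0]):
        return u_x, 1.0
    if x.size <= exact_max_n and y.size <= exact_max_n:
        p = _exact_mwu_p(x, y, alternative)
    else:
        _, p = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        p = float(p)
    return u_x, min(p, 1.0)


def feature_enrichment_report(
    gene_set: Iterable,
    flag_table: pd.DataFrame,
    universe: Iterable,
    adjust: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every binary feature column in a gene set.

    ``flag_table`` is indexed by gene id with boolean/0-1 feature columns;
    genes of the universe absent from the table count as feature-negative.
    Returns one row per feature with N, K, n, k, expected, fold and p
    (optionally Benjamini-Hochberg adjusted in an extra column).
    """
    genes = frozenset(gene_set)
    universe = frozenset(universe)
    if not genes:
        raise ValueError("empty gene set")
    if not genes <= universe:
        raise ValueError("gene set is not contained in the universe")
    N, n = len(universe), len(genes)
    rows = []
    table = flag_table.reindex(universe).fillna(False)
    for feature in flag_table.columns:
        positives = frozenset(table.index[table[feature].astype(bool)])
        K = len(positives)
        k = len(positives & genes)
        res = hypergeom_enrichment(k, K, n, N)
        rows.append(
            {
                "feature": feature,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "expected": res.expected,
                "fold": res.fold,
                "p": res.p_upper,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    if adjust:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
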