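"""Community ecology statistics: Bray-Curtis, Mantel, PERMANOVA, rank tests, nMDS.

Distances live in :class:`skbio.DistanceMatrix` objects. The permutation
tests are written here in full (observed statistic, explicit null by
permutation, p = (b + 1) / (n_perm + 1)) and switch to exact enumeration
of the permutation group whenever it is small enough, so that tiny
designs give exact p-values. Kruskal-Wallis and the pairwise Wilcoxon
rank-sum tests delegate to scipy, with Holm correction by default.

Environmental (Euclidean) distances standardize each covariate to zero
mean and unit variance first, and handle missing covariate values by
pairwise-complete deletion: each sample pair is compared over the
covariates observed in both, rescaled to the full covariate count.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .quantify import NormalizedMatrix
from .seqio import CountMatrix, SampleMetadata

logger = logging.getLogger(__name__)

EXACT_ENUMERATION_LIMIT = 5040  # 7!


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str  # "exact" or "permutation"

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def bray_curtis(matrix: CountMatrix | NormalizedMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples: sum|x-y| / sum(x+y) over genes.

    Samples containing missing values (e.g. a zero SCG mean upstream) are
    dropped with a warning; an all-zero sample is an error because its
    dissimilarity to anything is undefined.
    """
    df = matrix.data
    bad = df.columns[df.isna().any(axis=0)]
    if len(bad):
        logger.warning("dropping samples with missing abundances: %s", list(bad))
        df = df.drop(columns=bad)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples with complete abundances")
    x = df.to_numpy(dtype=float).T  # samples x genes
    if (x.sum(axis=1) == 0).any():
        zero = [s for s, tot in zip(df.columns, x.sum(axis=1)) if tot == 0]
        raise ValueError(f"all-zero samples have undefined dissimilarity: {zero}")
    return DistanceMatrix(squareform(pdist(x, metric="braycurtis")),
                          ids=list(df.columns))


def euclidean_env(
    meta: SampleMetadata,
    covariates: list[str] | None = None,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean distance over (standardized) environmental covariates.

    Missing values are handled by pairwise-complete deletion: the squared
    distance of a pair is averaged over covariates observed in both
    samples and rescaled by the total covariate count; the number of
    pairwise-dropped covariate comparisons is logged.
    """
    cov = meta.covariates() if covariates is None else meta.data[covariates].astype(float)
    if cov.shape[1] == 0:
        raise ValueError("no numeric covariates to build distances from")
    z = cov.to_numpy(dtype=float)
    if standardize:
        mu = np.nanmean(z, axis=0)
        sd = np.nanstd(z, axis=0, ddof=0)
        sd[sd == 0] = 1.0
        z = (z - mu) / sd
    n, p = z.shape
    present = ~np.isnan(z)
    d = np.zeros((n, n))
    dropped = 0
    for i, j in itertools.combinations(range(n), 2):
        shared = present[i] & present[j]
        m = int(shared.sum())
        dropped += p - m
        if m == 0:
            raise ValueError(
                f"samples {meta.sample_ids[i]} and {meta.sample_ids[j]} share no "
                "observed covariates"
            )
        sq = np.sum((z[i, shared] - z[j, shared]) ** 2) * (p / m)
        d[i, j] = d[j, i] = math.sqrt(sq)
    if dropped:
        logger.info("pairwise-complete deletion dropped %d covariate comparisons",
                    dropped)
    return DistanceMatrix(d, ids=meta.sample_ids)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    alternative: str = "greater",
    seed: int | None = None,
    method: str = "auto",
) -> PermutationTestResult:
    """Mantel correlation between two distance matrices.

    The statistic is the Pearson correlation of the upper-triangle
    vectors; the null permutes rows and columns of ``d2`` simultaneously.
    With ``method="auto"`` all n! permutations are enumerated when n! is
    small (exact p = proportion of permutations at least as extreme,
    identity included); otherwise ``n_perm`` random permutations give
    p = (b + 1) / (n_perm + 1). One-sided ("greater") by default;
    ``alternative="two-sided"`` compares absolute correlations.
    """
    if sorted(d1.ids) != sorted(d2.ids):
        raise ValueError("distance matrices cover different sample sets")
    d2 = d2.filter(d1.ids)
    n = d1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a, b_mat = d1.data, d2.data
    x = _upper(a)

    def corr(perm: np.ndarray) -> float:
        y = _upper(b_mat[np.ix_(perm, perm)])
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(np.arange(n))

    def extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs
        if alternative == "less":
            return r_perm <= r_obs
        return abs(r_perm) >= abs(r_obs)

    if method == "auto":
        method = "exact" if math.factorial(n) <= min(EXACT_ENUMERATION_LIMIT,
                                                     n_perm + 1) else "permutation"
    if method == "exact":
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        b = sum(extreme(corr(p)) for p in perms)
        return PermutationTestResult(statistic=r_obs, p_value=b / len(perms),
                                     n_permutations=len(perms), seed=seed,
                                     method="exact")
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        b += extreme(corr(rng.permutation(n)))
    return PermutationTestResult(statistic=r_obs, p_value=(b + 1) / (n_perm + 1),
                                 n_permutations=n_perm, seed=seed,
                                 method="permutation")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _multiset_permutations(items: list):
    """Distinct permutations of a multiset, lexicographic."""
    items = sorted(items)
    n = len(items)
    while True:
        yield tuple(items)
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1:] = reversed(items[i + 1:])


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's pseudo-F from squared dissimilarities.

    SS_total = sum_{i<j} d2_ij / n; SS_within = sum over groups of the
    within-group pair sums / group size; F = (SS_between / (a - 1)) /
    (SS_within / (n - a)).
    """
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    a = len(groups)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "auto",
) -> PermutationTestResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    The null permutes group labels across samples. With ``method="auto"``
    every distinct label arrangement is enumerated when few enough
    (exact p, identity arrangement included); otherwise random label
    permutations give p = (b + 1) / (n_perm + 1).
    """
    labels = np.asarray(pd.Series(grouping).reindex(d.ids)
                        if isinstance(grouping, (pd.Series, dict))
                        else grouping)
    if len(labels) != d.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2]
        raise ValueError(f"groups of size 1 are not testable: {list(small)}")
    d2 = d.data ** 2
    f_obs = _pseudo_f(d2, labels, groups)

    n_distinct = math.factorial(len(labels))
    for c in counts:
        n_distinct //= math.factorial(int(c))
    if method == "auto":
        method = "exact" if n_distinct <= min(EXACT_ENUMERATION_LIMIT,
                                              n_perm + 1) else "permutation"
    if method == "exact":
        b = 0
        total = 0
        for arrangement in _multiset_permutations(list(labels)):
            total += 1
            b += _pseudo_f(d2, np.asarray(arrangement), groups) >= f_obs
        return PermutationTestResult(statistic=f_obs, p_value=b / total,
                                     n_permutations=total, seed=seed,
                                     method="exact")
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        b += _pseudo_f(d2, rng.permutation(labels), groups) >= f_obs
    return PermutationTestResult(statistic=f_obs, p_value=(b + 1) / (n_perm + 1),
                                 n_permutations=n_perm, seed=seed,
                                 method="permutation")


def permanova_covariates(
    d: DistanceMatrix,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Distance-based regression PERMANOVA for continuous covariates.

    McArdle-Anderson formulation: the Gower-centered matrix G of the
    squared dissimilarities is projected on the hat matrix of the
    covariate design (intercept added); pseudo-F = (tr(HGH)/m) /
    (tr((I-H)G(I-H))/(n-m-1)); the null permutes the rows/columns of G.
    """
    X = covariates.reindex(d.ids).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("covariate matrix contains missing values")
    n, m = X.shape
    A = -0.5 * d.data ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    X1 = np.column_stack([np.ones(n), X])
    H = X1 @ np.linalg.pinv(X1)

    def f_stat(g: np.ndarray) -> float:
        num = np.trace(H @ g @ H) / m
        resid = (np.eye(n) - H)
        return float(num / (np.trace(resid @ g @ resid) / (n - m - 1)))

    f_obs = f_stat(G)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        b += f_stat(G[np.ix_(p, p)]) >= f_obs
    return PermutationTestResult(statistic=f_obs, p_value=(b + 1) / (n_perm + 1),
                                 n_permutations=n_perm, seed=seed,
                                 method="permutation")


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    Identical values across all groups return (0, 1) rather than erroring.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    samples = [values[groups == g] for g in uniq]
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def pairwise_wilcoxon(values, groups, correction: str = "holm") -> pd.DataFrame:
    """Post-hoc pairwise Wilcoxon rank-sum tests with multiplicity correction.

    Returns a symmetric DataFrame of corrected p-values (diagonal NaN).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(np.unique(groups))
    pairs = list(itertools.combinations(uniq, 2))
    raw = []
    for g1, g2 in pairs:
        _, p = stats.mannwhitneyu(values[groups == g1], values[groups == g2],
                                  alternative="two-sided")
        raw.append(p)
    corrected = multipletests(raw, method=correction)[1] if raw else []
    out = pd.DataFrame(np.nan, index=uniq, columns=uniq)
    for (g1, g2), p in zip(pairs, corrected):
        out.loc[g1, g2] = out.loc[g2, g1] = p
    return out


# ---------------------------------------------------------------------------
# Nonmetric multidimensional scaling
# ---------------------------------------------------------------------------


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float              # Kruskal stress-1 of the best start
    stress_history: list[float]
    n_starts: int
    seed: int | None


def _nmds_single(delta: np.ndarray, n: int, k: int, x0: np.ndarray,
                 max_iter: int, tol: float) -> tuple[np.ndarray, float, list[float]]:
    iso = IsotonicRegression(increasing=True)
    x = x0.copy()
    history: list[float] = []
    for _ in range(max_iter):
        dist = pdist(x)
        dhat = iso.fit_transform(delta, dist)
        # keep the disparities on the configuration's scale
        s = math.sqrt((dist ** 2).sum() / max((dhat ** 2).sum(), 1e-300))
        dhat = dhat * s
        stress = math.sqrt(((dist - dhat) ** 2).sum() / (dist ** 2).sum())
        history.append(stress)
        if len(history) > 1 and history[-2] - history[-1] < tol:
            break
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        x = B @ x / n
    return x, history[-1], history


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 300,
    seed: int | None = None,
    tol: float = 1e-7,
) -> NMDSResult:
    """Nonmetric MDS minimizing Kruskal stress-1 by iterative majorization.

    Disparities come from monotone (isotonic) regression of configuration
    distances on the input dissimilarities; the configuration is updated
    by the Guttman transform. The first start is the classical-scaling
    (PCoA) configuration, the rest are random; the lowest-stress start
    wins.
    """
    n = d.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples {n}")
    delta = _upper(d.data)
    rng = np.random.default_rng(seed)

    # classical-scaling start
    A = -0.5 * d.data ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    vals, vecs = np.linalg.eigh(G)
    idx = np.argsort(vals)[::-1][:k]
    pcoa = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))

    best: tuple[np.ndarray, float, list[float]] | None = None
    for start in range(max(1, n_starts)):
        x0 = pcoa if start == 0 else rng.standard_normal((n, k))
        result = _nmds_single(delta, n, k,
                              x0=np.asarray(x0, dtype=float), max_iter=max_iter,
                              tol=tol)
        if best is None or result[1] < best[1]:
            best = result
    x, stress, history = best
    coords = pd.DataFrame(x, index=list(d.ids),
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return NMDSResult(coordinates=coords, stress=stress, stress_history=history,
                      n_starts=max(1, n_starts), seed=seed)
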