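"""Group comparisons of size and shape among orientation classes.

Centroid sizes are compared by classical one-way ANOVA. Shape (tangent-
space) comparisons use canonical variate analysis and permutation tests
with two complementary statistics: Goodall's F, the ratio of between-group
to within-group mean squared Procrustes distances, and Pillai's trace, the
MANOVA statistic trace(H (H + E)^-1). Shape components obtained from the
object-symmetry decomposition are rank-deficient by construction, so the
multivariate statistics are computed on the principal subspace in which
the relevant scatter matrix has non-negligible eigenvalues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedShapeSample",
    "anova_centroid_size",
    "ANOVAResult",
    "goodall_f",
    "pillai_trace",
    "permutation_test",
    "PermutationTestResult",
    "cva",
    "CVAResult",
    "group_mean_shapes",
    "GroupMeans",
    "mean_confidence_ellipse",
]


@dataclass
class GroupedShapeSample:
    """Shape vectors labeled by a grouping factor.

    Parameters
    ----------
    data : (n, d) ndarray
        Tangent-space shape vectors, one row per organ.
    labels : (n,) array-like
        Group label per organ (e.g. compass or relative orientation
        sector).
    component : str
        Tag for bookkeeping: ``"symmetric"``, ``"asymmetric"`` or other.
    flower_ids : (n,) array-like, optional
        Flower each organ belongs to; required for flower-level
        permutation.
    """

    data: np.ndarray
    labels: np.ndarray
    component: str = ""
    flower_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n, d) matrix")
        if len(self.labels) != len(self.data):
            raise ValueError("labels length must match number of rows of data")
        if self.flower_ids is not None:
            self.flower_ids = np.asarray(self.flower_ids)
            if len(self.flower_ids) != len(self.data):
                raise ValueError("flower_ids length must match data")
        groups, counts = np.unique(self.labels, return_counts=True)
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        if (counts >= 2).sum() < 2:
            raise ValueError("need at least 2 groups with >= 2 members")

    @property
    def n(self) -> int:
        return len(self.data)

    def with_labels(self, labels: np.ndarray) -> "GroupedShapeSample":
        out = object.__new__(GroupedShapeSample)
        out.data = self.data
        out.labels = labels
        out.component = self.component
        out.flower_ids = self.flower_ids
        return out


def _group_decomposition(data: np.ndarray, labels: np.ndarray):
    """Group codes, counts, group means and grand mean."""
    groups, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    sums = np.zeros((len(groups), data.shape[1]))
    np.add.at(sums, codes, data)
    means = sums / counts[:, None]
    grand = data.mean(axis=0)
    return groups, codes, counts, means, grand


# ---------------------------------------------------------------------------
# ANOVA on centroid size


@dataclass
class ANOVAResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    table: pd.DataFrame  # group, n, mean, se


def anova_centroid_size(sizes, groups) -> ANOVAResult:
    """Classical one-way ANOVA of centroid size across orientation groups.

    Returns the F statistic with its degrees of freedom, the p-value, and
    a per-group table of sample size, mean and standard error (the layout
    used to report organ sizes per orientation sector).
    """
    sizes = np.asarray(sizes, dtype=float)
    labels = np.asarray(groups)
    levels, codes, counts, means, grand = _group_decomposition(
        sizes[:, None], labels
    )
    if len(levels) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if (counts < 1).any():
        raise ValueError("every group must have at least 1 member")
    n, g = len(sizes), len(levels)
    df_between, df_within = g - 1, n - g
    if df_within < 1:
        raise ValueError("no residual degrees of freedom")

    ssw = float(((sizes - means[codes, 0]) ** 2).sum())
    if ssw == 0.0:
        warnings.warn(
            "zero within-group variance: ANOVA F is infinite", RuntimeWarning
        )
        F, p = math.inf, 0.0
    else:
        F, p = stats.f_oneway(*(sizes[codes == i] for i in range(g)))
        F, p = float(F), float(p)

    rows = []
    for i, level in enumerate(levels):
        vals = sizes[codes == i]
        se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
        rows.append({"group": level, "n": len(vals),
                     "mean": float(vals.mean()), "se": se})
    return ANOVAResult(F, df_between, df_within, p, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# multivariate statistics


def _goodall_f(data: np.ndarray, labels: np.ndarray) -> float:
    _, codes, counts, means, grand = _group_decomposition(data, labels)
    g, n = len(counts), len(data)
    ssb = float((counts * ((means - grand) ** 2).sum(axis=1)).sum())
    ssw = float(((data - means[codes]) ** 2).sum())
    if ssw == 0.0:
        warnings.warn(
            "zero within-group dispersion: Goodall's F is infinite",
            RuntimeWarning,
        )
        return math.inf
    return (ssb / (g - 1)) / (ssw / (n - g))


def goodall_f(sample: GroupedShapeSample) -> float:
    """Goodall's F: between- vs within-group mean squared Procrustes distance.

    F = [sum_g n_g ||m_g - m||^2 / (G - 1)] / [sum_gi ||x_gi - m_g||^2 / (N - G)]
    with norms taken in tangent space. Scale-invariant; infinite (with a
    warning) if the within-group dispersion is zero.
    """
    return _goodall_f(sample.data, sample.labels)


def _pillai_trace(data: np.ndarray, labels: np.ndarray, tol: float = 1e-8) -> float:
    _, codes, counts, means, grand = _group_decomposition(data, labels)
    Xc = data - grand
    total = Xc.T @ Xc  # H + E
    evals, evecs = np.linalg.eigh(total)
    if evals[-1] <= 0.0:
        raise ValueError("all observations are identical; Pillai's trace undefined")
    keep = evals > tol * evals[-1]
    V = evecs[:, keep]
    Mc = (means - grand) @ V
    H = (counts[:, None] * Mc).T @ Mc
    T = np.diag(evals[keep])
    return float(np.trace(np.linalg.solve(T, H)))


def pillai_trace(sample: GroupedShapeSample, tol: float = 1e-8) -> float:
    """Pillai's trace, trace(H (H + E)^-1), on the retained-rank subspace.

    H and E are the between- and within-group cross-product matrices. The
    statistic is computed on the principal subspace where the total
    scatter H + E has eigenvalues above ``tol`` times its largest one,
    which keeps it well defined on rank-deficient shape components. Bounded
    by min(G - 1, rank).
    """
    return _pillai_trace(sample.data, sample.labels, tol=tol)


_STATISTICS = {"goodall_f": _goodall_f, "pillai": _pillai_trace}


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationTestResult:
    statistic: str
    observed: float
    p_value: float
    n_permutations: int
    seed: int | None
    unit: str = "organ"
    exhaustive: bool = False
    perm_mean: float = math.nan
    perm_sd: float = math.nan


def _multiset_permutations(items):
    """Yield all distinct permutations of a multiset (lexicographic)."""
    pool = sorted(items)
    n = len(pool)
    while True:
        yield tuple(pool)
        # next lexicographic permutation
        i = n - 2
        while i >= 0 and pool[i] >= pool[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while pool[j] <= pool[i]:
            j -= 1
        pool[i], pool[j] = pool[j], pool[i]
        pool[i + 1:] = pool[i + 1:][::-1]


def _n_distinct_arrangements(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _flower_blocks(flower_ids: np.ndarray) -> dict[int, list[np.ndarray]]:
    """Organ index blocks per flower, grouped by block size."""
    by_size: dict[int, list[np.ndarray]] = {}
    for fid in pd.unique(flower_ids):
        idx = np.flatnonzero(flower_ids == fid)
        by_size.setdefault(len(idx), []).append(idx)
    return by_size


def permutation_test(
    sample: GroupedShapeSample,
    statistic: str = "goodall_f",
    n_permutations: int = 10_000,
    seed: int | None = None,
    unit: str = "organ",
) -> PermutationTestResult:
    """Permutation test of no group differences in shape.

    Group labels are permuted across the chosen exchangeable unit:
    ``"organ"`` shuffles labels over all organs; ``"flower"`` keeps each
    flower's set of labels together and shuffles those label blocks among
    flowers with equal organ counts (organs within one flower may be
    correlated). The p-value uses the add-one convention
    p = (#{permuted stat >= observed} + 1) / (n_permutations + 1).

    With the organ unit, if the number of distinct label arrangements does
    not exceed ``n_permutations``, the test enumerates all of them exactly
    and the result is flagged ``exhaustive``.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    if callable(statistic):
        stat_fn, stat_name = statistic, getattr(statistic, "__name__", "custom")
    else:
        if statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {statistic!r}")
        stat_fn, stat_name = _STATISTICS[statistic], statistic
    data, labels = sample.data, sample.labels
    observed = stat_fn(data, labels)
    rng = np.random.default_rng(seed)

    if unit == "organ":
        total = _n_distinct_arrangements(labels)
        if total <= n_permutations:
            count_ge = 0
            for perm in _multiset_permutations(list(labels)):
                if stat_fn(data, np.asarray(perm)) >= observed - 1e-12:
                    count_ge += 1
            return PermutationTestResult(
                stat_name, float(observed), count_ge / total, total, seed,
                unit, exhaustive=True,
            )
        perms = (rng.permutation(labels) for _ in range(n_permutations))
    elif unit == "flower":
        if sample.flower_ids is None:
            raise ValueError("flower-level permutation requires flower_ids")
        blocks_by_size = _flower_blocks(sample.flower_ids)

        def _flower_perms():
            for _ in range(n_permutations):
                perm = np.empty_like(labels)
                for blocks in blocks_by_size.values():
                    order = rng.permutation(len(blocks))
                    for src, dst in enumerate(order):
                        perm[blocks[dst]] = labels[blocks[src]]
                yield perm

        perms = _flower_perms()
    else:
        raise ValueError(f"unknown permutation unit {unit!r}")

    perm_stats = np.array([stat_fn(data, p) for p in perms])
    count_ge = int((perm_stats >= observed - 1e-12).sum())
    p = (count_ge + 1) / (n_permutations + 1)
    return PermutationTestResult(
        stat_name, float(observed), p, n_permutations, seed, unit,
        exhaustive=False,
        perm_mean=float(perm_stats.mean()), perm_sd=float(perm_stats.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# canonical variate analysis


def mean_confidence_ellipse(points: np.ndarray, conf: float = 0.95):
    """95% confidence ellipse for a group mean from 2-D scores.

    The score covariance is scaled by 1/n and sized by the ``conf``
    quantile of the chi-square distribution with 2 df (large-sample
    convention). Returns (center (2,), semi_axes (2,) major first,
    angle_deg of the major axis).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("confidence ellipse requires at least 2 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1) / n
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)[::-1]
    evecs = evecs[:, ::-1]
    radius2 = stats.chi2.ppf(conf, df=2)
    semi_axes = np.sqrt(radius2 * evals)
    angle = math.degrees(math.atan2(evecs[1, 0], evecs[0, 0]))
    return center, semi_axes, angle


@dataclass
class CVAResult:
    """Canonical variate analysis output.

    ``axes`` maps centered input vectors to canonical scores; the pooled
    within-group covariance of the scores is the identity, so canonical
    axes are ordered by the between-group variance they carry
    (``eigenvalues``). ``ellipses`` tabulates the 95% confidence ellipses
    for the group means on CV1-CV2 (None when a single axis is retained).
    """

    axes: np.ndarray  # (d, m)
    scores: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,)
    groups: np.ndarray  # (G,)
    group_means: np.ndarray  # (G, m) in CV space
    grand_mean: np.ndarray  # (d,)
    ellipses: pd.DataFrame | None = field(default=None)


def cva(sample: GroupedShapeSample, tol: float = 1e-8) -> CVAResult:
    """Canonical variate analysis of grouped tangent-space shapes.

    The data are first projected onto the principal subspace in which the
    pooled within-group covariance has eigenvalues above ``tol`` times its
    largest (shape components are rank-deficient by construction), the
    within-group metric is whitened there, and the between-group
    covariance is diagonalized. At most min(G - 1, within-rank) axes are
    retained.
    """
    data, labels = sample.data, sample.labels
    groups, codes, counts, means, grand = _group_decomposition(data, labels)
    g, n = len(groups), len(data)
    if n <= g:
        raise ValueError("CVA requires more observations than groups")
    Xc = data - grand
    resid = data - means[codes]
    W = resid.T @ resid / (n - g)
    evals, evecs = np.linalg.eigh(W)
    if evals[-1] <= 0.0:
        raise ValueError("pooled within-group covariance has rank 0")
    keep = evals > tol * evals[-1]
    T = evecs[:, keep] / np.sqrt(evals[keep])

    Mz = (means - grand) @ T
    B = (counts[:, None] * Mz).T @ Mz / (g - 1)
    bvals, bvecs = np.linalg.eigh(B)
    order = np.argsort(bvals)[::-1]
    m = min(g - 1, T.shape[1])
    U = bvecs[:, order[:m]]
    eigenvalues = np.clip(bvals[order[:m]], 0.0, None)

    axes = T @ U
    scores = Xc @ axes
    group_means = Mz @ U

    ellipses = None
    if m >= 2:
        rows = []
        for i, level in enumerate(groups):
            pts = scores[codes == i][:, :2]
            if len(pts) < 2:
                continue
            center, semi, angle = mean_confidence_ellipse(pts)
            rows.append({"group": level, "n": int(counts[i]),
                         "center_1": center[0], "center_2": center[1],
                         "semi_major": semi[0], "semi_minor": semi[1],
                         "angle_deg": angle})
        ellipses = pd.DataFrame(rows)
    return CVAResult(axes, scores, eigenvalues, groups, group_means, grand,
                     ellipses)


# ---------------------------------------------------------------------------
# group means


@dataclass
class GroupMeans:
    groups: np.ndarray
    means: np.ndarray  # (G, d)
    grand_mean: np.ndarray  # (d,)
    differences: dict  # (a, b) -> means[a] - means[b]


def group_mean_shapes(sample: GroupedShapeSample) -> GroupMeans:
    """Per-group mean tangent vectors, grand mean, and pairwise differences."""
    groups, codes, counts, means, grand = _group_decomposition(
        sample.data, sample.labels
    )
    diffs = {}
    for i, a in enumerate(groups):
        for j, b in enumerate(groups):
            if i < j:
                diffs[(a, b)] = means[i] - means[j]
    return GroupMeans(groups, means, grand, diffs)
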