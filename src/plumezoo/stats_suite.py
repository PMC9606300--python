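"""Comparative statistics for regime contrasts.

Implements the non-parametric and multivariate procedures used to
compare stations across turbidity regimes:

* Kruskal-Wallis H with the tie correction H / (1 - sum(t^3 - t) /
  (N^3 - N)) and a chi-squared (df = k - 1) p-value;
* Dunn's post-hoc z-tests on rank means with tie-corrected pooled
  variance, optionally Holm-adjusted;
* Bray-Curtis dissimilarity (optionally on log10(x+1) abundances) and
  Euclidean distance on per-variable z-scored environmental data;
* one-way PERMANOVA: pseudo-F from the among/within partition of
  squared distances, permutation p = (b + 1)/(m + 1) under a seeded
  generator (9999 permutations by default);
* redundancy analysis (RDA) with variation partitioning over two or
  three predictor sets by inclusion-exclusion on sub-model R^2,
  optionally Ezekiel-adjusted (adjusted fractions may be negative and
  are reported as-is).

All stochastic procedures require an explicit seed to be reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "KWResult",
    "DunnResult",
    "DistanceMatrix",
    "PermanovaResult",
    "VarPartResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "distance_matrix",
    "permanova",
    "rda_varpart",
]


# ---------------------------------------------------------------- rank tests

@dataclass(frozen=True)
class KWResult:
    h_statistic: float
    p_value: float
    group_sizes: tuple
    ties_corrected: bool = True


@dataclass(frozen=True)
class DunnResult:
    pairs: tuple            # ((i, j), ...) group-index pairs
    z_statistics: tuple
    p_values: tuple
    adjustment: str = "none"


def _tie_term(all_values: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: list) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = tuple(len(g) for g in groups)
    if min(sizes) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least three observations in total")
    ranks = _sstats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    h = 0.0 if correction <= 0 else h / correction  # all observations tied
    df = len(groups) - 1
    p = float(_sstats.chi2.sf(h, df))
    return KWResult(float(h), p, sizes)


def dunn_posthoc(groups: list, adjust: str = "none") -> DunnResult:
    """Dunn's pairwise rank comparisons following Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - sum(t^3-t)/(12(N-1)))
    * (1/n_i + 1/n_j)); two-sided normal p-values, Holm step-down when
    ``adjust='holm'``.
    """
    if adjust not in ("none", "holm"):
        raise ValueError("adjust must be 'none' or 'holm'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = np.array([len(g) for g in groups])
    if sizes.min() == 0:
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = _sstats.rankdata(pooled)
    mean_ranks, start = [], 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    var_term = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))
    pairs, zs, ps = [], [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((i, j))
            zs.append(float(z))
            ps.append(float(2.0 * _sstats.norm.sf(abs(z))))
    if adjust == "holm":
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank_pos, idx in enumerate(order):
            running = max(running, (m - rank_pos) * ps[idx])
            adj[idx] = min(1.0, running)
        ps = list(adj)
    return DunnResult(tuple(pairs), tuple(zs), tuple(ps), adjust)


# ---------------------------------------------------------- distance matrices

@dataclass
class DistanceMatrix:
    labels: list
    data: np.ndarray
    metric: str
    undefined_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.data, self.data.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)


def distance_matrix(table, metric: str = "bray-curtis",
                    preprocess: str | None = None) -> DistanceMatrix:
    """Sample-by-sample distances from a samples x variables table.

    ``preprocess``: 'log10' applies log10(x + 1) (abundance tables),
    'zscore' standardises each variable (environmental tables), None
    leaves the data as-is.  For metric 'euclidean-normalized' the
    z-scoring is implied.
    """
    if isinstance(table, pd.DataFrame):
        labels = list(table.index)
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        labels = list(range(x.shape[0]))
    if metric == "euclidean-normalized" and preprocess is None:
        preprocess = "zscore"
    if preprocess == "log10":
        if np.any(x < 0):
            raise ValueError("log10(x+1) preprocessing needs x >= 0")
        x = np.log10(x + 1.0)
    elif preprocess == "zscore":
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        x = (x - x.mean(axis=0)) / sd
    elif preprocess is not None:
        raise ValueError(f"unknown preprocess {preprocess!r}")

    undefined: list[tuple] = []
    if metric == "bray-curtis":
        if np.any(x < 0):
            raise ValueError("Bray-Curtis needs non-negative data")
        with np.errstate(invalid="ignore"):
            d = squareform(pdist(x, metric="braycurtis"))
        zero_rows = np.nonzero(x.sum(axis=1) == 0)[0]
        for ii, i in enumerate(zero_rows):
            for j in zero_rows[ii + 1:]:
                d[i, j] = d[j, i] = np.nan
                undefined.append((labels[i], labels[j]))
        np.fill_diagonal(d, 0.0)
    elif metric == "euclidean-normalized":
        d = squareform(pdist(x, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels, d, metric, undefined)


# ------------------------------------------------------------------ PERMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    factor_levels: tuple
    ss_among: float
    ss_within: float


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    ss = 0.0
    for g in range(n_levels):
        idx = np.nonzero(codes == g)[0]
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(dm: DistanceMatrix, factor, n_perm: int = 9999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    The total sum of squared distances partitions (Gower) into among-
    and within-group parts; pseudo-F = (SS_A/(a-1)) / (SS_W/(N-a)).
    The p-value counts permuted statistics >= the observed one,
    p = (b + 1)/(m + 1); pass a seed for reproducibility.
    """
    codes, levels = pd.factorize(np.asarray(factor))
    if len(codes) != dm.n:
        raise ValueError("factor length must match distance matrix")
    a = len(levels)
    if a < 2:
        raise ValueError("factor needs >= 2 levels")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every level needs >= 2 members")
    if np.isnan(dm.data).any():
        raise ValueError("distance matrix contains undefined pairs")
    n = dm.n
    d2 = dm.data ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_w = _ss_within(d2, codes, a)
    ss_a = ss_total - ss_w
    denom = ss_w / (n - a)
    f_obs = np.inf if denom == 0 else (ss_a / (a - 1)) / denom

    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        ss_w_p = _ss_within(d2, perm, a)
        ss_a_p = ss_total - ss_w_p
        den_p = ss_w_p / (n - a)
        f_p = np.inf if den_p == 0 else (ss_a_p / (a - 1)) / den_p
        if f_p >= f_obs:
            b += 1
    p = (b + 1.0) / (n_perm + 1.0)
    return PermanovaResult(float(f_obs), float(p), n_perm, tuple(levels),
                           float(ss_a), float(ss_w))


# --------------------------------------------------- RDA variation partition

@dataclass(frozen=True)
class VarPartResult:
    total_r2: float
    fractions: dict          # e.g. {"X1": a, "X2": b, "X1&X2": c, ...}
    residual: float
    adjusted: bool
    n_sets: int


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def _rda_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """RDA R^2 of multivariate response y on predictors x (both centred):
    fitted sum of squares over total, via least squares. Returns the
    R^2 and the rank of the predictor matrix."""
    rank = int(np.linalg.matrix_rank(x))
    if rank < x.shape[1]:
        warnings.warn("collinear predictors; effective rank used",
                      stacklevel=3)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    ss_tot = float((y ** 2).sum())
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    return float((fitted ** 2).sum() / ss_tot), rank


def _ezekiel(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("too few rows for adjusted R^2 with "
                         f"{p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda_varpart(response, *predictor_sets, adjusted: bool = True) -> VarPartResult:
    """Partition RDA explained variance over 2 or 3 predictor sets.

    Unique and shared fractions come from inclusion-exclusion on the
    R^2 of every union of sets; in raw mode they sum exactly to the
    full-model R^2.  With ``adjusted=True`` each sub-model R^2 is
    Ezekiel-adjusted first (fractions can then be negative).
    """
    if len(predictor_sets) not in (1, 2, 3):
        raise ValueError("provide 1-3 predictor sets")
    y = _center(np.asarray(response, dtype=float).reshape(
        len(response), -1))
    xs = [_center(np.asarray(x, dtype=float).reshape(len(y), -1))
          for x in predictor_sets]
    n = y.shape[0]
    k = len(xs)

    def r2_of(subset: tuple) -> float:
        x = np.hstack([xs[i] for i in subset])
        if n < x.shape[1] + 2:
            raise ValueError("too few rows for predictor union "
                             f"{subset} ({x.shape[1]} columns)")
        r2, rank = _rda_r2(y, x)
        return _ezekiel(r2, n, rank) if adjusted else r2

    from itertools import combinations
    r2 = {}
    for size in range(1, k + 1):
        for comb in combinations(range(k), size):
            r2[comb] = r2_of(comb)
    full = r2[tuple(range(k))]
    names = [f"X{i + 1}" for i in range(k)]
    fr: dict[str, float] = {}
    if k == 1:
        fr[names[0]] = full
    elif k == 2:
        fr[names[0]] = full - r2[(1,)]
        fr[names[1]] = full - r2[(0,)]
        fr["X1&X2"] = r2[(0,)] + r2[(1,)] - full
    else:
        r1, r2_, r3 = r2[(0,)], r2[(1,)], r2[(2,)]
        r12, r13, r23 = r2[(0, 1)], r2[(0, 2)], r2[(1, 2)]
        g = r1 + r2_ + r3 - r12 - r13 - r23 + full
        fr[names[0]] = full - r23
        fr[names[1]] = full - r13
        fr[names[2]] = full - r12
        fr["X1&X2"] = (r1 + r2_ - r12) - g
        fr["X1&X3"] = (r1 + r3 - r13) - g
        fr["X2&X3"] = (r2_ + r3 - r23) - g
        fr["X1&X2&X3"] = g
    return VarPartResult(float(full), fr, float(1.0 - full), adjusted, k)
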