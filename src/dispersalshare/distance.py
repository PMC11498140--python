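"""Community distances, principal coordinate analysis, PERMANOVA and PERMDISP.

Everything here is computed from first principles on explicit matrices:
Bray-Curtis / Sørensen / Hellinger dissimilarities, classical metric scaling
(Gower-centered eigendecomposition), a distance-based pseudo-F with free
label permutation, and a dispersion test on distances to group spatial
medians (Weiszfeld iteration) with the negative-eigenvalue correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .asv_tables import AsvTable

_EIG_REL_TOL = 1e-9


# ---------------------------------------------------------------------------
# vector dissimilarities
# ---------------------------------------------------------------------------


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("vectors must be non-negative")
    return x, y


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Sum |x_i - y_i| / sum (x_i + y_i), in [0, 1]."""
    x, y = _check_pair(np.asarray(x), np.asarray(y))
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def sorensen(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis on presence/absence; equals (b+c)/(2a+b+c)."""
    x, y = _check_pair(np.asarray(x), np.asarray(y))
    return bray_curtis(np.sign(x), np.sign(y))


def hellinger_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Euclidean distance between square-rooted relative abundances; in [0, sqrt(2)]."""
    x, y = _check_pair(np.asarray(x), np.asarray(y))
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        raise ValueError("Hellinger distance undefined for a zero-sum vector")
    return float(np.linalg.norm(np.sqrt(x / sx) - np.sqrt(y / sy)))


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        d = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n},{n})")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(d < -1e-12):
            raise ValueError("distances must be non-negative")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        self.values = np.clip(d, 0.0, None)

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, keep: Sequence[int]) -> "DistanceMatrix":
        keep = list(keep)
        return DistanceMatrix(
            [self.ids[i] for i in keep], self.values[np.ix_(keep, keep)]
        )


_METRICS = ("bray", "sorensen", "hellinger")


def distance_matrix(table: AsvTable, metric: str = "sorensen") -> DistanceMatrix:
    """All pairwise dissimilarities between the table's samples."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    M = table.counts.astype(float)
    if np.any(M.sum(axis=1) == 0):
        bad = [s for s, t in zip(table.sample_ids, M.sum(axis=1)) if t == 0]
        raise ValueError(f"samples with zero reads: {bad}")
    n = M.shape[0]
    if metric == "sorensen":
        M = np.sign(M)
    if metric in ("bray", "sorensen"):
        s = M.sum(axis=1)
        d = np.zeros((n, n))
        for i in range(n - 1):
            num = np.abs(M[i + 1 :] - M[i]).sum(axis=1)
            den = s[i + 1 :] + s[i]
            d[i, i + 1 :] = num / den
        d = d + d.T
    else:
        H = np.sqrt(M / M.sum(axis=1, keepdims=True))
        sq = (H**2).sum(axis=1)
        g = H @ H.T
        d2 = np.clip(sq[:, None] + sq[None, :] - 2 * g, 0.0, None)
        d = np.sqrt(d2)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.sample_ids), d)


# ---------------------------------------------------------------------------
# principal coordinate analysis
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per positive axis


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _eigen_embedding(
    D: DistanceMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecompose the Gower-centered matrix.

    Returns (eigenvalues desc, real-axis coordinates, imaginary-axis
    coordinates); imaginary axes are scaled by sqrt(-eigenvalue).
    """
    B = _gower_center(D.values)
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = _EIG_REL_TOL * max(np.abs(evals).max(), 1e-300)
    evals = np.where(np.abs(evals) < tol, 0.0, evals)
    pos = evals > 0
    neg = evals < 0
    real = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return evals, real, imag


def pcoa(D: DistanceMatrix) -> Ordination:
    """Classical metric scaling; coordinates only for positive eigenvalues."""
    if D.n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    evals, real, _ = _eigen_embedding(D)
    pos_sum = evals[evals > 0].sum()
    prop = (evals[evals > 0] / pos_sum) if pos_sum > 0 else np.array([])
    return Ordination(
        ids=list(D.ids),
        coordinates=real,
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermutationTestResult:
    statistic: float
    permutation_p: float
    n_permutations: int
    seed: int
    details: dict = field(default_factory=dict)


def _group_codes(groups: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    labels = list(dict.fromkeys(groups))
    codes = np.array([labels.index(g) for g in groups])
    return codes, labels


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    df_a = n_groups - 1
    df_w = n - n_groups
    if ss_within <= 0:
        return 0.0 if ss_among <= 0 else np.inf
    return (ss_among / df_a) / (ss_within / df_w)


def permanova(
    D: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Distance-based pseudo-F with free permutation of sample labels.

    p uses the (1 + count >= observed) / (1 + n_perm) convention, so the
    smallest attainable p with 999 permutations is 0.001.
    """
    if len(groups) != D.n:
        raise ValueError("groups length must match distance matrix size")
    codes, labels = _group_codes(groups)
    counts = np.bincount(codes)
    if len(labels) < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    if counts.min() < 2:
        small = [l for l, c in zip(labels, counts) if c < 2]
        raise ValueError(f"singleton groups not allowed: {small}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = D.values**2
    f_obs = _pseudo_f(d2, codes, len(labels))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(labels)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermutationTestResult(
        statistic=float(f_obs),
        permutation_p=float(p),
        n_permutations=n_perm,
        seed=seed,
        details={"groups": labels, "group_sizes": counts.tolist()},
    )


def pairwise_permanova(
    D: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    adjust: str = "fdr_bh",
) -> list[PermutationTestResult]:
    """One PERMANOVA per unordered group pair, with multiplicity adjustment."""
    if adjust not in ("fdr_bh", "bonferroni", "none"):
        raise ValueError("adjust must be fdr_bh, bonferroni or none")
    codes, labels = _group_codes(groups)
    results = []
    raw_p = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            keep = np.flatnonzero((codes == a) | (codes == b))
            sub = D.submatrix(keep)
            sub_groups = [groups[i] for i in keep]
            res = permanova(sub, sub_groups, n_perm=n_perm, seed=seed)
            res.details["pair"] = (labels[a], labels[b])
            results.append(res)
            raw_p.append(res.permutation_p)
    if adjust == "none":
        adj = raw_p
    else:
        adj = multipletests(raw_p, method=adjust)[1]
    for res, p_raw, p_adj in zip(results, raw_p, adj):
        res.details["p_raw"] = float(p_raw)
        res.details["p_adjusted"] = float(min(1.0, p_adj))
        res.details["adjust"] = adjust
        res.permutation_p = float(min(1.0, p_adj))
    return results


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------


def spatial_median(
    points: np.ndarray, tol: float = 1e-8, max_iter: int = 10000
) -> np.ndarray:
    """Geometric median by damped Weiszfeld iteration (Vardi-Zhang step for
    iterates landing on a data point)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty 2-D array")
    if len(pts) == 1:
        return pts[0].copy()
    c = pts.mean(axis=0)
    for _ in range(max_iter):
        diff = pts - c
        dist = np.linalg.norm(diff, axis=1)
        on_point = dist < 1e-12
        if on_point.all():
            return c
        w = 1.0 / np.where(on_point, np.inf, dist)
        t = (pts * w[:, None]).sum(axis=0) / w.sum()
        if on_point.any():
            r_vec = (diff * w[:, None]).sum(axis=0)
            r = np.linalg.norm(r_vec)
            eta = on_point.sum()
            if r <= eta:  # current point is the minimizer
                return c
            c_new = max(0.0, 1.0 - eta / r) * t + min(1.0, eta / r) * c
        else:
            c_new = t
        if np.linalg.norm(c_new - c) < tol:
            return c_new
        c = c_new
    raise RuntimeError("spatial median iteration failed to converge")


@dataclass
class PermdispResult:
    ids: list[str]
    groups: list[str]
    distances: np.ndarray  # per-sample distance to own group median
    group_means: dict[str, float]
    f_statistic: float
    f_p_value: float
    df_groups: int
    df_residual: int
    ss_groups: float
    ss_residual: float
    permutation: PermutationTestResult


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float, float]:
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = len(values) - n_groups
    # guard against pure floating-point noise when distances are constant
    scale = float((values**2).sum()) + 1e-300
    if ss_b / scale < 1e-12:
        ss_b = 0.0
    if ss_w / scale < 1e-12:
        ss_w = 0.0
    if ss_w <= 0:
        f = 0.0 if ss_b <= 0 else np.inf
    else:
        f = (ss_b / df_b) / (ss_w / df_w)
    return f, ss_b, ss_w


def permdisp(
    D: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    use_median: bool = True,
) -> PermdispResult:
    """Homogeneity of multivariate dispersions.

    The distance matrix is embedded by metric scaling keeping real and
    imaginary axes; each sample's distance to its group's spatial median
    (or centroid with ``use_median=False``) is corrected for imaginary axes
    as sqrt(max(0, d_real^2 - d_imag^2)).  The classical one-way ANOVA F and
    p on these distances are primary; a permutation p of F accompanies them.
    """
    if len(groups) != D.n:
        raise ValueError("groups length must match distance matrix size")
    codes, labels = _group_codes(groups)
    counts = np.bincount(codes)
    if len(labels) < 2 or counts.min() < 2:
        raise ValueError("PERMDISP requires >= 2 groups with >= 2 members each")
    _, real, imag = _eigen_embedding(D)
    z = np.zeros(D.n)
    for g in range(len(labels)):
        idx = np.flatnonzero(codes == g)
        if use_median:
            c_real = spatial_median(real[idx])
            c_imag = spatial_median(imag[idx]) if imag.shape[1] else np.zeros(0)
        else:
            c_real = real[idx].mean(axis=0)
            c_imag = imag[idx].mean(axis=0) if imag.shape[1] else np.zeros(0)
        d2_real = ((real[idx] - c_real) ** 2).sum(axis=1)
        d2_imag = (
            ((imag[idx] - c_imag) ** 2).sum(axis=1) if imag.shape[1] else 0.0
        )
        z[idx] = np.sqrt(np.clip(d2_real - d2_imag, 0.0, None))
    f_obs, ss_b, ss_w = _anova_f(z, codes, len(labels))
    df_b = len(labels) - 1
    df_w = D.n - len(labels)
    if np.isinf(f_obs):
        f_p = 0.0
    elif f_obs == 0 and ss_w <= 0:
        f_p = 1.0
    else:
        f_p = float(stats.f.sf(f_obs, df_b, df_w))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _anova_f(z, perm, len(labels))[0] >= f_obs:
            hits += 1
    perm_res = PermutationTestResult(
        statistic=float(f_obs),
        permutation_p=(1 + hits) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
    )
    group_means = {
        labels[g]: float(z[codes == g].mean()) for g in range(len(labels))
    }
    return PermdispResult(
        ids=list(D.ids),
        groups=list(groups),
        distances=z,
        group_means=group_means,
        f_statistic=float(f_obs),
        f_p_value=f_p,
        df_groups=df_b,
        df_residual=df_w,
        ss_groups=float(ss_b),
        ss_residual=float(ss_w),
        permutation=perm_res,
    )
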