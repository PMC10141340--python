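"""Canonical correlation analysis with asymptotic and permutation inference.

Both blocks are whitened by their (optionally ridge-regularized) sample
covariance; the SVD of the whitened cross-covariance yields the canonical
correlations and weights.  Significance is available two ways: the classical
sequential Wilks' lambda with Rao's F approximation, and a permutation test
on the first canonical correlation (permute one block's sample order,
refit).  The permutation test is the default in the pipeline because it is
distribution-free on the small cohorts this package targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats


class CcaError(ValueError):
    pass


@dataclass
class CCAResult:
    """Canonical correlations, weights, variates, and shapes."""

    correlations: np.ndarray  # r_1 >= ... >= r_m, in [0, 1]
    x_weights: np.ndarray  # p × m
    y_weights: np.ndarray  # q × m
    x_scores: pd.DataFrame  # samples × m canonical variates, unit variance
    y_scores: pd.DataFrame
    ridge: float
    n: int
    p: int
    q: int


@dataclass
class CCASignificance:
    """Significance record for the canonical correlations."""

    wilks_lambda: np.ndarray | None = None
    f_statistic: np.ndarray | None = None
    df: list[tuple[float, float]] = field(default_factory=list)
    asymptotic_p: np.ndarray | None = None
    permutation_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    observed_r1: float | None = None


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _inv_sqrt(cov: np.ndarray, ridge: float) -> np.ndarray:
    p = cov.shape[0]
    if ridge > 0:
        cov = cov + ridge * (np.trace(cov) / p) * np.eye(p)
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() <= 1e-12 * max(vals.max(), 1.0):
        raise CcaError(
            "singular within-block covariance; pass ridge > 0 to regularize"
        )
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def _as_matrix(x) -> tuple[np.ndarray, list]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index)
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, list(range(arr.shape[0]))


def fit_cca(x_scores, y_scores, ridge: float = 0.0) -> CCAResult:
    """Fit canonical correlation analysis between two score blocks.

    ``ridge`` adds ``ridge * trace(S)/p`` to each within-block covariance
    diagonal, stabilizing near-collinear reduced blocks; 0 is exact CCA.
    """
    x, idx = _as_matrix(x_scores)
    y, idy = _as_matrix(y_scores)
    if x.shape[0] != y.shape[0]:
        raise CcaError("blocks must have equal sample counts")
    n = x.shape[0]
    if n <= 2:
        raise CcaError(f"need more than 2 samples, got {n}")
    if ridge < 0:
        raise CcaError("ridge must be >= 0")
    p, q = x.shape[1], y.shape[1]
    xc, yc = _center(x), _center(y)
    sxx = xc.T @ xc / (n - 1)
    syy = yc.T @ yc / (n - 1)
    sxy = xc.T @ yc / (n - 1)
    wx = _inv_sqrt(sxx, ridge)
    wy = _inv_sqrt(syy, ridge)
    u, s, vt = np.linalg.svd(wx @ sxy @ wy)
    m = min(p, q)
    r = np.clip(s[:m], 0.0, 1.0)
    a = wx @ u[:, :m]  # x-weights
    b = wy @ vt[:m].T  # y-weights
    xs = xc @ a
    ys = yc @ b
    # scale variates to unit sample variance
    xs_sd = xs.std(axis=0, ddof=1)
    ys_sd = ys.std(axis=0, ddof=1)
    xs_sd[xs_sd == 0] = 1.0
    ys_sd[ys_sd == 0] = 1.0
    a = a / xs_sd[None, :]
    b = b / ys_sd[None, :]
    xs = xs / xs_sd[None, :]
    ys = ys / ys_sd[None, :]
    cols = [f"CV{i + 1}" for i in range(m)]
    return CCAResult(
        correlations=r,
        x_weights=a,
        y_weights=b,
        x_scores=pd.DataFrame(xs, index=idx, columns=cols),
        y_scores=pd.DataFrame(ys, index=idy, columns=cols),
        ridge=ridge,
        n=n,
        p=p,
        q=q,
    )


def wilks_test(result: CCAResult) -> CCASignificance:
    """Sequential Wilks' lambda with Rao's F approximation.

    For hypothesis k (all correlations from the k-th on are zero),
    Λ_k = Π_{i>=k} (1 − r_i²); the F approximation uses the standard
    degrees of freedom.  With p = q = 1 this reduces exactly to the
    two-sided t-test on the Pearson correlation.
    """
    n, p, q = result.n, result.p, result.q
    if n <= p + q:
        raise CcaError(f"n={n} too small for Wilks test with p={p}, q={q}")
    r = result.correlations
    m = len(r)
    lam = np.empty(m)
    fstat = np.empty(m)
    pvals = np.empty(m)
    dfs: list[tuple[float, float]] = []
    for k in range(m):
        pk = p - k
        qk = q - k
        lam_k = float(np.prod(1.0 - r[k:] ** 2))
        lam_k = min(max(lam_k, np.finfo(float).tiny), 1.0)
        denom = pk**2 + qk**2 - 5
        s = np.sqrt((pk**2 * qk**2 - 4) / denom) if denom > 0 else 1.0
        w = n - k - (pk + qk + 3) / 2.0
        df1 = pk * qk
        df2 = w * s - pk * qk / 2.0 + 1.0
        if df2 <= 0:
            raise CcaError(f"n={n} too small for the F approximation at step {k + 1}")
        lam_root = lam_k ** (1.0 / s)
        f = (1.0 - lam_root) / lam_root * df2 / df1
        lam[k] = lam_k
        fstat[k] = f
        pvals[k] = scipy.stats.f.sf(f, df1, df2)
        dfs.append((df1, df2))
    return CCASignificance(
        wilks_lambda=lam, f_statistic=fstat, df=dfs, asymptotic_p=pvals
    )


def permutation_test(
    x_scores,
    y_scores,
    n_permutations: int = 999,
    seed: int = 0,
    ridge: float = 0.0,
) -> CCASignificance:
    """Permutation p-value for the first canonical correlation.

    One block's sample order is permuted ``n_permutations`` times and CCA is
    refit each time; p = (1 + #{r1_perm >= r1_obs}) / (1 + B).
    """
    if n_permutations < 99:
        raise CcaError("need at least 99 permutations for usable p resolution")
    x, _ = _as_matrix(x_scores)
    y, _ = _as_matrix(y_scores)
    obs = fit_cca(x, y, ridge=ridge)
    r1 = float(obs.correlations[0])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y.shape[0])
        r1_perm = float(fit_cca(x, y[perm], ridge=ridge).correlations[0])
        exceed += r1_perm >= r1 - 1e-12
    p = (1 + exceed) / (1 + n_permutations)
    return CCASignificance(
        permutation_p=p,
        n_permutations=n_permutations,
        seed=seed,
        observed_r1=r1,
    )


def structure_correlations(
    result: CCAResult, block_table: pd.DataFrame, block: str = "x"
) -> pd.DataFrame:
    """Correlate original (transformed) features with the canonical variates.

    Returns features × variates Pearson correlations against both the own-
    block and opposite-block variates (columns ``CVk_x`` / ``CVk_y``).
    Constant features get coefficient 0 with a warning.
    """
    if block not in ("x", "y"):
        raise CcaError("block must be 'x' or 'y'")
    feats = block_table.to_numpy(dtype=float)
    out = {}
    for tag, scores in (("x", result.x_scores), ("y", result.y_scores)):
        sc = scores.to_numpy()
        cols = []
        for j in range(sc.shape[1]):
            var = sc[:, j]
            coeffs = np.empty(feats.shape[1])
            for i in range(feats.shape[1]):
                f = feats[:, i]
                if f.std() == 0 or var.std() == 0:
                    warnings.warn(
                        f"constant feature {block_table.columns[i]!r}; "
                        "structure coefficient set to 0",
                        RuntimeWarning,
                    )
                    coeffs[i] = 0.0
                else:
                    coeffs[i] = np.corrcoef(f, var)[0, 1]
            cols.append(coeffs)
        for j, c in enumerate(cols):
            out[f"CV{j + 1}_{tag}"] = c
    return pd.DataFrame(out, index=block_table.columns)
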