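"""Sparse principal component analysis by rank-one deflation.

Each component is found by alternating power iterations with an ℓ1
soft-threshold on the loading vector, followed by projection deflation.  The
threshold is relative: at each update the loading entries are shrunk by
``penalty`` times the largest absolute entry, so ``penalty = 0`` recovers
ordinary PCA (power iteration on the residual matrix) and ``penalty → 1``
drives every loading to zero.  Components are extracted sequentially, which
keeps the penalty-free limit exactly comparable with an SVD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class SpcaError(ValueError):
    pass


@dataclass
class SparsePCAModel:
    """Fitted sparse PCA: loadings, scores, variance bookkeeping.

    ``loadings`` is features × k with unit-norm columns; ``scores`` is
    samples × k.  ``explained_variance_ratio`` is the variance of each
    component's scores over the total variance of the (centered, scaled)
    training matrix.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    penalty: float
    center: pd.Series
    scale: pd.Series
    converged: bool

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.loadings.index)

    def save(self, directory: str | Path) -> None:
        """Serialize as a JSON + TSV bundle reloadable by :func:`load_model`."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.loadings.to_csv(d / "loadings.tsv", sep="\t", index_label="feature_id")
        self.scores.to_csv(d / "scores.tsv", sep="\t", index_label="sample_id")
        pd.DataFrame({"center": self.center, "scale": self.scale}).to_csv(
            d / "scaling.tsv", sep="\t", index_label="feature_id"
        )
        (d / "model.json").write_text(
            json.dumps(
                {
                    "penalty": self.penalty,
                    "converged": self.converged,
                    "explained_variance": self.explained_variance.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                },
                indent=2,
            )
        )


def load_model(directory: str | Path) -> SparsePCAModel:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    loadings = pd.read_csv(d / "loadings.tsv", sep="\t", index_col="feature_id")
    scores = pd.read_csv(d / "scores.tsv", sep="\t", index_col="sample_id")
    scaling = pd.read_csv(d / "scaling.tsv", sep="\t", index_col="feature_id")
    return SparsePCAModel(
        loadings=loadings,
        scores=scores,
        explained_variance=np.asarray(meta["explained_variance"]),
        explained_variance_ratio=np.asarray(meta["explained_variance_ratio"]),
        penalty=meta["penalty"],
        center=scaling["center"],
        scale=scaling["scale"],
        converged=meta["converged"],
    )


def _soft_threshold(w: np.ndarray, penalty: float) -> np.ndarray:
    if penalty <= 0:
        return w
    thr = penalty * np.abs(w).max()
    out = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
    # entries at the threshold are zeroed too, so penalty >= 1 empties w
    out[np.abs(w) <= thr] = 0.0
    return out


def fit_spca(
    matrix: pd.DataFrame,
    k: int,
    penalty: float = 0.0,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
    scale: bool = False,
) -> SparsePCAModel:
    """Fit k sparse principal components by deflated power iteration.

    Parameters
    ----------
    matrix : DataFrame
        Samples × features; centered internally (and unit-scaled if
        ``scale=True``).
    k : int
        Number of components; at most ``min(n_samples - 1, n_features)``.
    penalty : float
        Relative ℓ1 soft-threshold: at each update, loading entries are
        shrunk by ``penalty`` times the largest absolute entry and entries at
        or below the threshold become exact zeros.  0 gives ordinary PCA;
        values >= 1 zero out every loading (an error).
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    n, p = matrix.shape
    if k < 1 or k > min(n - 1, p):
        raise SpcaError(f"k={k} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if penalty < 0:
        raise SpcaError(f"penalty must be >= 0, got {penalty}")

    center = matrix.mean(axis=0)
    x = matrix.to_numpy(dtype=float) - center.to_numpy()[None, :]
    if scale:
        sds = x.std(axis=0, ddof=1)
        if (sds == 0).any():
            j = int(np.argmax(sds == 0))
            raise SpcaError(f"cannot scale constant feature {matrix.columns[j]!r}")
        x = x / sds[None, :]
        scale_vec = pd.Series(sds, index=matrix.columns)
    else:
        scale_vec = pd.Series(np.ones(p), index=matrix.columns)

    total_var = (x**2).sum() / (n - 1)
    rng = np.random.default_rng(seed)
    residual = x.copy()
    loadings = np.zeros((p, k))
    converged = True
    for comp in range(k):
        # deterministic init from the residual's leading right-singular vector
        try:
            _, _, vt = np.linalg.svd(residual, full_matrices=False)
            w = vt[0]
        except np.linalg.LinAlgError:  # pragma: no cover - svd essentially always works
            w = rng.standard_normal(p)
            w /= np.linalg.norm(w)
        for _ in range(max_iter):
            t = residual @ w
            w_new = _soft_threshold(residual.T @ t, penalty)
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise SpcaError(
                    f"penalty {penalty} zeroed out component {comp + 1}; "
                    "use a smaller penalty"
                )
            w_new /= norm
            if np.linalg.norm(w_new - w) < tol or np.linalg.norm(w_new + w) < tol:
                w = w_new
                break
            w = w_new
        else:
            converged = False
            warnings.warn(
                f"sparse PCA component {comp + 1} did not converge in {max_iter} "
                "iterations",
                RuntimeWarning,
            )
        # sign convention: largest-magnitude loading entry positive
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        loadings[:, comp] = w
        t = residual @ w
        denom = t @ t
        if denom > 0:
            residual = residual - np.outer(t, t @ residual) / denom
    scores = x @ loadings
    explained = scores.var(axis=0, ddof=1)
    return SparsePCAModel(
        loadings=pd.DataFrame(
            loadings, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        scores=pd.DataFrame(
            scores, index=matrix.index, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        explained_variance=explained,
        explained_variance_ratio=explained / total_var,
        penalty=penalty,
        center=center,
        scale=scale_vec,
        converged=converged,
    )


def project(model: SparsePCAModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Project new samples onto a fitted model's components.

    Columns are aligned by feature id, so column order in ``matrix`` is
    irrelevant; a feature-set mismatch is an error.
    """
    if not isinstance(matrix, pd.DataFrame):
        raise SpcaError("project requires a DataFrame with feature ids as columns")
    want = set(model.feature_ids)
    have = set(matrix.columns)
    if want != have:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise SpcaError(f"feature mismatch: missing {missing}, unexpected {extra}")
    x = matrix[model.feature_ids].to_numpy(dtype=float)
    x = (x - model.center.to_numpy()[None, :]) / model.scale.to_numpy()[None, :]
    scores = x @ model.loadings.to_numpy()
    return pd.DataFrame(scores, index=matrix.index, columns=model.loadings.columns)


def choose_k(
    matrix: pd.DataFrame,
    policy: str = "sample_ratio",
    fixed_k: int | None = None,
    variance_threshold: float = 0.9,
) -> int:
    """Pick the number of components for a block.

    ``sample_ratio`` (default): ``min(5, n_samples // 3, n_features)`` —
    keeps the reduced dimension well below the sample count.
    ``variance_threshold``: smallest k whose cumulative penalty-free
    explained variance reaches the threshold.  ``fixed``: a user k, bounds
    checked.
    """
    n, p = matrix.shape
    kmax = min(n - 1, p)
    if policy == "sample_ratio":
        k = min(5, n // 3, p)
        if k < 1:
            raise SpcaError(f"too few samples (n={n}) for the sample_ratio policy")
        return k
    if policy == "fixed":
        if fixed_k is None or not 1 <= fixed_k <= kmax:
            raise SpcaError(f"fixed k={fixed_k} outside [1, {kmax}]")
        return fixed_k
    if policy == "variance_threshold":
        if not 0 < variance_threshold <= 1:
            raise SpcaError("variance_threshold must be in (0, 1]")
        x = matrix.to_numpy(dtype=float)
        x = x - x.mean(axis=0, keepdims=True)
        sv = np.linalg.svd(x, compute_uv=False)
        var = sv**2
        cum = np.cumsum(var) / var.sum()
        return int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    raise SpcaError(f"unknown policy {policy!r}")
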