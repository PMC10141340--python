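"""Community-level and univariate statistics.

Bray–Curtis dissimilarity, non-metric multidimensional scaling (NMDS),
PERMANOVA with exact enumeration on small designs, Wilcoxon rank-sum with
Benjamini–Hochberg correction, and the descriptive per-group summary tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable, SampleMetadata, StudyDataset, TableError


@dataclass
class DistanceMatrix:
    """Symmetric sample × sample dissimilarity matrix in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise TableError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise TableError("distance matrix has non-finite entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise TableError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise TableError("distance matrix must have zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples × k, centered at the origin
    stress: float  # Kruskal stress-1
    n_restarts: int
    converged: bool


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    exact: bool


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity: sum|x - y| / sum(x + y), pairwise."""
    values = table.data.to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).any():
        i = int(np.argmax(values.sum(axis=1) == 0))
        raise TableError(
            f"Bray–Curtis undefined for all-zero sample {table.data.index[i]!r}"
        )
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 500,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of ``n_restarts``."""
    if k < 1:
        raise TableError("k must be >= 1")
    if k >= dist.n:
        raise TableError(f"k={k} must be smaller than n={dist.n}")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_restarts,
        init="random",
        max_iter=max_iter,
        eps=1e-6,
        normalized_stress=True,
        random_state=seed,
    )
    coords = model.fit_transform(dist.values)
    coords = coords - coords.mean(axis=0, keepdims=True)
    frame = pd.DataFrame(
        coords, index=dist.sample_ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    converged = model.n_iter_ < max_iter
    return OrdinationResult(frame, float(model.stress_), n_restarts, bool(converged))


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R² from the squared-distance matrix (Anderson's SS).

    SS_total = sum of squared distances over all pairs / n;
    SS_within = per-group pair sums / group size.
    """
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    levels, counts = np.unique(labels, return_counts=True)
    for lev, cnt in zip(levels, counts):
        idx = np.flatnonzero(labels == lev)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * cnt)
    a = len(levels)
    ss_between = ss_total - ss_within
    if ss_within == 0:  # perfect separation
        f = np.inf
    else:
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return float(f), float(r2)


def permanova(
    dist: DistanceMatrix,
    groups: pd.Series | np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    exact_limit: int = 10_000,
) -> PermanovaResult:
    """Distance-based one-way PERMANOVA (Anderson's pseudo-F).

    The permutation p-value uses the add-one convention
    ``(1 + #{F_perm >= F_obs}) / (1 + B)``.  When the number of distinct
    label arrangements is at most ``exact_limit`` the full enumeration is
    used instead, giving an exact p-value.
    """
    labels = np.asarray(pd.Series(groups).loc[dist.sample_ids] if isinstance(
        groups, pd.Series) else groups)
    if labels.shape[0] != dist.n:
        raise TableError("group labels must match the distance matrix samples")
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise TableError("PERMANOVA requires at least 2 groups")
    if (counts < 2).any():
        raise TableError("every group needs at least 2 samples")

    d2 = dist.values**2
    f_obs, r2 = _permanova_f(d2, labels)

    n = dist.n
    n_arrangements = math.factorial(n)
    for c in counts:
        n_arrangements //= math.factorial(c)
    if n_arrangements <= exact_limit:
        # enumerate distinct multiset permutations of the labels
        exceed = 0
        total = 0
        for positions in itertools.combinations(range(n), counts[0]):
            if len(levels) == 2:
                perm = np.full(n, levels[1], dtype=labels.dtype)
                perm[list(positions)] = levels[0]
                f_perm, _ = _permanova_f(d2, perm)
                exceed += f_perm >= f_obs - 1e-12
                total += 1
            else:  # pragma: no cover - multi-group exact path, small designs only
                rest = [i for i in range(n) if i not in positions]
                for assignment in _multiset_assignments(rest, levels[1:], counts[1:]):
                    perm = np.empty(n, dtype=labels.dtype)
                    perm[list(positions)] = levels[0]
                    for pos, lab in assignment:
                        perm[pos] = lab
                    f_perm, _ = _permanova_f(d2, perm)
                    exceed += f_perm >= f_obs - 1e-12
                    total += 1
        return PermanovaResult(f_obs, r2, exceed / total, total, True)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        f_perm, _ = _permanova_f(d2, perm)
        exceed += f_perm >= f_obs - 1e-12
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations, False)


def _multiset_assignments(positions, levels, counts):
    if len(levels) == 1:
        yield [(p, levels[0]) for p in positions]
        return
    for chosen in itertools.combinations(positions, counts[0]):
        rest = [p for p in positions if p not in chosen]
        for tail in _multiset_assignments(rest, levels[1:], counts[1:]):
            yield [(p, levels[0]) for p in chosen] + tail


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum test; exact null when small and tie-free.

    Returns the rank-sum statistic W of the first sample and the p-value.
    Exact enumeration is used when n_x + n_y <= 20 with no ties; otherwise
    the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise TableError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return w, float(res.pvalue)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise TableError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(dataset: StudyDataset, block: str = "taxa") -> pd.DataFrame:
    """Per-feature two-sided rank-sum test between the two groups, with BH q.

    Runs on untransformed values: the rank-based test is invariant under
    monotone transforms.
    """
    table = dataset.taxa if block == "taxa" else dataset.voc
    groups = dataset.metadata.groups
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise TableError(f"need exactly 2 groups, found {levels}")
    g0 = table.data.loc[groups == levels[0]]
    g1 = table.data.loc[groups == levels[1]]
    rows = []
    for feat in table.feature_ids:
        w, p = wilcoxon_rank_sum(g0[feat].to_numpy(), g1[feat].to_numpy())
        rows.append(
            {
                "feature_id": feat,
                f"median_{levels[0]}": float(g0[feat].median()),
                f"median_{levels[1]}": float(g1[feat].median()),
                "statistic": w,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def summarize_vocs(dataset: StudyDataset) -> pd.DataFrame:
    """Per-VOC descriptive summary: group means ± sd, pooled mean, rank-sum p.

    The pooled ("All") mean is the sample-size-weighted mean of the group
    means, i.e. the plain overall mean.
    """
    groups = dataset.metadata.groups
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise TableError(f"need exactly 2 groups, found {levels}")
    sizes = {g: int((groups == g).sum()) for g in levels}
    if min(sizes.values()) == 0:
        raise TableError("both groups need at least one sample")
    data = dataset.voc.data
    rows = []
    for feat in dataset.voc.feature_ids:
        col = data[feat]
        means = {g: float(col[groups == g].mean()) for g in levels}
        sds = {g: float(col[groups == g].std(ddof=1)) for g in levels}
        pooled_mean = sum(sizes[g] * means[g] for g in levels) / sum(sizes.values())
        _, p = wilcoxon_rank_sum(
            col[groups == levels[0]].to_numpy(), col[groups == levels[1]].to_numpy()
        )
        rows.append(
            {
                "feature_id": feat,
                "mean_all": pooled_mean,
                "sd_all": float(col.std(ddof=1)),
                **{f"mean_{g}": means[g] for g in levels},
                **{f"sd_{g}": sds[g] for g in levels},
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def pooled_mean(group_means: dict[str, float], group_sizes: dict[str, int]) -> float:
    """Sample-size-weighted mean of group means (the overall mean)."""
    n = sum(group_sizes.values())
    return sum(group_sizes[g] * group_means[g] for g in group_means) / n


def _round_half_away(x: float, ndigits: int) -> float:
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def summarize_cohort(metadata: SampleMetadata) -> pd.DataFrame:
    """Demographic counts with percentages per group and in total.

    Percentages are reported to one decimal, rounding half away from zero.
    Categorical covariates (e.g. sex) are tabulated; numeric covariates get
    mean ± sd rows.
    """
    table = metadata.table
    levels = sorted(table["group"].unique())
    rows = []
    for col in table.columns:
        if col == "group":
            continue
        if pd.api.types.is_numeric_dtype(table[col]):
            row = {"variable": col, "category": "mean±sd"}
            for g in levels:
                sub = table.loc[table["group"] == g, col]
                row[g] = f"{sub.mean():.1f} ± {sub.std(ddof=1):.1f}"
            row["total"] = f"{table[col].mean():.1f} ± {table[col].std(ddof=1):.1f}"
            rows.append(row)
        else:
            for cat in sorted(table[col].dropna().unique()):
                row = {"variable": col, "category": cat}
                for g in levels:
                    sub = table.loc[table["group"] == g, col]
                    cnt = int((sub == cat).sum())
                    pct = _round_half_away(100.0 * cnt / len(sub), 1)
                    row[g] = f"{cnt} ({pct}%)"
                cnt = int((table[col] == cat).sum())
                pct = _round_half_away(100.0 * cnt / len(table), 1)
                row["total"] = f"{cnt} ({pct}%)"
                rows.append(row)
    return pd.DataFrame(rows)
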