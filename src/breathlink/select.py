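"""Feature selection and VOC–taxon association mapping.

The selection stage operationalizes a sensitivity analysis by backward
elimination: starting from all prevalence-filtered features of one study
group, the feature (from either block) whose removal best preserves the
first canonical correlation is removed, as long as the block association
stays significant; the survivors are the group's VOC and taxon signatures.
The mapping stage correlates each retained VOC with each retained taxon and
applies the |r| >= 0.5 reporting threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from . import cca as cca_mod
from . import spca as spca_mod
from .tables import StudyDataset, TableError, transform_values


@dataclass
class GroupCCAFit:
    """One group's fitted reduction + CCA, with both significance records."""

    voc_model: spca_mod.SparsePCAModel
    taxa_model: spca_mod.SparsePCAModel
    cca: cca_mod.CCAResult
    wilks: cca_mod.CCASignificance | None
    permutation: cca_mod.CCASignificance | None
    voc_transformed: pd.DataFrame
    taxa_transformed: pd.DataFrame

    @property
    def r1(self) -> float:
        return float(self.cca.correlations[0])


@dataclass
class EliminationStep:
    step: int
    removed: str
    block: str  # "voc" | "taxon"
    r1: float
    p: float
    rationale: str


@dataclass
class SelectionResult:
    group: str
    voc_retained: list[str]
    taxa_retained: list[str]
    final_r1: float
    final_p: float
    significant: bool
    alpha: float


@dataclass
class AssociationMatrix:
    """Retained VOC × retained taxon correlations with a threshold mask."""

    matrix: pd.DataFrame  # vocs × taxa
    method: str
    threshold: float | None = None
    mask: pd.DataFrame | None = None


DEFAULT_VOC_TRANSFORMS = ("log10_pseudo", "zscore")
DEFAULT_TAXA_TRANSFORMS = ("clr_with_zero_replacement",)


def transform_block(table, methods) -> pd.DataFrame:
    """Chain value transforms on a feature table; returns the data frame."""
    out = table
    for m in methods:
        out = transform_values(out, m)
    return out.data


def _reduce(block: pd.DataFrame, k_policy: str, penalty: float, seed: int,
            fixed_k: int | None = None) -> spca_mod.SparsePCAModel:
    k = spca_mod.choose_k(block, policy=k_policy, fixed_k=fixed_k)
    return spca_mod.fit_spca(block, k=k, penalty=penalty, seed=seed)


def fit_group_cca(
    voc_block: pd.DataFrame,
    taxa_block: pd.DataFrame,
    k_policy: str = "sample_ratio",
    penalty: float = 0.0,
    ridge: float = 1e-6,
    seed: int = 0,
    with_wilks: bool = True,
    n_permutations: int = 0,
    fixed_k: int | None = None,
) -> GroupCCAFit:
    """Reduce two transformed blocks with sparse PCA and fit CCA.

    ``n_permutations > 0`` adds a permutation significance record; the Wilks
    record is computed whenever the sample count allows it.
    """
    voc_model = _reduce(voc_block, k_policy, penalty, seed, fixed_k)
    taxa_model = _reduce(taxa_block, k_policy, penalty, seed + 1, fixed_k)
    result = cca_mod.fit_cca(voc_model.scores, taxa_model.scores, ridge=ridge)
    wilks = None
    if with_wilks and result.n > result.p + result.q:
        wilks = cca_mod.wilks_test(result)
    perm = None
    if n_permutations > 0:
        perm = cca_mod.permutation_test(
            voc_model.scores, taxa_model.scores, n_permutations, seed=seed, ridge=ridge
        )
    return GroupCCAFit(voc_model, taxa_model, result, wilks, perm, voc_block, taxa_block)


def choose_penalty(
    voc_block: pd.DataFrame,
    taxa_block: pd.DataFrame,
    grid: tuple[float, ...] = (0.0, 0.2, 0.4),
    n_folds: int = 5,
    k_policy: str = "sample_ratio",
    ridge: float = 1e-6,
    seed: int = 0,
) -> tuple[float, dict[float, float]]:
    """Pick the sparse-PCA penalty by held-out canonical correlation.

    For each grid value, sparse PCA + CCA are fit on training folds and the
    first canonical pair is evaluated as the Pearson correlation of the
    projected held-out variates; the penalty maximizing the mean held-out
    correlation wins (ties go to the sparser model).  Returns the winner and
    the per-penalty mean held-out correlation for the run log.
    """
    n = voc_block.shape[0]
    n_folds = min(n_folds, n // 3)
    if n_folds < 2:
        return grid[0], {}
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    scores: dict[float, float] = {}
    for pen in grid:
        held = []
        for fold in folds:
            test_mask = np.zeros(n, dtype=bool)
            test_mask[fold] = True
            tr_v, te_v = voc_block.iloc[~test_mask], voc_block.iloc[test_mask]
            tr_t, te_t = taxa_block.iloc[~test_mask], taxa_block.iloc[test_mask]
            try:
                fit = fit_group_cca(
                    tr_v, tr_t, k_policy, pen, ridge, seed, with_wilks=False
                )
                u = spca_mod.project(fit.voc_model, te_v).to_numpy() @ fit.cca.x_weights
                v = spca_mod.project(fit.taxa_model, te_t).to_numpy() @ fit.cca.y_weights
                if u[:, 0].std() == 0 or v[:, 0].std() == 0:
                    continue
                held.append(abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1]))
            except (spca_mod.SpcaError, cca_mod.CcaError):
                continue
        if held:
            scores[pen] = float(np.mean(held))
    if not scores:
        return grid[0], scores
    best = max(scores, key=lambda pen: (scores[pen], pen))
    return best, scores


def _scan_p(fit: GroupCCAFit) -> float:
    """Significance used while scanning candidates: Wilks first-hypothesis p."""
    if fit.wilks is None:
        raise cca_mod.CcaError(
            "sample count too small for the Wilks scan p; reduce k or features"
        )
    return float(fit.wilks.asymptotic_p[0])


def backward_eliminate(
    dataset_group: StudyDataset,
    alpha: float = 0.05,
    min_features: tuple[int, int] = (5, 5),
    k_policy: str = "sample_ratio",
    penalty: float = 0.0,
    ridge: float = 1e-6,
    n_permutations: int = 199,
    seed: int = 0,
    voc_transforms: tuple[str, ...] = DEFAULT_VOC_TRANSFORMS,
    taxa_transforms: tuple[str, ...] = DEFAULT_TAXA_TRANSFORMS,
    scan_k: int | None = None,
    rule: str = "least_contributing",
) -> tuple[SelectionResult, list[EliminationStep]]:
    """Backward elimination across both blocks of one study group.

    Two removal rules are available.  The default, ``least_contributing``,
    removes at each step the feature with the smallest absolute structure
    coefficient (correlation with its own block's first canonical variate)
    whose removal keeps the association significant (scan p < alpha) — the
    feature contributing least to the canonical pair.  ``max_r1`` instead
    refits sparse PCA + CCA for every candidate and removes the one whose
    removal yields the highest first canonical correlation among refits
    that stay significant; with redundant signatures the marginal effect of
    any single feature is near zero, so this rule discriminates poorly and
    is kept for sensitivity analysis of the selection itself.

    Elimination stops when no removal stays significant or both blocks are
    at their floors (``min_features``, per block).  The initial and final
    significance gates use the permutation test; the per-candidate scan
    uses the Wilks p for tractability.  Ties break by smaller |structure
    coefficient|, then lexicographic feature id.
    """
    if rule not in ("least_contributing", "max_r1"):
        raise ValueError(f"unknown elimination rule {rule!r}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    groups = dataset_group.metadata.groups.unique()
    if len(groups) != 1:
        raise TableError(f"backward elimination needs a single-group dataset, got {list(groups)}")
    group = str(groups[0])
    min_voc, min_taxa = min_features

    voc_block = transform_block(dataset_group.voc, voc_transforms)
    taxa_block = transform_block(dataset_group.taxa, taxa_transforms)

    kp = "fixed" if scan_k is not None else k_policy
    fit = fit_group_cca(
        voc_block, taxa_block, kp, penalty, ridge, seed,
        n_permutations=n_permutations, fixed_k=scan_k,
    )
    init_p = float(fit.permutation.permutation_p)
    if init_p >= alpha:
        return (
            SelectionResult(
                group,
                list(voc_block.columns),
                list(taxa_block.columns),
                fit.r1,
                init_p,
                significant=False,
                alpha=alpha,
            ),
            [],
        )

    trace: list[EliminationStep] = []
    step = 0
    while True:
        candidates: list[tuple[str, str]] = []
        if voc_block.shape[1] > min_voc:
            candidates += [(f, "voc") for f in voc_block.columns]
        if taxa_block.shape[1] > min_taxa:
            candidates += [(f, "taxon") for f in taxa_block.columns]
        if not candidates:
            break

        # structure coefficients of the current fit, for tie-breaking
        struct: dict[str, float] = {}
        for blk_df, scores in (
            (voc_block, fit.cca.x_scores),
            (taxa_block, fit.cca.y_scores),
        ):
            cv1 = scores.to_numpy()[:, 0]
            for name in blk_df.columns:
                col = blk_df[name].to_numpy()
                struct[name] = (
                    abs(float(np.corrcoef(col, cv1)[0, 1])) if col.std() > 0 else 0.0
                )

        def refit_without(name: str, blk: str) -> GroupCCAFit:
            if blk == "voc":
                return fit_group_cca(
                    voc_block.drop(columns=[name]), taxa_block,
                    kp, penalty, ridge, seed, fixed_k=scan_k,
                )
            return fit_group_cca(
                voc_block, taxa_block.drop(columns=[name]),
                kp, penalty, ridge, seed, fixed_k=scan_k,
            )

        best: tuple | None = None
        if rule == "least_contributing":
            # try candidates from the least-contributing upward; commit the
            # first whose removal stays significant
            for name, blk in sorted(candidates, key=lambda c: (struct[c[0]], c[0])):
                cand_fit = refit_without(name, blk)
                p = _scan_p(cand_fit)
                if p < alpha:
                    best = (cand_fit.r1, name, blk, cand_fit, p)
                    break
        else:  # max_r1
            for name, blk in candidates:
                cand_fit = refit_without(name, blk)
                p = _scan_p(cand_fit)
                if p >= alpha:
                    continue
                # maximize r1; tie-break on smaller |structure coeff|, then id
                take = best is None or cand_fit.r1 > best[0] + 1e-12 or (
                    abs(cand_fit.r1 - best[0]) <= 1e-12
                    and (struct[name], name) < (struct[best[1]], best[1])
                )
                if take:
                    best = (cand_fit.r1, name, blk, cand_fit, p)
        if best is None:
            break
        _, name, blk, fit, p = best
        step += 1
        if blk == "voc":
            voc_block = voc_block.drop(columns=[name])
        else:
            taxa_block = taxa_block.drop(columns=[name])
        rationale = (
            "smallest |structure coefficient| with significant refit"
            if rule == "least_contributing"
            else "max r1 among significant refits"
        )
        trace.append(EliminationStep(step, name, blk, fit.r1, p, rationale))

    final = cca_mod.permutation_test(
        fit.voc_model.scores, fit.taxa_model.scores, n_permutations,
        seed=seed, ridge=ridge,
    )
    return (
        SelectionResult(
            group,
            list(voc_block.columns),
            list(taxa_block.columns),
            fit.r1,
            float(final.permutation_p),
            significant=float(final.permutation_p) < alpha,
            alpha=alpha,
        ),
        trace,
    )


def cross_block_correlations(
    dataset_group: StudyDataset,
    selection: SelectionResult,
    method: str = "spearman",
    voc_transforms: tuple[str, ...] = DEFAULT_VOC_TRANSFORMS,
) -> AssociationMatrix:
    """Pairwise correlations of retained VOCs (transformed) with retained taxa.

    Spearman by default — peak areas are heavy-tailed and rank correlation
    is invariant under the monotone transforms applied upstream.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be spearman or pearson, got {method!r}")
    if not selection.voc_retained or not selection.taxa_retained:
        raise TableError("selection has an empty retained set")
    voc = transform_block(dataset_group.voc, voc_transforms)[selection.voc_retained]
    taxa = dataset_group.taxa.data[selection.taxa_retained]
    out = np.empty((voc.shape[1], taxa.shape[1]))
    for i, vname in enumerate(voc.columns):
        x = voc[vname].to_numpy()
        for j, tname in enumerate(taxa.columns):
            y = taxa[tname].to_numpy()
            if x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"constant feature in pair ({vname!r}, {tname!r}); correlation 0",
                    RuntimeWarning,
                )
                out[i, j] = 0.0
                continue
            if method == "spearman":
                out[i, j] = scipy.stats.spearmanr(x, y).statistic
            else:
                out[i, j] = np.corrcoef(x, y)[0, 1]
    frame = pd.DataFrame(out, index=voc.columns, columns=taxa.columns)
    return AssociationMatrix(frame, method)


def apply_threshold(
    assoc: AssociationMatrix, tau: float = 0.5
) -> tuple[AssociationMatrix, pd.DataFrame]:
    """Mask the association matrix at |r| >= tau and drop featureless rows/cols.

    Returns the filtered matrix (features with no surviving partner removed)
    and the retained pair list sorted by |r| descending.
    """
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    mask = assoc.matrix.abs() >= tau
    rows = mask.any(axis=1)
    cols = mask.any(axis=0)
    filtered = assoc.matrix.loc[rows, cols]
    pairs = [
        {"voc": v, "taxon": t, "r": float(assoc.matrix.at[v, t])}
        for v in assoc.matrix.index
        for t in assoc.matrix.columns
        if mask.at[v, t]
    ]
    pair_df = pd.DataFrame(pairs, columns=["voc", "taxon", "r"])
    if len(pair_df):
        pair_df = pair_df.reindex(
            pair_df["r"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return (
        AssociationMatrix(filtered, assoc.method, threshold=tau, mask=mask.loc[rows, cols]),
        pair_df,
    )


@dataclass
class HeatmapTable:
    """Row/column-clustered z-scored matrix for the VOC overview heatmap."""

    matrix: pd.DataFrame  # features × samples, z-scored log values, reordered
    feature_order: list[str]
    sample_order: list[str]
    feature_linkage: np.ndarray
    sample_linkage: np.ndarray


def cluster_heatmap_table(voc_table) -> HeatmapTable:
    """Hierarchically cluster the VOC table for a features × samples heatmap.

    Values are log10(pseudo)-transformed then z-scored per feature;
    average-linkage hierarchical clustering with Euclidean distance orders
    both axes.  Constant features are an error (their z-score is undefined).
    """
    if voc_table.n_features < 2:
        raise TableError("need at least 2 features to cluster")
    z = transform_block(voc_table, ("log10_pseudo", "zscore"))
    m = z.to_numpy().T  # features × samples
    feat_link = sch.linkage(m, method="average", metric="euclidean")
    samp_link = sch.linkage(m.T, method="average", metric="euclidean")
    feat_order = sch.leaves_list(feat_link)
    samp_order = sch.leaves_list(samp_link)
    features = [z.columns[i] for i in feat_order]
    samples = [z.index[i] for i in samp_order]
    frame = pd.DataFrame(m, index=z.columns, columns=z.index).loc[features, samples]
    return HeatmapTable(frame, features, samples, feat_link, samp_link)
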