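"""End-to-end group-stratified analysis: config, orchestration, report bundle.

Stage order: read/align (or simulate) → prevalence filters → pooled
community statistics → per-group transform → sparse PCA → CCA with
significance → backward elimination → association mapping with the |r| >=
0.5 threshold → report files.  Every source of randomness derives its seed
from the master seed and a stage name, so stages re-run reproducibly in
isolation and the whole bundle is byte-identical under a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cca as cca_mod
from . import community as comm
from . import select as sel
from .simulate import SyntheticConfig, generate_cohort, write_truth
from .tables import (
    FeatureTable,
    StudyDataset,
    TableError,
    align_samples,
    prevalence_filter,
    read_metadata,
    read_taxon_profiles,
    read_voc_table,
)

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific sub-seed below 2**31 from the master seed."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    # input: either the three table paths or a simulate block
    voc_path: str | None = None
    taxa_path: str | None = None
    metadata_path: str | None = None
    simulate: dict | None = None

    voc_min_prevalence: float = 0.2
    taxa_min_prevalence: float = 0.3
    voc_transforms: tuple[str, ...] = sel.DEFAULT_VOC_TRANSFORMS
    taxa_transforms: tuple[str, ...] = sel.DEFAULT_TAXA_TRANSFORMS

    k_policy: str = "sample_ratio"
    penalty: float | str = "auto"  # "auto" → cross-validated grid choice
    penalty_grid: tuple[float, ...] = (0.0, 0.2, 0.4)
    ridge: float = 1e-6
    n_permutations: int = 199
    alpha: float = 0.05
    min_features: tuple[int, int] = (5, 5)
    correlation_method: str = "spearman"
    tau: float = 0.5

    out_dir: str = "breathlink_run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("voc_transforms", "taxa_transforms", "penalty_grid", "min_features"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("voc_transforms", "taxa_transforms", "penalty_grid", "min_features"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class GroupReport:
    group: str
    fit: sel.GroupCCAFit
    selection: sel.SelectionResult
    trace: list[sel.EliminationStep]
    association: sel.AssociationMatrix
    thresholded: sel.AssociationMatrix
    pairs: pd.DataFrame
    penalty_used: float
    penalty_log: dict


@dataclass
class ReportBundle:
    config: RunConfig
    dataset: StudyDataset
    community: dict
    groups: dict[str, GroupReport] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _load_dataset(config: RunConfig) -> tuple[StudyDataset, object | None]:
    if config.simulate is not None:
        sim = SyntheticConfig.from_dict(config.simulate)
        dataset, truth = generate_cohort(sim)
        return dataset, truth
    if not (config.voc_path and config.taxa_path and config.metadata_path):
        raise TableError("config needs either a simulate block or all three input paths")
    voc = read_voc_table(config.voc_path)
    taxa = read_taxon_profiles(config.taxa_path)
    metadata = read_metadata(config.metadata_path)
    return align_samples(voc, taxa, metadata), None


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, encoding="utf-8")


def _community_stage(dataset: StudyDataset, config: RunConfig, out: Path) -> dict:
    seed = stage_seed(config.seed, "community")
    dist = comm.bray_curtis(dataset.taxa)
    ordination = comm.nmds(dist, k=2, seed=seed)
    perma = comm.permanova(dist, dataset.metadata.groups, seed=seed)
    diff = comm.differential_abundance(dataset)
    voc_summary = comm.summarize_vocs(dataset)
    cohort = comm.summarize_cohort(dataset.metadata)

    _write_tsv(dist.to_frame(), out / "bray_curtis.tsv", "sample_id")
    _write_tsv(ordination.coordinates, out / "nmds_coordinates.tsv", "sample_id")
    (out / "permanova.json").write_text(
        json.dumps(
            {
                "pseudo_F": perma.pseudo_f,
                "R2": perma.r2,
                "p_value": perma.p_value,
                "n_permutations": perma.n_permutations,
                "exact": perma.exact,
                "nmds_stress": ordination.stress,
            },
            indent=2,
        )
    )
    _write_tsv(diff, out / "differential_abundance.tsv", "feature_id")
    _write_tsv(voc_summary, out / "voc_summary.tsv", "feature_id")
    cohort.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
    heat = sel.cluster_heatmap_table(dataset.voc)
    _write_tsv(heat.matrix, out / "voc_heatmap_matrix.tsv", "feature_id")
    return {
        "distance": dist,
        "nmds": ordination,
        "permanova": perma,
        "differential_abundance": diff,
        "voc_summary": voc_summary,
        "cohort_summary": cohort,
        "heatmap": heat,
    }


def _drop_group_degenerate(table: FeatureTable, min_fraction: float) -> FeatureTable:
    """Within-group prevalence + variance filter before transforms.

    A feature detected in the pooled cohort can be absent or constant inside
    one group, which makes its z-score (and any correlation) undefined
    there; such features carry no within-group information and are dropped.
    """
    filtered = prevalence_filter(table, min_fraction)
    values = filtered.data.to_numpy()
    keep = np.ptp(values, axis=0) > 0
    cols = [c for c, k in zip(filtered.data.columns, keep) if k]
    if not cols:
        raise TableError("no informative features left within the group")
    return FeatureTable(filtered.data[cols], filtered.kind, {
        k: v for k, v in filtered.feature_meta.items() if k in set(cols)})


def _group_stage(
    dataset: StudyDataset, group: str, config: RunConfig, out: Path
) -> GroupReport:
    seed = stage_seed(config.seed, f"group:{group}")
    sub = dataset.subset_group(group)
    sub = StudyDataset(
        _drop_group_degenerate(sub.voc, config.voc_min_prevalence),
        _drop_group_degenerate(sub.taxa, config.taxa_min_prevalence),
        sub.metadata,
    )
    voc_block = sel.transform_block(sub.voc, config.voc_transforms)
    taxa_block = sel.transform_block(sub.taxa, config.taxa_transforms)

    penalty_log: dict = {}
    if config.penalty == "auto":
        penalty, penalty_log = sel.choose_penalty(
            voc_block,
            taxa_block,
            grid=config.penalty_grid,
            k_policy=config.k_policy,
            ridge=config.ridge,
            seed=seed,
        )
        logger.info("group %s: penalty grid %s -> %s", group, penalty_log, penalty)
    else:
        penalty = float(config.penalty)

    fit = sel.fit_group_cca(
        voc_block,
        taxa_block,
        k_policy=config.k_policy,
        penalty=penalty,
        ridge=config.ridge,
        seed=seed,
        n_permutations=config.n_permutations,
    )
    selection, trace = sel.backward_eliminate(
        sub,
        alpha=config.alpha,
        min_features=config.min_features,
        k_policy=config.k_policy,
        penalty=penalty,
        ridge=config.ridge,
        n_permutations=config.n_permutations,
        seed=seed,
        voc_transforms=config.voc_transforms,
        taxa_transforms=config.taxa_transforms,
    )
    association = sel.cross_block_correlations(
        sub, selection, method=config.correlation_method,
        voc_transforms=config.voc_transforms,
    )
    thresholded, pairs = sel.apply_threshold(association, tau=config.tau)

    gdir = out / f"group_{group}"
    gdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(
        pd.DataFrame(fit.cca.correlations[None, :],
                     columns=fit.cca.x_scores.columns, index=["r"]),
        gdir / "canonical_correlations.tsv",
    )
    _write_tsv(fit.cca.x_scores, gdir / "voc_variates.tsv", "sample_id")
    _write_tsv(fit.cca.y_scores, gdir / "taxa_variates.tsv", "sample_id")
    struct_v = cca_mod.structure_correlations(fit.cca, voc_block)
    struct_t = cca_mod.structure_correlations(fit.cca, taxa_block, block="y")
    _write_tsv(struct_v, gdir / "voc_structure_coefficients.tsv", "feature_id")
    _write_tsv(struct_t, gdir / "taxa_structure_coefficients.tsv", "feature_id")
    sig = {
        "group": group,
        "r1": fit.r1,
        "permutation_p": fit.permutation.permutation_p if fit.permutation else None,
        "n_permutations": config.n_permutations,
        "wilks_p": float(fit.wilks.asymptotic_p[0]) if fit.wilks else None,
        "ridge": config.ridge,
        "penalty": penalty,
        "penalty_grid_heldout_r": {str(k): v for k, v in penalty_log.items()},
        "seed": seed,
    }
    (gdir / "cca_significance.json").write_text(json.dumps(sig, indent=2))
    trace_df = pd.DataFrame(
        [dataclasses.asdict(s) for s in trace],
        columns=["step", "removed", "block", "r1", "p", "rationale"],
    )
    trace_df.to_csv(gdir / "elimination_trace.tsv", sep="\t", index=False)
    (gdir / "selection.json").write_text(
        json.dumps(dataclasses.asdict(selection), indent=2)
    )
    _write_tsv(association.matrix, gdir / "association_matrix.tsv", "voc")
    _write_tsv(thresholded.matrix, gdir / "association_matrix_thresholded.tsv", "voc")
    pairs.to_csv(gdir / "retained_pairs.tsv", sep="\t", index=False)
    return GroupReport(
        group, fit, selection, trace, association, thresholded, pairs,
        penalty, penalty_log,
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage and write the report bundle under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage read/align")
    dataset, truth = _load_dataset(config)
    if truth is not None:
        write_truth(truth, out / "truth.json")

    logger.info("stage prevalence filters")
    voc = prevalence_filter(dataset.voc, config.voc_min_prevalence)
    taxa = prevalence_filter(dataset.taxa, config.taxa_min_prevalence)
    dataset = StudyDataset(voc, taxa, dataset.metadata)
    voc.to_tsv(out / "voc_filtered.tsv")
    taxa.to_tsv(out / "taxa_filtered.tsv")
    dataset.metadata.table.to_csv(out / "metadata.tsv", sep="\t", index_label="sample_id")

    logger.info("stage community statistics")
    community = _community_stage(dataset, config, out)

    groups: dict[str, GroupReport] = {}
    for group in sorted(dataset.metadata.groups.unique()):
        logger.info("stage integrate group=%s", group)
        groups[group] = _group_stage(dataset, group, config, out)

    manifest = {
        "package": "breathlink",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {
            "community": stage_seed(config.seed, "community"),
            **{
                f"group:{g}": stage_seed(config.seed, f"group:{g}")
                for g in groups
            },
        },
        "files": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ReportBundle(config, dataset, community, groups, manifest)
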