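"""Synthetic paired breath-VOC / fecal-taxon cohorts with planted structure.

The generator emulates the statistical shape of a two-group breath–stool
study: log-normal GC–MS peak areas with below-detection zeros, zero-inflated
compositional taxon abundances, unequal group sizes (16 cancer / 33 control
by default), and a planted latent factor.  Per sample a latent pair
``(u, v)`` is drawn with ``corr(u, v) = rho``; ``u`` loads onto that group's
VOC signature features and ``v`` onto its taxon signature features, both on
the log scale before exponentiation, zeroing, and compositional closure.
Signature sets are disjoint between groups, so the canonical structure each
group carries is its own.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata, StudyDataset


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of the paired-cohort generator.

    Defaults mirror the study design the pipeline targets: 16 cancer and 33
    control participants, a strong planted canonical correlation, and peak
    areas in the 1e5–1e6 range typical of untargeted GC–MS tables.
    """

    n_cancer: int = 16
    n_control: int = 33
    p_voc: int = 60
    q_taxa: int = 80
    sig_voc: int = 8
    sig_taxa: int = 10
    rho: float = 0.9
    loading_scale: float = 2.0
    voc_logmean_range: tuple[float, float] = (11.5, 14.5)  # ln peak-area baseline
    voc_logsd: float = 1.0
    taxa_concentration: float = 1.0  # inverse scale of per-sample log noise
    zero_prob_range: tuple[float, float] = (0.0, 0.4)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cancer < 0 or self.n_control < 0:
            raise ConfigError("sample counts must be non-negative")
        if self.n_cancer + self.n_control < 3:
            raise ConfigError("need at least 3 samples in total")
        if not (0 <= self.rho <= 1):
            raise ConfigError(f"rho must be in [0, 1], got {self.rho}")
        if self.sig_voc * 2 > self.p_voc:
            raise ConfigError("need 2*sig_voc <= p_voc for disjoint group signatures")
        if self.sig_taxa * 2 > self.q_taxa:
            raise ConfigError("need 2*sig_taxa <= q_taxa for disjoint group signatures")
        lo, hi = self.zero_prob_range
        if not (0 <= lo <= hi < 1):
            raise ConfigError("zero_prob_range must satisfy 0 <= lo <= hi < 1")
        if self.loading_scale < 0 or self.voc_logsd <= 0 or self.taxa_concentration <= 0:
            raise ConfigError("scales must be positive (loading_scale may be 0)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voc_logmean_range"] = list(self.voc_logmean_range)
        d["zero_prob_range"] = list(self.zero_prob_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for k in ("voc_logmean_range", "zero_prob_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort, for recovery tests."""

    rho: dict[str, float]  # per group
    voc_signature: dict[str, list[str]]
    taxa_signature: dict[str, list[str]]
    u: dict[str, float] = field(default_factory=dict)  # per-sample latent scores
    v: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "voc_signature": self.voc_signature,
            "taxa_signature": self.taxa_signature,
            "u": self.u,
            "v": self.v,
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


GROUPS = ("cancer", "control")


def generate_cohort(config: SyntheticConfig) -> tuple[StudyDataset, GroundTruth]:
    """Draw one paired cohort with planted canonical structure.

    Deterministic under ``config.seed``: the same configuration always
    produces bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cancer + config.n_control
    sample_ids = [f"GC{i + 1:03d}" for i in range(config.n_cancer)] + [
        f"HC{i + 1:03d}" for i in range(config.n_control)
    ]
    groups = ["cancer"] * config.n_cancer + ["control"] * config.n_control

    voc_ids = [f"VOC_{j + 1:03d}" for j in range(config.p_voc)]
    taxa_ids = [f"s__Taxon_{j + 1:03d}" for j in range(config.q_taxa)]
    sig = {
        "cancer": (
            voc_ids[: config.sig_voc],
            taxa_ids[: config.sig_taxa],
        ),
        "control": (
            voc_ids[config.sig_voc : 2 * config.sig_voc],
            taxa_ids[config.sig_taxa : 2 * config.sig_taxa],
        ),
    }

    # latent pair with corr(u, v) = rho
    u = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    v = config.rho * u + np.sqrt(1.0 - config.rho**2) * eps

    # --- VOC block: log-normal peak areas -----------------------------------
    lo, hi = config.voc_logmean_range
    voc_mu = rng.uniform(lo, hi, size=config.p_voc)
    log_voc = voc_mu[None, :] + config.voc_logsd * rng.standard_normal((n, config.p_voc))
    for g in GROUPS:
        rows = [i for i, gg in enumerate(groups) if gg == g]
        cols = [voc_ids.index(f) for f in sig[g][0]]
        if rows and cols:
            log_voc[np.ix_(rows, cols)] += config.loading_scale * u[rows, None]
    voc_values = np.exp(log_voc)

    # --- taxon block: logistic-normal composition ----------------------------
    taxa_base = rng.normal(0.0, 2.0, size=config.q_taxa)
    noise_sd = 1.0 / np.sqrt(config.taxa_concentration)
    log_taxa = taxa_base[None, :] + noise_sd * rng.standard_normal((n, config.q_taxa))
    for g in GROUPS:
        rows = [i for i, gg in enumerate(groups) if gg == g]
        cols = [taxa_ids.index(f) for f in sig[g][1]]
        if rows and cols:
            log_taxa[np.ix_(rows, cols)] += config.loading_scale * v[rows, None]
    taxa_values = np.exp(log_taxa)

    # --- below-detection censoring, applied after signal injection -----------
    # each feature has a detection limit at its zero_prob quantile: the
    # lowest floor(n * zero_prob) values are censored to zero, so feature
    # prevalence is 1 - zero_prob while zeros remain low-intensity cells
    zlo, zhi = config.zero_prob_range
    voc_zero_p = rng.uniform(zlo, zhi, size=config.p_voc)
    taxa_zero_p = rng.uniform(zlo, zhi, size=config.q_taxa)
    for values, probs in ((voc_values, voc_zero_p), (taxa_values, taxa_zero_p)):
        for j in range(values.shape[1]):
            n_zero = int(np.floor(n * probs[j]))
            if n_zero:
                order = np.argsort(values[:, j])
                values[order[:n_zero], j] = 0.0

    # closure; guard against an all-zero stool profile by restoring the
    # sample's dominant taxon
    row_sums = taxa_values.sum(axis=1)
    dead = row_sums == 0
    if dead.any():
        resurrect = np.exp(log_taxa[dead]).argmax(axis=1)
        taxa_values[np.flatnonzero(dead), resurrect] = np.exp(
            log_taxa[dead, resurrect]
        )
        row_sums = taxa_values.sum(axis=1)
    taxa_values = taxa_values / row_sums[:, None]

    # light demographic covariates, carried but unused by the core analysis
    sex = np.where(rng.random(n) < 0.69, "female", "male")
    age = np.where(
        np.array(groups) == "cancer",
        rng.normal(62.0, 11.5, n),
        rng.normal(51.0, 14.0, n),
    ).round(1)

    voc = FeatureTable(pd.DataFrame(voc_values, index=sample_ids, columns=voc_ids), "voc")
    taxa = FeatureTable(
        pd.DataFrame(taxa_values, index=sample_ids, columns=taxa_ids), "taxon"
    )
    metadata = SampleMetadata(
        pd.DataFrame(
            {"group": groups, "sex": sex, "age": age},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = GroundTruth(
        rho={g: config.rho for g in GROUPS},
        voc_signature={g: list(sig[g][0]) for g in GROUPS},
        taxa_signature={g: list(sig[g][1]) for g in GROUPS},
        u={s: float(x) for s, x in zip(sample_ids, u)},
        v={s: float(x) for s, x in zip(sample_ids, v)},
        config=config.to_dict(),
    )
    return StudyDataset(voc, taxa, metadata), truth


def null_cohort(config: SyntheticConfig) -> tuple[StudyDataset, GroundTruth]:
    """Pure-noise cohort: rho forced to 0 and no signature features.

    Used as the type-I-error harness: every feature in both blocks is
    independent of the latent pair, so any detected canonical structure is a
    false positive.
    """
    null_cfg = dataclasses.replace(config, rho=0.0, sig_voc=0, sig_taxa=0)
    dataset, truth = generate_cohort(null_cfg)
    return dataset, truth


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize ground truth as JSON; round-trips losslessly."""
    Path(path).write_text(
        json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
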