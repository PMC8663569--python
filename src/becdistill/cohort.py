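"""Synthetic asthma-cohort generator.

Emulates the statistical structure of a bronchial-epithelial-brushing
expression study: a cohort of healthy controls (HC), mild-to-moderate
(MMA) and severe (SA) asthmatics whose log2 expression matrix carries

* four latent patient clusters of roughly equal size, one enriched for
  healthy controls and one for severe asthma;
* cluster-discriminative genes shifted up or down in exactly one
  cluster;
* covariate effects (biologic sex, oral corticosteroid use) on a
  disjoint gene subset;
* lung function (FEV1 % predicted) generated as a sparse linear
  function of a handful of planted genes plus noise, with an extra
  decrement in the severe-asthma-enriched cluster.

Every generated object is accompanied by a :class:`GroundTruth` that
records the planted structure, so downstream stages can be scored for
parameter recovery.  All randomness flows from one integer seed;
sub-streams are derived with fixed offsets so the cohort, the gene-set
library and the external validation cohort are independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetLibrary,
    SampleMetadata,
)


class ConfigError(ValueError):
    """A cohort configuration field is invalid."""


@dataclass
class CohortConfig:
    """Generative parameters for a synthetic cohort.

    Defaults describe the reference study conditions: 160 participants,
    2,000 genes, 4 latent clusters of equal size, 25 discriminative
    genes per cluster at |log2FC| 1.5 over unit log2 noise, 50
    covariate-responsive genes, and FEV1 driven by 5 planted genes at
    roughly 70% explained variance.
    """

    n_samples: int = 160
    n_genes: int = 2000
    n_clusters: int = 4
    cluster_proportions: tuple[float, ...] | None = None
    n_de_genes_per_cluster: int = 25
    de_gene_counts: tuple[int, ...] | None = None
    de_effect: float = 1.5
    covariate_effect: float = 1.0
    n_covariate_genes: int = 50
    noise_sd: float = 1.0
    fev1_coef: dict[str, float] | None = None
    fev1_noise_sd: float = 8.6
    fev1_intercept: float = 85.0
    sa_cluster_fev1_offset: float = -15.0
    floor_value: float = 2.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    severity_confusion: float = 0.15
    # gene-set library shape
    gs_set_size: int = 50
    gs_overlap: int = 20
    gs_n_null: int = 10
    # external (validation) cohort
    n_external: int = 65
    platform_scale: float = 1.1
    platform_offset: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_clusters", "n_covariate_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple(
                1.0 / self.n_clusters for _ in range(self.n_clusters)
            )
        self.cluster_proportions = tuple(float(p) for p in self.cluster_proportions)
        if len(self.cluster_proportions) != self.n_clusters:
            raise ConfigError(
                "cluster_proportions length "
                f"{len(self.cluster_proportions)} != n_clusters {self.n_clusters}"
            )
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-12:
            raise ConfigError("cluster_proportions must sum to 1")
        if any(p <= 0 for p in self.cluster_proportions):
            raise ConfigError("cluster_proportions must be positive")
        if self.de_gene_counts is None:
            self.de_gene_counts = tuple(
                self.n_de_genes_per_cluster for _ in range(self.n_clusters)
            )
        self.de_gene_counts = tuple(int(c) for c in self.de_gene_counts)
        if len(self.de_gene_counts) != self.n_clusters:
            raise ConfigError("de_gene_counts length != n_clusters")
        if any(c <= 0 for c in self.de_gene_counts):
            raise ConfigError("de_gene_counts entries must be positive")
        if sum(self.de_gene_counts) + self.n_covariate_genes > self.n_genes:
            raise ConfigError(
                "n_genes too small for requested DE + covariate genes "
                f"({sum(self.de_gene_counts)} + {self.n_covariate_genes} "
                f"> {self.n_genes})"
            )
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0 <= self.severity_confusion < 1:
            raise ConfigError("severity_confusion must be in [0, 1)")
        if self.gs_set_size > self.n_genes:
            raise ConfigError("gs_set_size exceeds n_genes")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    cluster_labels: dict[str, int]
    de_genes: dict[int, dict[str, int]]  # cluster -> gene -> sign (+1/-1)
    covariate_genes: dict[str, str]  # gene -> covariate name ('sex'|'ocs')
    fev1_coef: dict[str, float]
    signature_genes: dict[str, list[str]]
    enriched_terms: dict[str, int] = field(default_factory=dict)
    # archetype information for external-cohort generation
    baseline_means: dict[str, float] = field(default_factory=dict)

    def labels_array(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.cluster_labels[s] for s in sample_ids])

    @property
    def all_de_genes(self) -> set[str]:
        return {g for sub in self.de_genes.values() for g in sub}

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["de_genes"] = {str(k): v for k, v in payload["de_genes"].items()}
        payload["enriched_terms"] = {k: int(v) for k, v in payload["enriched_terms"].items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["de_genes"] = {int(k): v for k, v in payload["de_genes"].items()}
        return cls(**payload)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n: int, prefix: str = "S") -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _cluster_assignment(n: int, proportions: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Deterministic counts from proportions, randomly permuted over samples."""
    counts = np.floor(np.asarray(proportions) * n).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = np.asarray(proportions) * n - counts
    for i in np.argsort(-frac)[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(1, len(proportions) + 1), counts)
    rng.shuffle(labels)
    return labels


def _ics_dose(severity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ordinal inhaled-corticosteroid dose 0..4, rising with severity
    but overlapping between classes (dose escalation is individual)."""
    centers = np.select(
        [severity == "HC", severity == "MMA"], [0.5, 2.0], default=3.5
    )
    return np.clip(np.round(rng.normal(centers, 1.0)), 0, 4).astype(int)


def _severity_from_cluster(
    labels: np.ndarray, k: int, confusion: float, rng: np.random.Generator
) -> np.ndarray:
    """Noisy map: cluster 1 -> HC, cluster k -> SA, middle -> MMA."""
    base = np.where(labels == 1, "HC", np.where(labels == k, "SA", "MMA"))
    out = base.copy()
    flip = rng.random(labels.size) < confusion
    classes = np.array(["HC", "MMA", "SA"])
    for i in np.where(flip)[0]:
        others = classes[classes != base[i]]
        out[i] = rng.choice(others)
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, GroundTruth]:
    """Generate one synthetic cohort with ground truth.

    Returns the log2 expression matrix (genes x samples), the sample
    metadata table and the planted structure.  Deterministic for a
    given config (including its seed).
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])

    genes = _gene_ids(cfg.n_genes)
    samples = _sample_ids(cfg.n_samples)
    k = cfg.n_clusters

    labels = _cluster_assignment(cfg.n_samples, cfg.cluster_proportions, rng)

    # --- gene roles -------------------------------------------------------
    n_de_total = sum(cfg.de_gene_counts)
    special = rng.choice(cfg.n_genes, size=n_de_total + cfg.n_covariate_genes, replace=False)
    de_idx = special[:n_de_total]
    cov_idx = special[n_de_total:]

    de_genes: dict[int, dict[str, int]] = {}
    pos = 0
    de_sign = np.zeros(cfg.n_genes)
    de_cluster = np.zeros(cfg.n_genes, dtype=int)
    for c in range(1, k + 1):
        count = cfg.de_gene_counts[c - 1]
        idx = de_idx[pos : pos + count]
        pos += count
        signs = rng.choice([-1, 1], size=count)
        signs[0] = 1  # every cluster keeps at least one up-regulated gene
        de_genes[c] = {genes[i]: int(s) for i, s in zip(idx, signs)}
        de_sign[idx] = signs
        de_cluster[idx] = c

    half = cfg.n_covariate_genes // 2
    covariate_genes = {genes[i]: "sex" for i in cov_idx[:half]}
    covariate_genes.update({genes[i]: "ocs" for i in cov_idx[half:]})

    # --- covariates -------------------------------------------------------
    sex = np.where(rng.random(cfg.n_samples) < 0.5, "F", "M")
    severity = _severity_from_cluster(labels, k, cfg.severity_confusion, rng)
    ocs_prob = np.where(labels == k, 0.6, 0.05)
    ocs = rng.random(cfg.n_samples) < ocs_prob
    ics = _ics_dose(severity, rng)

    # --- expression -------------------------------------------------------
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    x = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    in_cluster = de_cluster[:, None] == labels[None, :]
    x += np.where(in_cluster, (de_sign * cfg.de_effect)[:, None], 0.0)
    sex_rows = np.array([g in covariate_genes and covariate_genes[g] == "sex" for g in genes])
    ocs_rows = np.array([g in covariate_genes and covariate_genes[g] == "ocs" for g in genes])
    x[sex_rows] += cfg.covariate_effect * (sex == "M")[None, :]
    x[ocs_rows] += cfg.covariate_effect * ocs[None, :]
    np.maximum(x, cfg.floor_value, out=x)

    # --- FEV1 -------------------------------------------------------------
    fev1_coef = cfg.fev1_coef
    if fev1_coef is None:
        fev1_coef = _default_fev1_coef(de_genes, k)
    missing = [g for g in fev1_coef if g not in genes]
    if missing:
        raise ConfigError(f"fev1_coef references unknown genes: {missing}")
    gene_pos = {g: i for i, g in enumerate(genes)}
    y = np.full(cfg.n_samples, cfg.fev1_intercept)
    y += cfg.sa_cluster_fev1_offset * (labels == k)
    for g, beta in fev1_coef.items():
        row = x[gene_pos[g]]
        sd = row.std()
        if sd > 0:
            y += beta * (row - row.mean()) / sd
    y += rng.normal(0.0, cfg.fev1_noise_sd, size=cfg.n_samples)
    y = np.clip(y, 0.0, 200.0)

    # --- assemble ---------------------------------------------------------
    expr = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples))
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "severity": severity,
                "sex": sex,
                "ics_dose": ics,
                "ocs_use": ocs,
                "fev1_pct": np.round(y, 4),
                "cluster": labels,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = GroundTruth(
        cluster_labels={s: int(c) for s, c in zip(samples, labels)},
        de_genes=de_genes,
        covariate_genes=covariate_genes,
        fev1_coef={g: float(b) for g, b in fev1_coef.items()},
        signature_genes=_signature_genes(de_genes, k),
        baseline_means={g: float(m) for g, m in zip(genes, mu)},
    )
    return expr, meta, truth


def _default_fev1_coef(de_genes: Mapping[int, Mapping[str, int]], k: int) -> dict[str, float]:
    """Five planted coefficients on cluster-discriminative genes.

    Standardized effect sizes ~(0.42, 0.40, 0.36, 0.33, 0.31) scaled to
    percent-predicted units (x15); negatives sit on severe-cluster
    genes, mirroring deleterious transcripts.
    """
    betas = [-6.3, -6.0, 5.4, -4.95, 4.65]
    donors = [k, k, 2, k - 1 if k > 1 else k, 2]
    coef: dict[str, float] = {}
    used: set[str] = set()
    for beta, c in zip(betas, donors):
        cands = [g for g in sorted(de_genes.get(c, {})) if g not in used]
        if not cands:  # fall back to any unused planted gene
            cands = [g for cc in sorted(de_genes) for g in sorted(de_genes[cc]) if g not in used]
        g = cands[0]
        used.add(g)
        coef[g] = beta
    return coef


def _signature_genes(de_genes: Mapping[int, Mapping[str, int]], k: int) -> dict[str, list[str]]:
    """Planted stand-ins for T2/IL-13/IFN-gamma response signatures."""

    def ups(c: int) -> list[str]:
        return sorted(g for g, s in de_genes.get(c, {}).items() if s > 0)

    t2_donor = min(3, k)  # the T2-high cluster analogue
    t2_up = ups(t2_donor)
    sa_up = ups(k)
    return {
        "T2": t2_up[:3] or t2_up or sa_up[:3],
        "IL13": (t2_up[3:6] or t2_up[:3] or sa_up[:3]),
        "IFNG": sa_up[:3] or sa_up,
    }


def generate_gene_set_library(
    config: CohortConfig, truth: GroundTruth
) -> GeneSetLibrary:
    """Build a typed gene-set library with recoverable structure.

    For each cluster c: a biological-process set ``BP_cluster{c}`` seeded
    with that cluster's planted up-regulated genes (random padding to
    ``gs_set_size``), and a TF-target set ``TFT_cluster{c}`` sharing
    ``gs_overlap`` members with the BP set so the overlap network can
    recover BP-TFT edges.  Plus ``gs_n_null`` random null sets.
    Records term->cluster assignments in ``truth.enriched_terms``.
    """
    cfg = config
    if cfg.gs_set_size > cfg.n_genes:
        raise ConfigError("gs_set_size exceeds n_genes")
    rng = np.random.default_rng([cfg.seed, 1])
    genes = _gene_ids(cfg.n_genes)
    lib = GeneSetLibrary()
    truth.enriched_terms = {}

    for c in sorted(truth.de_genes):
        planted_up = sorted(g for g, s in truth.de_genes[c].items() if s > 0)
        members = list(planted_up[: cfg.gs_set_size])
        pool = [g for g in genes if g not in members]
        pad = rng.choice(len(pool), size=cfg.gs_set_size - len(members), replace=False)
        members += [pool[i] for i in sorted(pad)]
        bp_name = f"BP_cluster{c}"
        lib.add(GeneSet(bp_name, "BP", tuple(members)))
        truth.enriched_terms[bp_name] = c

        n_shared = min(cfg.gs_overlap, len(members))
        shared_idx = rng.choice(len(members), size=n_shared, replace=False)
        shared = [members[i] for i in sorted(shared_idx)]
        pool_t = [g for g in genes if g not in members]
        pad_t = rng.choice(len(pool_t), size=cfg.gs_set_size - n_shared, replace=False)
        tft_members = shared + [pool_t[i] for i in sorted(pad_t)]
        tft_name = f"TFT_cluster{c}"
        lib.add(GeneSet(tft_name, "TFT", tuple(tft_members)))
        truth.enriched_terms[tft_name] = c

    for j in range(1, cfg.gs_n_null + 1):
        idx = rng.choice(cfg.n_genes, size=cfg.gs_set_size, replace=False)
        lib.add(GeneSet(f"NULL_{j:02d}", "OTHER", tuple(genes[i] for i in sorted(idx))))
    return lib


def generate_external_cohort(
    truth: GroundTruth, config: CohortConfig
) -> tuple[ExpressionMatrix, SampleMetadata, GroundTruth]:
    """Draw a validation cohort from the same latent clusters.

    New samples come from the training archetypes (baseline mean plus
    planted cluster shifts) but through an affine platform shift
    (``platform_scale``/``platform_offset``) with independent noise —
    emulating an RNA-seq validation cohort for a microarray-trained
    model.  Sample IDs are disjoint from the training cohort.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 2])
    genes = sorted(truth.baseline_means, key=lambda g: g)
    if not genes:
        raise ConfigError("ground truth carries no archetypes (baseline_means empty)")
    genes = _gene_ids(len(genes))
    mu = np.array([truth.baseline_means[g] for g in genes])
    k = max(truth.de_genes) if truth.de_genes else 1
    n = cfg.n_external

    samples = _sample_ids(n, prefix="V")
    labels = _cluster_assignment(n, cfg.cluster_proportions, rng)

    de_sign = np.zeros(len(genes))
    de_cluster = np.zeros(len(genes), dtype=int)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for c, sub in truth.de_genes.items():
        for g, s in sub.items():
            de_sign[gene_pos[g]] = s
            de_cluster[gene_pos[g]] = c

    x = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))
    in_cluster = de_cluster[:, None] == labels[None, :]
    x += np.where(in_cluster, (de_sign * cfg.de_effect)[:, None], 0.0)

    sex = np.where(rng.random(n) < 0.5, "F", "M")
    severity = _severity_from_cluster(labels, k, cfg.severity_confusion, rng)
    ocs = rng.random(n) < np.where(labels == k, 0.6, 0.05)
    ics = _ics_dose(severity, rng)
    sex_rows = np.array([truth.covariate_genes.get(g) == "sex" for g in genes])
    ocs_rows = np.array([truth.covariate_genes.get(g) == "ocs" for g in genes])
    x[sex_rows] += cfg.covariate_effect * (sex == "M")[None, :]
    x[ocs_rows] += cfg.covariate_effect * ocs[None, :]

    # platform shift, then floor on the shifted scale
    x = cfg.platform_offset + cfg.platform_scale * x
    floor = cfg.platform_offset + cfg.platform_scale * cfg.floor_value
    np.maximum(x, floor, out=x)

    y = np.full(n, cfg.fev1_intercept) + cfg.sa_cluster_fev1_offset * (labels == k)
    for g, beta in truth.fev1_coef.items():
        row = x[gene_pos[g]]
        sd = row.std()
        if sd > 0:
            y += beta * (row - row.mean()) / sd
    y += rng.normal(0.0, cfg.fev1_noise_sd, size=n)
    y = np.clip(y, 0.0, 200.0)

    expr = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples))
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "severity": severity,
                "sex": sex,
                "ics_dose": ics,
                "ocs_use": ocs,
                "fev1_pct": np.round(y, 4),
                "cluster": labels,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    ext_truth = GroundTruth(
        cluster_labels={s: int(c) for s, c in zip(samples, labels)},
        de_genes=truth.de_genes,
        covariate_genes=truth.covariate_genes,
        fev1_coef=truth.fev1_coef,
        signature_genes=truth.signature_genes,
        enriched_terms=truth.enriched_terms,
    )
    return expr, meta, ext_truth
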