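"""End-to-end pipeline orchestration.

``run_all`` executes the full analysis in dependency order on one
YAML/JSON config — simulate (or load) a cohort, normalize, call
severity-differential genes, cluster participants, call
cluster-specific genes, run enrichment and the term-overlap network,
distill the sparse classifier signature, predict the external cohort,
model FEV1 with the elastic net, and score the planted signatures —
writing every artifact plus a reproducibility manifest (config hash,
seeds, versions, per-stage row counts, artifact checksums).  A rerun
with the same config reproduces the manifest bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import compare_partitions, kmeans_cluster, select_k_gap
from .cohort import (
    CohortConfig,
    generate_cohort,
    generate_external_cohort,
    generate_gene_set_library,
)
from .diffexpr import (
    DesignMatrix,
    build_design,
    cluster_specific_genes,
    fit_moderated_lm,
    ocs_contrast_overlap,
    severity_de_genes,
)
from .distill import distill_signature, predict_clusters
from .enrich import gsea_library, hypergeom_enrich
from .fev1 import coefficient_gene_validation, fit_elastic_net, validate_predictions
from .io import (
    read_expression,
    read_gmt,
    read_metadata,
    write_expression,
    write_gmt,
    write_metadata,
)
from .network import build_overlap_network, export_network, link_communities
from .normalize import normalize_cyclic_loess
from .scores import score_signature

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_DEFAULTS: dict[str, dict[str, Any]] = {
    "normalize": {"enabled": True, "method": "fast", "n_cycles": 3, "span": 0.7},
    "de": {"alpha": 0.05},
    "cluster": {"k": "auto", "k_range": [1, 8], "n_refs": 50, "n_starts": 25},
    "enrich": {"n_perm": 1000, "min_size": 5, "max_size": 500},
    "network": {"p_threshold": 1e-8},
    "distill": {"n_per_pc_max": 25, "folds": 5, "repeats": 10, "loess_span": 0.75},
    "fev1": {"alpha": 0.5},
}


@dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    simulate: dict[str, Any] | None = None
    paths: dict[str, str] | None = None
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def stage(self, name: str) -> dict[str, Any]:
        merged = dict(_DEFAULTS.get(name, {}))
        merged.update(self.stages.get(name, {}))
        return merged

    def canonical(self) -> str:
        payload = {
            "seed": self.seed,
            "simulate": self.simulate,
            "paths": self.paths,
            "stages": {k: self.stage(k) for k in _DEFAULTS},
        }
        return json.dumps(payload, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise PipelineConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise PipelineConfigError(f"{path}: config must be a mapping")
    errors = validate_config_dict(raw)
    if errors:
        raise PipelineConfigError("; ".join(errors))
    stages = {k: v for k, v in raw.items() if k in _DEFAULTS and isinstance(v, dict)}
    return PipelineConfig(
        seed=int(raw["seed"]),
        out_dir=Path(raw.get("out_dir", "pipeline_out")),
        simulate=raw.get("simulate"),
        paths=raw.get("paths"),
        stages=stages,
    )


def validate_config_dict(raw: dict[str, Any]) -> list[str]:
    """Field-level validation; returns a list of error messages."""
    errors: list[str] = []
    if "seed" not in raw:
        errors.append("missing required field 'seed'")
    elif not isinstance(raw["seed"], int):
        errors.append(f"seed must be an integer, got {raw['seed']!r}")
    if raw.get("simulate") is None and raw.get("paths") is None:
        errors.append("either a 'simulate' block or a 'paths' block is required")
    if raw.get("paths") is not None:
        for key in ("expr", "meta", "gmt"):
            p = raw["paths"].get(key)
            if p is None:
                errors.append(f"paths.{key} is required")
            elif not Path(p).exists():
                errors.append(f"paths.{key}: {p} does not exist")
    cl = raw.get("cluster", {})
    if "k_range" in cl:
        kr = cl["k_range"]
        if (
            not isinstance(kr, (list, tuple))
            or len(kr) != 2
            or not all(isinstance(v, int) for v in kr)
            or kr[0] < 1
            or kr[1] < kr[0]
        ):
            errors.append(f"cluster.k_range must be [lo>=1, hi>=lo], got {kr!r}")
    de = raw.get("de", {})
    if "alpha" in de and not (0 < de["alpha"] <= 1):
        errors.append(f"de.alpha must lie in (0, 1], got {de['alpha']!r}")
    fv = raw.get("fev1", {})
    if "alpha" in fv and not (0 <= fv["alpha"] <= 1):
        errors.append(f"fev1.alpha must lie in [0, 1], got {fv['alpha']!r}")
    en = raw.get("enrich", {})
    if "n_perm" in en and (not isinstance(en["n_perm"], int) or en["n_perm"] < 10):
        errors.append(f"enrich.n_perm must be an integer >= 10, got {en['n_perm']!r}")
    return errors


def validate_config(path: str | Path) -> list[str]:
    """Validate a config file, returning error messages (empty = valid)."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        return [f"cannot parse {path}: {exc}"]
    if not isinstance(raw, dict):
        return [f"{path}: config must be a mapping"]
    return validate_config_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj: Any, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def run_all(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "versions": {
            "becdistill": __version__,
            "python": ".".join(map(str, sys.version_info[:3])),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "artifacts": {},
    }
    counts = manifest["stages"]

    def record(name: str, **info: Any) -> None:
        counts[name] = info
        logger.info("stage %s done: %s", name, info)

    def run_stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            _write_json(manifest, out / "manifest.partial.json")
            raise PipelineStageError(name, exc) from exc

    seed = config.seed

    # ---- stage 1: data ----------------------------------------------------
    def stage_data():
        if config.simulate is not None:
            cc = CohortConfig(**{**config.simulate, "seed": seed})
            expr, meta, truth = generate_cohort(cc)
            library = generate_gene_set_library(cc, truth)
            ext_expr, ext_meta, ext_truth = generate_external_cohort(truth, cc)
            write_expression(expr, out / "expression.tsv")
            write_metadata(meta, out / "metadata.tsv")
            write_gmt(library, out / "library.gmt")
            truth.to_json(out / "truth.json")
            write_expression(ext_expr, out / "external_expression.tsv")
            write_metadata(ext_meta, out / "external_metadata.tsv")
            return cc, expr, meta, truth, library, ext_expr, ext_meta, ext_truth
        paths = config.paths
        expr = read_expression(paths["expr"])
        meta = read_metadata(paths["meta"]).aligned_to(expr.sample_ids)
        library = read_gmt(paths["gmt"])
        return None, expr, meta, None, library, None, None, None

    cc, expr, meta, truth, library, ext_expr, ext_meta, ext_truth = run_stage(
        "data", stage_data
    )
    record("data", n_genes=expr.n_genes, n_samples=expr.n_samples, n_sets=len(library))

    # ---- stage 2: normalization -------------------------------------------
    ncfg = config.stage("normalize")
    if ncfg["enabled"]:
        floor = cc.floor_value if cc is not None else None
        expr = run_stage(
            "normalize",
            lambda: normalize_cyclic_loess(
                expr,
                floor_ref=floor,
                span=ncfg["span"],
                n_cycles=ncfg["n_cycles"],
                method=ncfg["method"],
                seed=seed,
            ),
        )
        write_expression(expr, out / "normalized.tsv")
        record("normalize", n_genes=expr.n_genes, method=ncfg["method"])

    # ---- stage 3: severity DE ---------------------------------------------
    alpha = config.stage("de")["alpha"]
    sev = run_stage("severity_de", lambda: severity_de_genes(expr, meta, alpha=alpha))
    clustering_genes = sorted(sev.union)
    sev.fit.omnibus.to_csv(out / "severity_de.tsv", sep="\t", float_format="%.8g")
    _write_json(
        {
            "venn": sev.venn,
            "union": clustering_genes,
            "per_class": {
                c: {d: sorted(v) for d, v in dirs.items()}
                for c, dirs in sev.per_class.items()
            },
        },
        out / "severity_genes.json",
    )
    record("severity_de", n_tested=sev.n_tested, n_union=len(clustering_genes))
    if not clustering_genes:
        raise PipelineStageError("severity_de", RuntimeError("no differential genes"))

    # ---- stage 4: clustering ----------------------------------------------
    ccfg = config.stage("cluster")
    sub = expr.subset_genes(clustering_genes)

    def stage_cluster():
        if ccfg["k"] == "auto":
            lo, hi = ccfg["k_range"]
            hi = min(hi, sub.n_samples - 1)
            k_star, curve = select_k_gap(
                sub, range(lo, hi + 1), n_refs=ccfg["n_refs"], seed=seed
            )
        else:
            k_star, curve = int(ccfg["k"]), None
        assign = kmeans_cluster(
            sub, k_star, seed=seed, n_starts=ccfg["n_starts"], gap_curve=curve
        )
        return assign

    assign = run_stage("cluster", stage_cluster)
    assign.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    if assign.gap_curve is not None:
        assign.gap_curve.to_csv(out / "gap_curve.tsv", sep="\t", index=False, float_format="%.8g")
    record("cluster", k=assign.k, inertia=round(assign.inertia, 6))

    # ---- stage 5: cluster-specific DE --------------------------------------
    cluster_sets = run_stage(
        "cluster_de",
        lambda: cluster_specific_genes(expr, assign.labels, meta, alpha=alpha),
    )
    _write_json(
        {str(c): {d: sorted(v) for d, v in dirs.items()} for c, dirs in cluster_sets.items()},
        out / "cluster_genes.json",
    )
    ocs_n, ocs_overlap, _ = run_stage(
        "cluster_de", lambda: ocs_contrast_overlap(expr, meta, clustering_genes, alpha=alpha)
    )
    record(
        "cluster_de",
        per_cluster={str(c): len(v["up"]) + len(v["down"]) for c, v in cluster_sets.items()},
        ocs_genes=ocs_n,
        ocs_overlap_with_clustering=ocs_overlap,
    )

    # ---- stage 6: enrichment ----------------------------------------------
    ecfg = config.stage("enrich")
    universe = expr.gene_ids

    def stage_enrich():
        hyper_rows = []
        gsea_rows = []
        design = build_design(meta, covariates=())
        labels_arr = assign.labels_array(expr.sample_ids)
        for c in sorted(cluster_sets):
            up = sorted(cluster_sets[c]["up"])
            if up:
                tbl = hypergeom_enrich(up, library, universe)
                tbl = tbl.assign(cluster=c)
                hyper_rows.append(tbl)
            # ranking statistic: moderated t of cluster-vs-rest
            cols = {
                "in_c": (labels_arr == c).astype(float),
                "intercept": np.ones(labels_arr.size),
            }
            dm = DesignMatrix(pd.DataFrame(cols, index=meta.table.index))
            dm.add_contrast("c_vs_rest", {"in_c": 1.0})
            fit = fit_moderated_lm(expr, dm)
            ranks = fit.tables["c_vs_rest"]["t"]
            gt = gsea_library(
                ranks,
                library,
                n_perm=ecfg["n_perm"],
                seed=seed + c,
                min_size=ecfg["min_size"],
                max_size=ecfg["max_size"],
            )
            gsea_rows.append(gt.assign(cluster=c))
        hyper = pd.concat(hyper_rows) if hyper_rows else pd.DataFrame()
        gsea = pd.concat(gsea_rows) if gsea_rows else pd.DataFrame()
        return hyper, gsea

    hyper, gsea = run_stage("enrich", stage_enrich)
    if len(hyper):
        hyper_out = hyper.copy()
        hyper_out["enriched_genes"] = hyper_out["enriched_genes"].map(",".join)
        hyper_out.to_csv(out / "enrichment_hyper.tsv", sep="\t", float_format="%.8g")
    gsea.to_csv(out / "enrichment_gsea.tsv", sep="\t", float_format="%.8g")
    record("enrich", n_hyper=len(hyper), n_gsea=len(gsea))

    # ---- stage 7: term network ---------------------------------------------
    pthr = config.stage("network")["p_threshold"]

    def stage_network():
        # network for the most severe cluster (highest SA fraction)
        sa_frac = {
            c: float(
                (meta.table.loc[np.array(expr.sample_ids)[assign.labels_array(expr.sample_ids) == c], "severity"] == "SA").mean()
            )
            for c in sorted(cluster_sets)
        }
        target = max(sa_frac, key=lambda c: (sa_frac[c], c))
        sub_h = hyper[hyper["cluster"] == target] if len(hyper) else pd.DataFrame()
        sig = sub_h[(sub_h["p"] < alpha) & (sub_h["q"] < alpha)] if len(sub_h) else sub_h
        bp = sig[sig["type"] == "BP"] if len(sig) else pd.DataFrame()
        tft = sig[sig["type"] == "TFT"] if len(sig) else pd.DataFrame()
        net = build_overlap_network(bp, tft, len(universe), p_threshold=pthr)
        if net.n_edges:
            link_communities(net)
        return target, net

    target_cluster, net = run_stage("network", stage_network)
    export_network(net, out / "network.graphml", "graphml")
    export_network(net, out / "network_edges.tsv", "edge_tsv")
    record(
        "network",
        cluster=target_cluster,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        partition_density=net.partition_density,
    )

    # ---- stage 8: signature distillation ------------------------------------
    dcfg = config.stage("distill")

    def stage_distill():
        grid = range(1, dcfg["n_per_pc_max"] + 1)
        return distill_signature(
            expr,
            assign.labels,
            clustering_genes,
            n_per_pc_grid=grid,
            folds=dcfg["folds"],
            repeats=dcfg["repeats"],
            loess_span=dcfg["loess_span"],
            seed=seed,
        )

    model, trace, chosen = run_stage("distill", stage_distill)
    model.to_json(out / "model.json")
    trace.table.to_csv(out / "trace.tsv", sep="\t", index=False, float_format="%.8g")
    record("distill", chosen_n_per_pc=chosen, n_signature_genes=len(model.genes))

    # ---- stage 9: external prediction ---------------------------------------
    if ext_expr is not None:
        def stage_predict():
            pred = predict_clusters(model, ext_expr)
            conc, ari = compare_partitions(
                pred.labels, ext_truth.cluster_labels, sample_ids=ext_expr.sample_ids
            )
            return pred, conc, ari

        pred, conc, ari = run_stage("predict", stage_predict)
        pred.to_frame().to_csv(out / "external_prediction.tsv", sep="\t")
        record("predict", concordance=round(conc, 6), ari=round(ari, 6))

    # ---- stage 10: FEV1 elastic net -----------------------------------------
    fcfg = config.stage("fev1")

    def stage_fev1():
        en = fit_elastic_net(
            expr, meta.table["fev1_pct"], genes=model.genes, alpha=fcfg["alpha"], seed=seed
        )
        rho, p = validate_predictions(en, meta.table["fev1_pct"])
        per_gene = coefficient_gene_validation(en, expr, meta.table["fev1_pct"])
        return en, rho, p, per_gene

    en, rho, p, per_gene = run_stage("fev1", stage_fev1)
    en.summary().to_csv(out / "en_coefficients.tsv", sep="\t", float_format="%.8g")
    en.loo_predictions.rename("loo_prediction").to_csv(
        out / "en_predictions.tsv", sep="\t", index_label="sample_id", float_format="%.8g"
    )
    per_gene.to_csv(out / "en_gene_validation.tsv", sep="\t", float_format="%.8g")
    record(
        "fev1",
        n_nonzero=len(en.nonzero_genes),
        loo_spearman_rho=round(rho, 6),
        loo_spearman_p=float(f"{p:.6g}"),
    )

    # ---- stage 11: signature scores ------------------------------------------
    def stage_scores():
        sig_lists = truth.signature_genes if truth is not None else {}
        rows = {}
        for name, genes in sorted(sig_lists.items()):
            present = [g for g in genes if g in expr.data.index]
            if not present:
                continue
            rows[name] = score_signature(expr, present, "geometric_mean", name).scores
        return pd.DataFrame(rows)

    score_table = run_stage("scores", stage_scores)
    score_table.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id", float_format="%.8g")
    record("scores", n_signatures=score_table.shape[1])

    # ---- manifest -------------------------------------------------------------
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name not in ("manifest.json", "manifest.partial.json", "run.log"):
            manifest["artifacts"][f.name] = _sha256(f)
    _write_json(manifest, out / "manifest.json")
    return out
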