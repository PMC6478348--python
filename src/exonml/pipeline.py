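"""End-to-end orchestration of the analysis stages.

Each stage reads its inputs from the config's paths, runs the library
code, and writes TSV/JSON reports into the output directory.  Every
report directory carries a ``run_info.json`` with the config hash and
the stage seeds, so a finished run is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster, deu, enrichment, features, pca, simulate, som
from .io import (
    DataError,
    ExonCountTable,
    read_conditions,
    read_gmt,
    read_meta_map,
    read_target_map,
    write_conditions,
    write_gmt,
    write_meta_map,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_deu", "run_ml", "run_enrichment"]


@dataclass
class PipelineConfig:
    output_dir: str = "results"
    counts_path: str | None = None
    conditions_path: str | None = None
    catalog_path: str | None = None
    meta_map_path: str | None = None
    target_map_path: str | None = None
    fdr: float = 0.1
    top_n: int = 50
    kmax: int = 10
    kmeans_starts: int = 50
    null_reps: int = 1000
    gap_B: int = 100
    hopkins_repeats: int = 100
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.kmax < 2 or self.top_n < 1 or self.kmeans_starts < 1 or self.null_reps < 1:
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        # hash the scientific parameters only, not filesystem locations
        payload = {k: v for k, v in asdict(self).items()
                   if k != "output_dir" and not k.endswith("_path")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = int(hashlib.sha256(f"{self.seed}:{stage}".encode()).hexdigest(), 16)
        return h % (2**31 - 1)


def _outdir(config: PipelineConfig, stage: str) -> Path:
    out = Path(config.output_dir) / stage
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_run_info(out: Path, config: PipelineConfig, stage: str, extra: dict | None = None) -> None:
    info = {"stage": stage, "config_hash": config.config_hash(), "seed": config.stage_seed(stage)}
    info.update(extra or {})
    (out / "run_info.json").write_text(json.dumps(info, indent=2, sort_keys=True) + "\n")


def run_simulate(config: PipelineConfig) -> Path:
    """Emit a full synthetic dataset: counts, truth, conditions, catalog."""
    out = _outdir(config, "simulate")
    seed = config.stage_seed("simulate")
    sim_cfg = simulate.SimulationConfig(**{**config.simulation, "seed": seed})
    counts, truth = simulate.generate_exon_counts(sim_cfg)
    counts.write(out / "exon_counts.tsv")
    write_conditions(counts.conditions, out / "conditions.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    n_terms = max(10, sim_cfg.n_genes // 5)
    catalog = simulate.generate_annotation_catalog(
        n_genes=sim_cfg.n_genes, n_terms=n_terms,
        n_meta_groups=min(20, n_terms), seed=seed,
    )
    write_gmt(catalog.terms, out / "catalog.gmt")
    write_meta_map(catalog.meta_map, out / "meta_map.tsv")
    _write_run_info(out, config, "simulate", {"n_genes": sim_cfg.n_genes})
    logger.info("simulated %d exons for %d genes", len(counts.table), sim_cfg.n_genes)
    return out


def run_deu(config: PipelineConfig) -> Path:
    """Differential exon usage: full table plus the FDR-filtered table."""
    out = _outdir(config, "deu")
    counts_path = config.counts_path or str(Path(config.output_dir) / "simulate" / "exon_counts.tsv")
    cond_path = config.conditions_path or str(Path(config.output_dir) / "simulate" / "conditions.tsv")
    if not Path(counts_path).exists():
        raise DataError(f"counts file not found: {counts_path}")
    conditions = read_conditions(cond_path)
    counts = ExonCountTable.read(counts_path, conditions)
    results = deu.test_differential_usage(counts)
    table = deu.results_to_frame(results)
    table.to_csv(out / "deu_full.tsv", sep="\t", index=False)
    sig = deu.filter_significant(results, fdr=config.fdr)
    deu.results_to_frame(sig).to_csv(out / "deu_significant.tsv", sep="\t", index=False)
    n_up = sum(1 for r in sig if r.log2fc < 0)  # up under alcohol = negative fold change
    n_down = len(sig) - n_up
    genes = len({r.gene_id for r in sig})
    logger.info(
        "%d significant exons (fdr<%.2g): %d up / %d down under alcohol, %d genes",
        len(sig), config.fdr, n_up, n_down, genes,
    )
    _write_run_info(out, config, "deu", {"n_significant": len(sig), "n_up_alcohol": n_up,
                                         "n_down_alcohol": n_down, "n_genes": genes})
    return out


def run_ml(config: PipelineConfig) -> Path:
    """Unsupervised stage: PCA contributions, HCPC, k-selection, k-means,
    fuzzy memberships, Hopkins and VAT reports."""
    out = _outdir(config, "ml")
    seed = config.stage_seed("ml")
    deu_path = Path(config.output_dir) / "deu" / "deu_significant.tsv"
    if not deu_path.exists():
        raise DataError(f"DEU table not found: {deu_path}; run the deu stage first")
    table = pd.read_csv(deu_path, sep="\t")
    if len(table) < 3:
        logger.warning("too few significant exons (%d); ml stage skipped", len(table))
        _write_run_info(out, config, "ml", {"skipped": True})
        return out
    value_cols = [c for c in table.columns if c.startswith(("norm_", "usage_"))]
    data = table.set_index(table["gene_id"] + ":" + table["exon_id"])[value_cols]
    fm_raw = features.FeatureMatrix(data=data)
    fm = features.scale_matrix(fm_raw)

    p = pca.run_pca(fm)
    p.eigenvalues.to_csv(out / "pca_eigenvalues.tsv", sep="\t")
    top = pca.top_contributors(p, dims=(1, 2), n=config.top_n)
    top.to_csv(out / "top_contributors.tsv", sep="\t")

    hc = cluster.hcpc(p, kmax=config.kmax)
    hc.labels.to_csv(out / "hcpc_labels.tsv", sep="\t")

    ksel = cluster.select_k(
        fm, kmax=min(config.kmax, fm.n_obs - 1), n_starts=config.kmeans_starts,
        gap_B=config.gap_B, seed=seed,
    )
    ksel.table.to_csv(out / "k_selection.tsv", sep="\t")
    km = cluster.kmeans_multi(fm, k=ksel.consensus_k, n_starts=config.kmeans_starts, seed=seed)
    km.labels.to_csv(out / "kmeans_labels.tsv", sep="\t")
    fcm = cluster.fuzzy_cmeans(fm, k=ksel.consensus_k, seed=seed)
    fcm.membership.to_csv(out / "fuzzy_membership.tsv", sep="\t")

    hop = cluster.hopkins(fm, repeats=config.hopkins_repeats, seed=seed)
    v = cluster.vat(fm)
    pd.DataFrame(v.ordered_dissimilarity, index=v.ordering, columns=v.ordering).to_csv(
        out / "vat_matrix.tsv", sep="\t"
    )
    summary = {
        "hopkins": hop.H, "hopkins_m": hop.m, "hopkins_repeats": hop.repeats,
        "elbow_k": ksel.elbow_k, "silhouette_k": ksel.silhouette_k,
        "gap_k": ksel.gap_k, "consensus_k": ksel.consensus_k,
        "kmeans_wss": km.total_wss, "hcpc_k": hc.k,
    }
    (out / "ml_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    try:
        sm = som.som_fit(fm, seed=seed, n_partitions=hc.k)
        sm.training_curve.to_csv(out / "som_training_curve.tsv", sep="\t")
        sm.partition.to_csv(out / "som_partition.tsv", sep="\t")
    except som.InsufficientObservationsError as exc:
        logger.warning("SOM skipped: %s", exc)
    _write_run_info(out, config, "ml", summary)
    return out


def run_enrichment(config: PipelineConfig) -> Path:
    """Per-miRNA (or generic list) enrichment with the size-matched null."""
    out = _outdir(config, "enrichment")
    seed = config.stage_seed("enrichment")
    catalog_path = config.catalog_path or str(Path(config.output_dir) / "simulate" / "catalog.gmt")
    meta_path = config.meta_map_path or str(Path(config.output_dir) / "simulate" / "meta_map.tsv")
    if not Path(catalog_path).exists():
        raise DataError(f"catalog not found: {catalog_path}")
    terms = read_gmt(catalog_path)
    meta_map = read_meta_map(meta_path) if Path(meta_path).exists() else {t: ["meta_01"] for t in terms}
    universe = set().union(*terms.values()) if terms else set()
    catalog = simulate.AnnotationCatalog(terms=terms, universe=universe, meta_map=meta_map)

    if config.target_map_path and Path(config.target_map_path).exists():
        target_map = read_target_map(config.target_map_path)
    else:
        raise DataError("no target map supplied (target_map_path)")
    profiles = enrichment.mirna_pathway_profile(
        target_map, catalog, reps=config.null_reps, seed=seed
    )
    for mirna, prof in profiles.items():
        prof.to_csv(out / f"profile_{mirna.replace('/', '_')}.tsv", sep="\t")
    counts = {m: int((p["verdict"] == "validated-enriched").sum()) for m, p in profiles.items()}
    (out / "enrichment_summary.json").write_text(json.dumps(
        {"validated_terms_per_mirna": counts, "reps": config.null_reps}, indent=2, sort_keys=True) + "\n")
    _write_run_info(out, config, "enrichment", {"n_mirnas": len(profiles), "reps": config.null_reps})
    return out
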