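"""End-to-end orchestration of the two-stage methylation analysis.

``run_screening_stage`` chains synthetic-data generation (or TSV inputs),
sample QC, quantile normalization, beta computation, the per-gene Wilcoxon
screen, rank-based sample clustering, unweighted GSEA and candidate
selection. ``run_replication_stage`` fine-maps the selected candidates on a
per-CpG amplicon panel, checks the calibration standards and reports
direction consistency against the screen.

Configuration is a plain nested dict (YAML-friendly); the effective config
is echoed into the output directory and its hash stamped into every
artifact header, together with the run seed. Per-operation seeds are
derived from the run seed by fixed offsets, so a (config, seed) pair pins
every byte of output.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, finemap, gsea, screening, synthetic
from ._io import config_hash, write_tsv
from .preprocess import signals_to_beta, qc_filter

logger = logging.getLogger("cardiometh")

__all__ = ["DEFAULT_CONFIG", "load_config", "run_screening_stage", "run_replication_stage"]

# Seed offsets per stochastic operation, fixed so stages stay independent.
_SEED_BETA = 11
_SEED_SIGNALS = 23
_SEED_PANEL = 37
_SEED_CALIBRATION = 41
_SEED_CATEGORIES = 53

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "screening": {
        "design": {
            "n_cases": 9,
            "n_controls": 8,
            "n_genes": 2000,
            "n_planted": 90,
            "delta": 0.2,
            "precision": 50.0,
        },
        "signals": {"intensity": 5000.0, "noise": 50.0},
        "qc_z_threshold": 3.0,
        "beta_offset": 100.0,
        "restrict_heart": True,
        "alpha": 0.05,
        "linkage": "complete",
        "selection": {"top_n_by_p": 20, "top_n_per_direction": 5},
        "gsea": {"n_random_categories": 20, "category_size": 30},
    },
    "replication": {
        "n_cases": 30,
        "n_controls": 28,
        "cpgs_per_amplicon": 5,
        "consistent_fraction": 12 / 20,
        "delta": 0.10,
        "precision": 60.0,
        "alpha": 0.05,
        "calibration_noise": 1.0,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally merged with a YAML file and a dict of overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


@dataclass
class ScreeningStageOutput:
    dataset: synthetic.BetaDataset
    truth: pd.DataFrame
    qc_report: pd.DataFrame
    gene_beta: pd.DataFrame
    results: pd.DataFrame
    dendrogram: clustering.Dendrogram
    enrichment: list[gsea.EnrichmentResult]
    candidates: pd.DataFrame


@dataclass
class ReplicationStageOutput:
    panel: finemap.AmpliconPanel
    panel_truth: pd.DataFrame
    stats: pd.DataFrame
    calibration: finemap.CalibrationResult
    consistency: dict


def _echo_config(config: dict, outdir: Path) -> str:
    h = config_hash(config)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        fh.write(f"# config_hash={h}\n")
        yaml.safe_dump(config, fh, sort_keys=True)
    return h


def run_screening_stage(config: dict, outdir: str | Path) -> ScreeningStageOutput:
    """Execute preprocess -> screen -> cluster -> GSEA -> candidate selection."""
    outdir = Path(outdir)
    h = _echo_config(config, outdir)
    seed = int(config["seed"])
    note = f"config_hash={h} seed={seed}"
    scfg = config["screening"]

    design = synthetic.CohortDesign(seed=seed + _SEED_BETA, **scfg["design"])
    dataset, truth = synthetic.gen_beta_matrix(design)
    logger.info("screening: generated %d probes x %d samples", *dataset.beta.shape)
    signals = synthetic.gen_bead_signals(
        dataset.beta, seed=seed + _SEED_SIGNALS, **scfg["signals"]
    )

    passing, qc = qc_filter(signals, z_threshold=scfg["qc_z_threshold"])
    if not passing:
        raise RuntimeError("screening stage: QC left no samples")
    beta = signals_to_beta(
        signals.subset_samples(passing), offset=scfg["beta_offset"]
    )
    groups = dataset.groups().loc[passing]

    gene_counts = dataset.annotation.groupby("gene_id")["probe_id"].count()
    gene_beta = screening.aggregate_gene_beta(
        beta, dataset.annotation, restrict_heart=scfg["restrict_heart"]
    )
    results = screening.wilcoxon_gene_screen(gene_beta, groups, n_probes=gene_counts)
    logger.info(
        "screening: %d genes tested, %d at p<%g",
        len(results),
        int((results["p_value"] < scfg["alpha"]).sum()),
        scfg["alpha"],
    )

    # Cluster samples on the significant genes (rank space, Euclidean).
    sig_genes = results.loc[results["p_value"] < scfg["alpha"], "gene_id"]
    cluster_input = gene_beta.loc[gene_beta.index.intersection(sig_genes)]
    if len(cluster_input) < 2:
        cluster_input = gene_beta
    ranks = clustering.rank_transform(cluster_input)
    dend = clustering.agglomerative_cluster(
        clustering.euclidean_distance_matrix(ranks), linkage=scfg["linkage"]
    )

    # GSEA on the probe-level sorted list collapsed to genes.
    case_cols = [s for s in beta.columns if groups[s] == "case"]
    ctrl_cols = [s for s in beta.columns if groups[s] == "control"]
    probe_scores = (
        beta[case_cols].median(axis=1) - beta[ctrl_cols].median(axis=1)
    ).abs()
    probe_to_gene = dataset.annotation.set_index("probe_id")["gene_id"].to_dict()
    sorted_list = gsea.build_sorted_list(probe_scores.to_dict(), probe_to_gene)
    collection = _build_categories(
        truth, sorted_list, seed + _SEED_CATEGORIES, scfg["gsea"]
    )
    enrichment = gsea.enrich_categories(sorted_list, collection)

    flags = pd.DataFrame(
        {
            "has_cgi": True,
            "heart_expressed": dataset.annotation.groupby("gene_id")[
                "heart_expressed"
            ].first(),
        }
    )
    rules = screening.SelectionRules(**scfg["selection"])
    candidates = screening.select_candidates(results, rules, gene_flags=flags)

    write_tsv(qc.table, outdir / "qc_report.tsv", note)
    write_tsv(beta, outdir / "beta_matrix.tsv", note, index=True)
    write_tsv(dataset.metadata, outdir / "sample_metadata.tsv", note)
    write_tsv(dataset.annotation, outdir / "probe_annotation.tsv", note)
    write_tsv(truth, outdir / "truth.tsv", note)
    write_tsv(results, outdir / "screening_results.tsv", note)
    write_tsv(dend.to_frame(), outdir / "dendrogram_merges.tsv", note)
    (outdir / "dendrogram.nwk").write_text(f"# {note}\n{dend.to_newick()}\n")
    enr = pd.DataFrame(
        [
            {
                "category": r.category,
                "k": r.k,
                "n": r.n,
                "rs_max": r.rs_max,
                "p_exact": r.p_exact,
                "q_bh": r.q_bh,
                "empty_intersection": r.empty_intersection,
            }
            for r in enrichment
        ]
    )
    write_tsv(enr, outdir / "enrichment.tsv", note)
    write_tsv(candidates, outdir / "candidates.tsv", note)
    return ScreeningStageOutput(
        dataset, truth, qc.table, gene_beta, results, dend, enrichment, candidates
    )


def _build_categories(truth, sorted_list, seed, gcfg) -> dict[str, list[str]]:
    """A planted-signal category plus random same-universe categories."""
    rng = np.random.default_rng(seed)
    universe = [g for g in sorted_list.genes]
    size = min(gcfg["category_size"], len(universe))
    planted = [
        g
        for g in truth.loc[truth["is_differential"], "gene_id"]
        if g in set(universe)
    ]
    collection = {}
    if planted:
        collection["planted_differential"] = sorted(
            rng.choice(planted, size=min(size, len(planted)), replace=False).tolist()
        )
    for i in range(gcfg["n_random_categories"]):
        collection[f"random_{i + 1:02d}"] = sorted(
            rng.choice(universe, size=size, replace=False).tolist()
        )
    return collection


def run_replication_stage(
    config: dict, candidates: pd.DataFrame, outdir: str | Path
) -> ReplicationStageOutput:
    """Fine-map the candidate list on a synthetic per-CpG amplicon panel."""
    if candidates is None or candidates.empty:
        raise ValueError("replication stage: candidate list is empty")
    outdir = Path(outdir)
    h = _echo_config(config, outdir)
    seed = int(config["seed"])
    note = f"config_hash={h} seed={seed}"
    rcfg = config["replication"]

    cand_ids = list(candidates["gene_id"])
    directions = dict(zip(candidates["gene_id"], candidates["direction"]))
    panel, panel_truth = synthetic.gen_amplicon_panel(
        cand_ids,
        directions=directions,
        n_cases=rcfg["n_cases"],
        n_controls=rcfg["n_controls"],
        cpgs_per_amplicon=rcfg["cpgs_per_amplicon"],
        consistent_fraction=rcfg["consistent_fraction"],
        delta=rcfg["delta"],
        precision=rcfg["precision"],
        seed=seed + _SEED_PANEL,
    )
    groups = panel.groups()
    rows = []
    for cand in cand_ids:
        means = finemap.mean_cpg_methylation(panel, cand).set_index("sample")
        case_v = means.loc[[s for s in means.index if groups[s] == "case"], "mean_fraction"]
        ctrl_v = means.loc[
            [s for s in means.index if groups[s] == "control"], "mean_fraction"
        ]
        res = finemap.group_ttest(case_v, ctrl_v)
        rows.append(
            {
                "gene_id": cand,
                "mean_diff": res.mean_diff,
                "t": res.t,
                "p": res.p,
                "degenerate": res.degenerate,
            }
        )
    stats_df = pd.DataFrame(rows)

    # Calibration standards 0..100% with a small measurement error.
    rng = np.random.default_rng(seed + _SEED_CALIBRATION)
    nominal = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 100.0])
    measured = np.clip(
        nominal + rng.normal(0.0, rcfg["calibration_noise"], size=nominal.size),
        0.0,
        100.0,
    )
    calibration = finemap.calibration_check(nominal, measured)

    consistency = finemap.direction_consistency(
        candidates[["gene_id", "median_diff"]], stats_df, alpha=rcfg["alpha"]
    )
    logger.info(
        "replication: %d/%d same direction, %d significant",
        consistency["n_same_direction"],
        consistency["n_candidates"],
        consistency["n_significant"],
    )

    write_tsv(panel.data, outdir / "amplicon_panel.tsv", note)
    write_tsv(panel.metadata, outdir / "replication_metadata.tsv", note)
    write_tsv(panel_truth, outdir / "panel_truth.tsv", note)
    write_tsv(stats_df, outdir / "replication_stats.tsv", note)
    write_tsv(consistency["table"], outdir / "consistency_report.tsv", note)
    calib_df = pd.DataFrame(
        {
            "nominal_percent": nominal,
            "measured_percent": measured,
        }
    )
    write_tsv(calib_df, outdir / "calibration_series.tsv", note)
    write_tsv(
        pd.DataFrame(
            [
                {
                    "slope": calibration.slope,
                    "intercept": calibration.intercept,
                    "r_squared": calibration.r_squared,
                    "unbiased": calibration.unbiased,
                }
            ]
        ),
        outdir / "calibration_check.tsv",
        note,
    )
    return ReplicationStageOutput(panel, panel_truth, stats_df, calibration, consistency)
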