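"""Pipeline orchestration: named runs over the stages
simulate → preprocess → DEG → overlap bootstrap → classification → metrics,
with YAML configuration and machine-readable JSON reports.

Every report embeds the fully resolved configuration and the master seed, so
re-running a command with the same config reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .classify import FourWayClassification
from .deg import DifferentialExpression
from .design import make_fmt_design
from .metrics import (
    group_comparison,
    growth_rates_by_tissue,
    mouse_distance_summary,
    paired_secretion_comparison,
    taxa_distance_ratio,
)
from .overlap import OverlapBootstrap
from .preprocess import filter_sparse_genes, normalize_library_size, pca_summary
from .simulate import (
    EffectSpec,
    generate_counts,
    generate_distance_measurements,
    generate_mucus_timeseries,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 0
    outdir: str = "runs/out"
    counts_path: str | None = None
    design_path: str | None = None
    distances_path: str | None = None
    mucus_path: str | None = None
    simulate: dict = field(
        default_factory=lambda: {
            "n_genes": 10_000,
            "n_shared_effect": 1_000,
            "n_cohort_specific": 0,
            "log2_effect_size": 3.0,
            "dispersion": 0.3,
            "sparse_fraction": None,
            "n_per_group": 7,
            "distance_treatment_scale": 0.5,
            "control_rate": 2.0,
            "treated_rate": 1.0,
            "noise_sd": 2.0,
        }
    )
    filter: dict = field(default_factory=lambda: {"max_zero_fraction": 0.5})
    normalize: dict = field(default_factory=lambda: {"scale": 1e6})
    pca: dict = field(
        default_factory=lambda: {"n_components": 2, "log1p": False, "scale_genes": False}
    )
    deg: dict = field(
        default_factory=lambda: {"alpha": 0.05, "pseudocount": 1.0, "correction": None}
    )
    overlap: dict = field(default_factory=lambda: {"n_boot": 10_000})
    classifier: dict = field(
        default_factory=lambda: {
            "n_trees": 200,
            "iterations": 200,
            "n_train_per_group": 5,
            "n_test_per_group": 2,
            "top_k": 200,
        }
    )
    metrics: dict = field(default_factory=lambda: {"distance_summary": "mean"})
    # recorded interpretation: random gene sets are drawn per cohort's
    # significant set from the post-filter tested universe
    notes: dict = field(
        default_factory=lambda: {
            "bootstrap_universe": "post-filter tested genes, sampled without replacement",
            "deg_rule": "two-sided Mann-Whitney p < alpha, uncorrected",
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _write_report(payload: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def _load_or_simulate(config: RunConfig):
    """Counts + design from configured paths, else from the simulator."""
    if config.counts_path and config.design_path:
        counts = io.read_counts(config.counts_path)
        design = io.read_design(config.design_path)
        truth = None
    else:
        sim = config.simulate
        design = make_fmt_design(n_per_group=int(sim.get("n_per_group", 7)))
        spec = EffectSpec(
            n_genes=int(sim["n_genes"]),
            n_shared_effect=int(sim.get("n_shared_effect", 0)),
            n_cohort_specific=int(sim.get("n_cohort_specific", 0)),
            log2_effect_size=float(sim.get("log2_effect_size", 0.0)),
            dispersion=float(sim.get("dispersion", 0.3)),
            sparse_fraction=sim.get("sparse_fraction"),
            seed=config.seed,
        )
        counts, truth = generate_counts(design, spec)
    return counts, design, truth


def run_simulation(config: RunConfig) -> dict:
    """Generate and write all synthetic inputs for a run."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, design, truth = _load_or_simulate(config)
    io.write_counts(counts, outdir / "counts.tsv")
    io.write_design(design, outdir / "design.csv")
    if truth is not None:
        truth.to_csv(outdir / "truth_labels.csv", index_label="gene_id")

    sim = config.simulate
    distances = generate_distance_measurements(
        n_mice=int(sim.get("n_mice", 5)),
        treatment_scale=float(sim.get("distance_treatment_scale", 0.5)),
        taxa_params={"EUB338": (4.0, 15.0), "Clep866": (4.0, 10.0), "GAM42a": (4.0, 25.0)},
        seed=config.seed,
    )
    io.write_measurements(distances, outdir / "distances.csv")
    mucus = generate_mucus_timeseries(
        n_pairs=int(sim.get("n_pairs", 6)),
        control_rate=float(sim.get("control_rate", 2.0)),
        treated_rate=float(sim.get("treated_rate", 1.0)),
        noise_sd=float(sim.get("noise_sd", 2.0)),
        seed=config.seed,
    )
    io.write_measurements(mucus, outdir / "mucus.csv")
    report = {
        "stage": "simulate",
        "seed": config.seed,
        "config": config.resolved(),
        "n_genes": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
    }
    _write_report(report, outdir / "simulate.json")
    return report


def _preprocess(counts: pd.DataFrame, config: RunConfig):
    filtered, report = filter_sparse_genes(
        counts, max_zero_fraction=float(config.filter["max_zero_fraction"])
    )
    norm = normalize_library_size(filtered, scale=float(config.normalize["scale"]))
    return norm, report


def run_overlap_analysis(config: RunConfig) -> dict:
    """filter → normalize → DEG per cohort → signed sets → directional
    overlap → bootstrap → empirical p, with a JSON report."""
    t0 = time.perf_counter()
    counts, design, _ = _load_or_simulate(config)
    norm, filter_report = _preprocess(counts, config)

    cohorts = list(dict.fromkeys(design["cohort"]))
    treatments = list(dict.fromkeys(design["treatment"]))
    if len(cohorts) != 2 or len(treatments) != 2:
        raise ValueError("overlap analysis needs 2 cohorts x 2 treatments")
    control, treated = treatments

    deg_cfg = config.deg
    sets, sign_maps, deg_counts = [], [], {}
    for cohort in cohorts:
        ctrl_ids = design.index[
            (design["cohort"] == cohort) & (design["treatment"] == control)
        ]
        trt_ids = design.index[
            (design["cohort"] == cohort) & (design["treatment"] == treated)
        ]
        res = DifferentialExpression(
            norm, ctrl_ids, trt_ids, pseudocount=float(deg_cfg["pseudocount"])
        ).fit()
        sig = res.significant_set(
            alpha=float(deg_cfg["alpha"]), correction=deg_cfg.get("correction")
        )
        sets.append(sig)
        sign_maps.append(res.table["direction"].astype(int).to_dict())
        deg_counts[cohort] = len(sig)

    model = OverlapBootstrap(sets[0], sets[1])
    results = model.fit(
        n_boot=int(config.overlap["n_boot"]),
        seed=config.seed,
        signs_a=sign_maps[0],
        signs_b=sign_maps[1],
    )

    outdir = Path(config.outdir)
    report = {
        "stage": "overlap",
        "seed": config.seed,
        "config": config.resolved(),
        "filter_report": json.loads(filter_report.to_json()),
        "significant_set_sizes": deg_counts,
        "overlap": results.result.to_dict(),
    }
    logger.info("overlap stage done in %.2fs", time.perf_counter() - t0)
    _write_report(report, outdir / "overlap.json")
    pd.Series(results.null).to_csv(outdir / "overlap_null.csv", index=False, header=["overlap"])
    return report


def run_classification(config: RunConfig) -> dict:
    """filter → normalize → repeated-split forest → top-k genes →
    z-score → clustered heatmap order."""
    t0 = time.perf_counter()
    counts, design, _ = _load_or_simulate(config)
    norm, filter_report = _preprocess(counts, config)

    coords, var_frac = pca_summary(
        norm,
        n_components=int(config.pca["n_components"]),
        log1p=bool(config.pca["log1p"]),
        scale_genes=bool(config.pca["scale_genes"]),
    )

    cls = config.classifier
    results = FourWayClassification(
        norm,
        design,
        n_train_per_group=int(cls["n_train_per_group"]),
        n_test_per_group=int(cls["n_test_per_group"]),
        n_trees=int(cls["n_trees"]),
    ).fit(iterations=int(cls["iterations"]), seed=config.seed)

    top_k = min(int(cls.get("top_k", 200)), results.importances.size)
    top = results.top_features(k=top_k)
    heat = results.ordered_heatmap(k=top_k)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.confusion.matrix.to_csv(outdir / "confusion.csv")
    results.importances.to_csv(outdir / "importances.csv", header=True)
    pd.Series(top, name="gene_id").to_csv(outdir / "top_genes.csv", index=False)
    heat.to_csv(outdir / "heatmap_matrix.csv")

    report = {
        "stage": "classify",
        "seed": config.seed,
        "config": config.resolved(),
        "filter_report": json.loads(filter_report.to_json()),
        "pca_variance_fractions": [float(v) for v in var_frac],
        "pca_pc1_pc2_percent": float(100 * var_frac[:2].sum()),
        "confusion": json.loads(results.confusion.to_json()),
        "overall_accuracy_percent": results.confusion.overall_accuracy,
        "top_k": top_k,
    }
    logger.info("classification stage done in %.2fs", time.perf_counter() - t0)
    _write_report(report, outdir / "classification.json")
    return report


def run_metrics(config: RunConfig) -> dict:
    """Barrier metrics over measurement CSVs plus group comparisons."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    dist_path = config.distances_path or outdir / "distances.csv"
    mucus_path = config.mucus_path or outdir / "mucus.csv"

    report: dict = {
        "stage": "metrics",
        "seed": config.seed,
        "config": config.resolved(),
    }

    distances = io.read_measurements(dist_path)
    summary = mouse_distance_summary(
        distances, statistic=config.metrics["distance_summary"]
    )
    per_probe = {}
    for probe, sub in summary.groupby("probe"):
        per_probe[probe] = group_comparison(sub["value"], sub["group"])
    report["distance_by_probe"] = per_probe
    summary.to_csv(outdir / "distance_summary.csv", index=False)

    probes = sorted(distances["probe"].unique())
    if {"Clep866", "GAM42a"} <= set(probes):
        ratios = taxa_distance_ratio(distances, "Clep866", "GAM42a")
        report["clostridia_gamma_ratio"] = group_comparison(
            ratios["ratio"], ratios["group"]
        )
        ratios.to_csv(outdir / "taxa_ratio.csv", index=False)

    mucus = io.read_measurements(mucus_path)
    rates = growth_rates_by_tissue(mucus)
    rates.to_csv(outdir / "growth_rates.csv", index=False)
    paired = paired_secretion_comparison(rates)
    report["mucus_secretion"] = {
        "n_pairs": paired["n_pairs"],
        "mean_difference_um_per_min": paired["mean_difference"],
        "mean_ratio_control_over_treated": paired["mean_ratio"],
        "paired_t_p_value": paired["p_value"],
    }
    logger.info("metrics stage done in %.2fs", time.perf_counter() - t0)
    _write_report(report, outdir / "metrics.json")
    return report


def run_all(config: RunConfig) -> dict:
    """simulate → overlap → classify → metrics."""
    reports = {"simulate": run_simulation(config)}
    reports["overlap"] = run_overlap_analysis(config)
    reports["classify"] = run_classification(config)
    reports["metrics"] = run_metrics(config)
    return reports
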