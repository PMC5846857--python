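"""End-to-end study orchestration.

``run_study`` executes, per dataset: pairwise similarity for every measure,
unfolding, SRD with bootstrap cross-validation; then aggregates the
bootstrap means into the long table, runs the three one-way ANOVA
decompositions (measure / class / metricity) and the best/medium/worst
grouping.  ``run_comparison`` runs the cluster-agreement analysis of chosen
measures against the quantitative reference.

All randomness flows from one master seed through named
:class:`numpy.random.SeedSequence` substreams, so a rerun with the same
configuration is bit-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anova as _anova
from .catalog import catalog, get_measure
from .cluster import (binary_distance, ccr, cut_tree, quantitative_distance,
                      ward_linkage)
from .engine import assemble_srd_input, pairwise_similarity
from .io import BinaryFingerprintMatrix, QuantitativeMatrix, read_binary_matrix
from .srd import bootstrap_srd, run_srd
from .synth import SyntheticSpec, generate

__all__ = ["StudyConfig", "StudyReport", "run_study", "run_comparison", "ComparisonReport"]


@dataclass
class StudyConfig:
    """Declarative description of one consensus-ranking study."""

    datasets: dict[int, BinaryFingerprintMatrix | SyntheticSpec | str | Path]
    measure_ids: list[str] | None = None  # None -> all 44
    reference_mode: str = "average"
    bootstrap_iterations: int = 100
    seed: int = 0
    thresholds: tuple[float, float] = (15.0, 25.0)
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("need at least one dataset")
        if self.bootstrap_iterations < 2:
            raise ValueError("bootstrap_iterations must be >= 2")
        low, high = self.thresholds
        if not (0 < low < high < 100):
            raise ValueError("thresholds must satisfy 0 < low < high < 100")

    def config_hash(self) -> str:
        payload = {
            "datasets": {k: _dataset_fingerprint(v) for k, v in self.datasets.items()},
            "measures": self.measure_ids,
            "reference_mode": self.reference_mode,
            "bootstrap_iterations": self.bootstrap_iterations,
            "seed": self.seed,
            "thresholds": list(self.thresholds),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _dataset_fingerprint(ds) -> str:
    if isinstance(ds, BinaryFingerprintMatrix):
        return hashlib.sha256(ds.values.tobytes()).hexdigest()[:12]
    if isinstance(ds, SyntheticSpec):
        return json.dumps(dataclasses.asdict(ds), sort_keys=True)
    return str(ds)


@dataclass
class StudyReport:
    config: StudyConfig
    srd_tables: dict[int, pd.DataFrame]  # per dataset
    long_table: pd.DataFrame
    anova: dict[str, _anova.AnovaResult]
    groups: dict[str, str]
    seed: int
    config_hash: str


def _resolve_dataset(ds) -> BinaryFingerprintMatrix:
    if isinstance(ds, BinaryFingerprintMatrix):
        return ds
    if isinstance(ds, SyntheticSpec):
        return generate(ds).binary
    path = Path(ds)
    dialect = "tsv" if path.suffix.lower() in (".tsv", ".txt") else (
        "sheet" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    return read_binary_matrix(path, dialect=dialect)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full consensus-ranking study described by *config*."""
    measures = catalog() if config.measure_ids is None else [
        get_measure(mid) for mid in config.measure_ids
    ]
    master = np.random.SeedSequence(config.seed)
    substreams = master.spawn(len(config.datasets))
    srd_tables: dict[int, pd.DataFrame] = {}
    boot_results = {}
    for (dataset_id, ds), ss in zip(sorted(config.datasets.items()), substreams):
        try:
            binary = _resolve_dataset(ds)
            X = assemble_srd_input(binary, measures)
            rng = np.random.default_rng(ss)
            full = run_srd(X, mode=config.reference_mode, seed=rng)
            boots = bootstrap_srd(X, iterations=config.bootstrap_iterations,
                                  seed=rng, mode=config.reference_mode)
        except Exception as exc:
            raise RuntimeError(f"study failed on dataset {dataset_id}: {exc}") from exc
        boot_results[dataset_id] = boots
        srd_tables[dataset_id] = pd.DataFrame(
            {
                "measure": [r.measure_id for r in full],
                "srd": [r.srd for r in full],
                "srd_max": [r.srd_max for r in full],
                "srd_norm": [r.srd_norm for r in full],
                "null_5": [r.null_percentiles[0] for r in full],
                "null_50": [r.null_percentiles[1] for r in full],
                "null_95": [r.null_percentiles[2] for r in full],
                "boot_mean": [b.mean_srd_norm for b in boots],
                "boot_sd": [b.sd for b in boots],
            }
        )
    long_table = _anova.aggregate(boot_results, measures)
    anova_results = {}
    for factor in ("measure", "class", "metricity"):
        col = {"measure": "measure_id", "class": "class_tag",
               "metricity": "metricity_tag"}[factor]
        counts = long_table[col].value_counts()
        # skip factors that cannot be decomposed (single level, or a level
        # with a single observation, e.g. per-measure ANOVA of one dataset)
        if len(counts) >= 2 and counts.min() >= 2:
            anova_results[factor] = _anova.anova_by_factor(long_table, factor)
    groups = _anova.classify_groups(long_table, *config.thresholds)
    report = StudyReport(
        config=config,
        srd_tables=srd_tables,
        long_table=long_table,
        anova=anova_results,
        groups=groups,
        seed=config.seed,
        config_hash=config.config_hash(),
    )
    if config.output_dir is not None:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: StudyReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": report.config_hash, "seed": report.seed}
    for dataset_id, table in report.srd_tables.items():
        t = table.copy()
        for key, val in stamp.items():
            t[key] = val
        t.to_csv(outdir / f"srd_dataset_{dataset_id}.csv", index=False)
    lt = report.long_table.copy()
    for key, val in stamp.items():
        lt[key] = val
    lt.to_csv(outdir / "srd_long_table.csv", index=False)
    summary = {
        **stamp,
        "groups": report.groups,
        "anova": {
            factor: {
                "F": res.f_statistic,
                "p": res.p_value,
                "df": [res.df_between, res.df_within],
                "levene_p": res.levene_p,
                "level_means": res.level_means.to_dict(orient="records"),
            }
            for factor, res in report.anova.items()
        },
    }
    (outdir / "study_summary.json").write_text(json.dumps(summary, indent=2))


@dataclass
class ComparisonReport:
    reference_tree_newick: str
    results: pd.DataFrame  # measure, ccr_percent, misclassified, rand_percent
    k: int
    config_hash: str


def run_comparison(
    binary: BinaryFingerprintMatrix,
    quantitative: QuantitativeMatrix,
    measure_ids: list[str] = ("BUB", "Di1"),
    k: int = 2,
    ward_dialect: str = "d",
) -> ComparisonReport:
    """Cluster-agreement of binary-fingerprint trees vs the quantitative tree."""
    if list(binary.sample_ids) != list(quantitative.sample_ids):
        raise ValueError("binary and quantitative tables must list the same samples in order")
    from .cluster import to_newick

    ref_tree = ward_linkage(quantitative_distance(quantitative), dialect=ward_dialect)
    ref_labels = cut_tree(ref_tree, k)
    rows = []
    for mid in measure_ids:
        measure = get_measure(mid)
        tree = ward_linkage(binary_distance(pairwise_similarity(binary, measure)),
                            dialect=ward_dialect)
        labels = cut_tree(tree, k)
        cmp = ccr(labels, ref_labels, k=k, sample_ids=list(binary.sample_ids))
        rows.append((mid, cmp.ccr_percent, cmp.misclassification_count, cmp.rand_percent))
    results = pd.DataFrame(rows, columns=["measure", "ccr_percent", "misclassified", "rand_percent"])
    payload = hashlib.sha256(
        binary.values.tobytes() + quantitative.values.tobytes() + str(sorted(measure_ids)).encode()
    ).hexdigest()[:12]
    return ComparisonReport(
        reference_tree_newick=to_newick(ref_tree),
        results=results,
        k=k,
        config_hash=payload,
    )
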