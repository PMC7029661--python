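"""End-to-end orchestration: simulate -> group -> build -> extract -> select
-> classify, with reproducible seeds and a provenance record.

Every stage reads and writes the package's standard text artifacts, so runs
are resumable stage by stage and two runs with the same config reproduce all
numeric artifacts bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import MKLConfig, loo_cv_classify
from .comparison import select_features, standardized_metric_regression
from .grouping import GroupingResult, cluster_rois
from .hypernetwork import LambdaGrid, build_hypernetwork, edge_degree_distribution
from .metrics import FeatureTable, build_feature_table, feature_names
from .solvers import SolverConfig
from .synthetic import CohortConfig, SubjectTimeSeries, read_timeseries, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "compare_methods"]

METHODS = ("lasso", "glasso", "sglasso")


@dataclass
class PipelineConfig:
    """Everything one run needs; the global seed drives every stochastic stage."""

    method: str = "sglasso"
    k: int = 30
    cohort: CohortConfig = field(default_factory=CohortConfig)
    manifest_path: str | None = None  # read real/serialized data instead of simulating
    grid: LambdaGrid = field(default_factory=LambdaGrid)
    solver: SolverConfig = field(default_factory=SolverConfig)
    selection_q: float = 0.05
    selection_mode: str = "asymptotic"
    selection_scope: str = "nested"
    n_permutations: int = 1000
    mkl: MKLConfig = field(default_factory=MKLConfig)
    clustering_restarts: int = 10
    seed: int = 0
    out_dir: str = "hyperfc_run"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.method == "lasso" and self.k is not None:
            warnings.warn("method=lasso ignores k", UserWarning, stacklevel=2)
        if self.method != "lasso" and not self.k:
            raise ValueError(f"{self.method} requires k")

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _load_subjects(config: PipelineConfig) -> list[SubjectTimeSeries]:
    if config.manifest_path is not None:
        return read_timeseries(config.manifest_path)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    return simulate_cohort(cohort_cfg)


def _build_features(
    config: PipelineConfig,
    subjects: Sequence[SubjectTimeSeries],
    grouping_seed: int,
    out_dir: str | None = None,
) -> tuple[FeatureTable, GroupingResult | None, list]:
    partition = None
    if config.method != "lasso":
        partition = cluster_rois(
            subjects, config.k, restarts=config.clustering_restarts, rng_seed=grouping_seed
        )
        if out_dir:
            partition.to_tsv(os.path.join(out_dir, "grouping.tsv"))
    hypergraphs = []
    for s in subjects:
        H = build_hypernetwork(
            s, method=config.method, grid=config.grid,
            partition=partition, solver_config=config.solver,
        )
        if out_dir:
            H.to_edgelist_tsv(os.path.join(out_dir, f"incidence_{s.subject_id}.tsv"))
        hypergraphs.append(H)
    table = build_feature_table(
        hypergraphs, [s.subject_id for s in subjects], [s.cohort for s in subjects]
    )
    if out_dir:
        table.to_tsv(os.path.join(out_dir, "features.tsv"))
    return table, partition, hypergraphs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, writing artifacts into ``config.out_dir``.

    Artifacts: grouping.tsv (group methods), per-subject incidence edge
    lists, features.tsv, selection_{hcc,comhcc}.tsv, classification.json and
    provenance.json.  Returns a summary dict.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    subjects = _load_subjects(config)
    table, partition, hypergraphs = _build_features(
        config, subjects, grouping_seed=config.seed, out_dir=config.out_dir
    )

    selection = select_features(
        table,
        q=config.selection_q,
        mode=config.selection_mode,
        n_permutations=config.n_permutations,
        rng_seed=config.seed,
    )
    names = feature_names(table.n_nodes)
    n_hcc = 3 * table.n_nodes
    selection["hcc"].to_tsv(
        os.path.join(config.out_dir, "selection_hcc.tsv"), names[:n_hcc]
    )
    selection["comhcc"].to_tsv(
        os.path.join(config.out_dir, "selection_comhcc.tsv"), names[n_hcc:]
    )

    report = loo_cv_classify(
        table,
        positive_label="B",
        config=dataclasses.replace(config.mkl, rng_seed=config.seed),
        selection_scope=config.selection_scope,
        selection_mode=config.selection_mode,
        selection_q=config.selection_q,
        n_permutations=config.n_permutations,
    )
    degree_dist = edge_degree_distribution(hypergraphs[0])
    result = {
        "classification": report.to_dict(),
        "n_selected": {
            fam: int(selection[fam].selected.sum()) for fam in ("hcc", "comhcc")
        },
        "edge_degree_proportions": degree_dist["proportions"],
        "n_subjects": len(subjects),
        "n_edges": hypergraphs[0].n_edges,
    }
    with open(os.path.join(config.out_dir, "classification.json"), "w") as fh:
        json.dump(result, fh, indent=2)
    provenance = {
        "package_version": __version__,
        "config": _jsonable(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    with open(os.path.join(config.out_dir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2)
    return result


def compare_methods(
    config: PipelineConfig, methods: Sequence[str] = METHODS
) -> pd.DataFrame:
    """Run the pipeline per method on one cohort; emit a 3-methods x
    {single-node, pairwise, multi-feature} summary plus edge-degree bins."""
    subjects = _load_subjects(config)
    rows = []
    degree_rows = []
    tables: dict[str, FeatureTable] = {}
    for method in methods:
        cfg = dataclasses.replace(config, method=method)
        table, _, hypergraphs = _build_features(cfg, subjects, grouping_seed=config.seed)
        tables[method] = table
        dist = edge_degree_distribution(hypergraphs[0])
        degree_rows.append({"method": method, **dist["proportions"]})
        for label, fams in (
            ("single_node", ("hcc",)),
            ("pairs_of_nodes", ("comhcc",)),
            ("multi_feature", ("hcc", "comhcc")),
        ):
            report = loo_cv_classify(
                table,
                positive_label="B",
                config=dataclasses.replace(cfg.mkl, rng_seed=config.seed),
                selection_scope=cfg.selection_scope,
                selection_mode=cfg.selection_mode,
                selection_q=cfg.selection_q,
                n_permutations=cfg.n_permutations,
                families=fams,
            )
            rows.append(
                {
                    "method": method,
                    "features": label,
                    "accuracy": round(report.accuracy, 2),
                    "sensitivity": round(report.sensitivity, 2),
                    "specificity": round(report.specificity, 2),
                    "bac": round(report.bac, 2),
                }
            )
    summary = pd.DataFrame(rows)
    os.makedirs(config.out_dir, exist_ok=True)
    summary.to_csv(os.path.join(config.out_dir, "method_comparison.tsv"), sep="\t", index=False)
    pd.DataFrame(degree_rows).to_csv(
        os.path.join(config.out_dir, "edge_degree_distribution.tsv"), sep="\t", index=False
    )
    if "sglasso" in tables:
        reg = _metric_regressions(tables)
        pd.DataFrame(reg).to_csv(
            os.path.join(config.out_dir, "metric_regressions.tsv"), sep="\t", index=False
        )
    return summary


def _metric_regressions(tables: dict[str, FeatureTable]) -> list[dict]:
    """Regress per-ROI cohort-mean standardized metric values of sgLasso on
    each other method, per cohort — the cross-method association of network
    indicators."""
    out = []
    ref = tables["sglasso"]
    for other in tables:
        if other == "sglasso":
            continue
        for cohort in np.unique(ref.labels):
            mask = ref.labels == cohort
            x = tables[other].values[mask].mean(axis=0)
            y = ref.values[mask].mean(axis=0)
            fit = standardized_metric_regression(x, y)
            out.append(
                {
                    "comparison": f"sglasso_vs_{other}",
                    "cohort": cohort,
                    "slope": round(fit["slope"], 4),
                    "adjusted_r_squared": round(fit["adjusted_r_squared"], 4),
                }
            )
    return out
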