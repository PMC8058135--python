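"""End-to-end orchestration: extraction -> selection -> comparison -> maps.

A single declarative :class:`RunConfig` (YAML-loadable) drives the whole
experiment; every random stream is derived from the one config seed, so a
rerun with the same config produces byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome_data import (
    BehavioralScores,
    CohortTable,
    align_scores,
    load_cohort,
    load_scores,
    write_cohort,
    write_scores,
)
from .errors import ConfigError, DomainError
from .features import (
    FeatureModel,
    error_curve,
    fit_method,
    transform,
    truncate,
)
from .maps import PredictiveMap, back_project, export_map, map_correlation
from .model_selection import (
    CVResult,
    HyperGrid,
    compare_models,
    loo_select,
    nested_loo_select,
)
from .synthetic import SyntheticConfig, generate_cohort, write_ground_truth

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one experiment."""

    # data source: either file paths ...
    cohort_file: str | None = None
    atlas_file: str | None = None
    scores_file: str | None = None
    score_domain: str | None = None
    # ... or a synthetic cohort
    synthetic: SyntheticConfig | None = None

    methods: tuple[str, ...] = ("pca", "ica", "dl", "nnmf")
    grid: HyperGrid = field(default_factory=HyperGrid)
    scheme: str = "loo"                     # "loo" or "nested_loo"
    aggregation: str = "median"             # nested only
    fit_scope: str = "full"                 # "full" or "scored_only"
    standardize_scope: str = "train"        # "train" or "full"
    negativity_policy: str = "shift"
    dl_sparsity: float = 1.0
    top_n_edges: int = 200
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        has_files = self.cohort_file is not None
        if has_files == (self.synthetic is not None):
            raise ConfigError("configure exactly one of file inputs or synthetic")
        if has_files and (self.atlas_file is None or self.scores_file is None):
            raise ConfigError("file input needs cohort_file, atlas_file and scores_file")
        if self.scheme not in ("loo", "nested_loo"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.fit_scope not in ("full", "scored_only"):
            raise ConfigError(f"unknown fit_scope {self.fit_scope!r}")
        for m in self.methods:
            if m not in ("pca", "ica", "dl", "nnmf"):
                raise ConfigError(f"unknown method {m!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["grid"] = {
            "k_values": list(self.grid.k_values),
            "lambda_values": [float(v) for v in self.grid.lambda_values],
            "alpha_values": list(self.grid.alpha_values),
        }
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "grid" in d and d["grid"] is not None:
            g = dict(d["grid"])
            if {"lambda_min", "lambda_max", "n_lambdas"} <= g.keys():
                g["lambda_values"] = np.logspace(
                    np.log10(g.pop("lambda_min")),
                    np.log10(g.pop("lambda_max")),
                    g.pop("n_lambdas"),
                ).tolist()
            d["grid"] = HyperGrid(
                k_values=tuple(g.get("k_values", HyperGrid().k_values)),
                lambda_values=tuple(g.get("lambda_values", HyperGrid().lambda_values)),
                alpha_values=tuple(g.get("alpha_values", HyperGrid().alpha_values)),
            )
        if "synthetic" in d and d["synthetic"] is not None and not isinstance(
            d["synthetic"], SyntheticConfig
        ):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ExperimentResult:
    config: RunConfig
    results_table: pd.DataFrame
    error_curve_table: pd.DataFrame
    wilcoxon_table: pd.DataFrame | None
    cv_results: dict[str, CVResult]
    maps: dict[str, PredictiveMap]
    map_correlations: pd.DataFrame | None
    outdir: Path


def _load_inputs(config: RunConfig) -> tuple[CohortTable, BehavioralScores]:
    if config.synthetic is not None:
        cohort, scores, _ = generate_cohort(config.synthetic)
        return cohort, scores
    cohort = load_cohort(cohort_file=config.cohort_file, atlas_file=config.atlas_file)
    scores = load_scores(config.scores_file, domain=config.score_domain)
    return cohort, scores


def _fit_features(
    config: RunConfig,
    X_fit: np.ndarray,
    ks: Sequence[int],
    seed: int,
) -> dict[str, dict[int, FeatureModel]]:
    """Fit every (method, k) model on the designated fitting sample."""
    models: dict[str, dict[int, FeatureModel]] = {}
    kwargs = {
        "dl": {"sparsity": config.dl_sparsity},
        "nnmf": {"negativity_policy": config.negativity_policy},
    }
    for mi, method in enumerate(config.methods):
        t0 = time.perf_counter()
        per_k: dict[int, FeatureModel] = {}
        if method == "pca":
            full = fit_method("pca", X_fit, max(ks))
            for k in ks:
                per_k[k] = truncate(full, k)
        else:
            for ki, k in enumerate(ks):
                per_k[k] = fit_method(
                    method, X_fit, k,
                    seed=seed + 7919 * mi + 104729 * ki,
                    **kwargs.get(method, {}),
                )
        models[method] = per_k
        logger.info("fitted %s at %d k values in %.1fs",
                    method, len(ks), time.perf_counter() - t0)
    return models


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Execute the full pipeline and write all artifacts to ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort, scores = _load_inputs(config)
    X_sub, y, kept_ids = align_scores(cohort, scores)
    keep_idx = [cohort.subject_ids.index(sid) for sid in kept_ids]
    logger.info("n=%d subjects (%d scored), p=%d edges",
                cohort.n_subjects, len(y), cohort.n_edges)

    ks = [k for k in config.grid.admissible_k(len(y))
          if k <= min(cohort.n_subjects - 1, cohort.n_edges)]
    if not ks:
        raise ConfigError("no admissible k values for this cohort size")

    X_fit = cohort.X if config.fit_scope == "full" else X_sub
    models = _fit_features(config, X_fit, ks, config.seed)

    curve = error_curve(
        X_fit, config.methods, ks, seed=config.seed,
        method_kwargs={
            "dl": {"sparsity": config.dl_sparsity},
            "nnmf": {"negativity_policy": config.negativity_policy},
        },
    )

    cv_results: dict[str, CVResult] = {}
    pmap_by_method: dict[str, PredictiveMap] = {}
    rows = []
    for method in config.methods:
        features_by_k = {
            k: (fm.F_train[keep_idx] if config.fit_scope == "full" else fm.F_train)
            for k, fm in models[method].items()
        }
        t0 = time.perf_counter()
        if config.scheme == "loo":
            res = loo_select(
                features_by_k, y, config.grid,
                standardize_scope=config.standardize_scope,
            )
        else:
            res = nested_loo_select(
                features_by_k, y, config.grid, config.aggregation,
                standardize_scope=config.standardize_scope,
            )
        logger.info("%s %s selection in %.1fs", method, config.scheme,
                    time.perf_counter() - t0)
        cv_results[method] = res
        k_best, lam, alpha = res.best_hyperparams
        pmap = back_project(models[method][k_best], res.final_model, cohort.atlas)
        pmap_by_method[method] = pmap
        export_map(pmap, outdir / "maps", prefix=method, top_n=config.top_n_edges)
        rows.append(
            {
                "method": method,
                "scheme": res.scheme,
                "aggregation": res.aggregation,
                "r2": res.r2,
                "mse": res.mse,
                "bic": res.bic,
                "lambda": lam,
                "alpha": alpha,
                "k": k_best,
                "nz": res.nonzero_count,
            }
        )
    results_table = pd.DataFrame(rows)

    wilcoxon_table = None
    corr_table = None
    if len(config.methods) >= 2:
        wilcoxon_table = compare_models(
            {m: cv_results[m].squared_residuals for m in config.methods}
        )
        corr = np.eye(len(config.methods))
        for i, a in enumerate(config.methods):
            for j, b in enumerate(config.methods):
                if i < j:
                    try:
                        r = map_correlation(pmap_by_method[a], pmap_by_method[b])
                    except DomainError:  # an all-zero map (fully shrunk model)
                        r = float("nan")
                    corr[i, j] = corr[j, i] = r
        corr_table = pd.DataFrame(
            corr, index=list(config.methods), columns=list(config.methods)
        )

    results_table.to_csv(outdir / "results.csv", index=False, float_format=FLOAT_FORMAT)
    curve.to_csv(outdir / "error_curve.csv", index=False, float_format=FLOAT_FORMAT)
    if wilcoxon_table is not None:
        wilcoxon_table.to_csv(outdir / "wilcoxon.csv", index=False, float_format=FLOAT_FORMAT)
    if corr_table is not None:
        corr_table.to_csv(outdir / "map_correlations.csv", float_format=FLOAT_FORMAT)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_scored": len(y),
        "n_subjects": cohort.n_subjects,
        "p": cohort.n_edges,
        "P": cohort.atlas.n_parcels,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    result = ExperimentResult(
        config=config,
        results_table=results_table,
        error_curve_table=curve,
        wilcoxon_table=wilcoxon_table,
        cv_results=cv_results,
        maps=pmap_by_method,
        map_correlations=corr_table,
        outdir=outdir,
    )
    (outdir / "report.md").write_text(report(result))
    return result


def report(result: ExperimentResult) -> str:
    """Human-readable markdown summary of one experiment."""
    lines = ["# Prediction results", "", "```"]
    lines.append(result.results_table.to_string(index=False, float_format="%.4g".__mod__))
    lines.append("```")
    lines.append("")
    if result.map_correlations is not None:
        lines.append("## Predictive-map cross-correlations")
        lines.extend(["", "```"])
        lines.append(result.map_correlations.to_string(float_format="%.3f".__mod__))
        lines.extend(["```", ""])
    if result.wilcoxon_table is not None:
        lines.append("## Pairwise Wilcoxon signed-rank tests (squared residuals)")
        lines.extend(["", "```"])
        lines.append(result.wilcoxon_table.to_string(index=False, float_format="%.4g".__mod__))
        lines.extend(["```", ""])
    return "\n".join(lines)


def simulate_to_files(config: SyntheticConfig, outdir: str | Path) -> None:
    """Generate a synthetic cohort and write it in the canonical file formats."""
    cohort, scores, truth = generate_cohort(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, outdir / "cohort.csv")
    cohort.atlas.to_file(outdir / "atlas.csv")
    write_scores(scores, outdir / "scores.csv")
    write_ground_truth(truth, config, outdir)
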