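"""End-to-end pipeline: ingest -> reduce -> score -> cluster -> characterise.

One configurable run that either reads the four cohort CSVs or draws a
synthetic cohort, then writes every intermediate artifact (reduced matrix,
composite scores, assignments, clustering diagnostics, importance table,
cluster profile) plus a summary report to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import (average_bilateral, normalize_volumes_by_tiv,
                     read_feature_tables)
from .importance import predictor_importance, rank_predictors
from .posthoc import cluster_profile
from .scoring import composite_scores, load_roi_definitions
from .simulate import GeneratorParams, generate_cohort, write_cohort
from .twostep import CFTreeParams, cluster_scores

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # exactly one of input_paths / generator must be set
    input_paths: dict[str, str] | None = None   # thickness/volumes/fa/metadata
    generator: GeneratorParams | None = None
    roi_definitions_path: str | None = None
    bypass_tree: bool = True
    k_max: int = 15
    c1: float = 0.04
    c2: float = 1.15
    refine: bool = False
    seed: int = 0
    outdir: str = "results/run"
    plots: bool = False

    def validate(self) -> None:
        if (self.input_paths is None) == (self.generator is None):
            raise ValueError("set exactly one of input_paths / generator")
        if self.input_paths is not None:
            missing = {"thickness", "volumes", "fa", "metadata"} - set(self.input_paths)
            if missing:
                raise ValueError(f"input_paths missing entries: {sorted(missing)}")

    def digest(self) -> str:
        payload = asdict(self)
        for presentation_only in ("outdir", "plots"):
            payload.pop(presentation_only)
        if self.generator is not None:
            payload["generator"] = asdict(self.generator)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class AnalysisReport:
    k_selected: int
    cluster_sizes: list[int]
    cluster_percent: list[float]
    mean_silhouette: float
    bic_table: dict[int, float]
    importance_ranking: list[str]
    profile: dict
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)
            fh.write("\n")


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute all stages in order and write artifacts to ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        log.info("stage simulate: drawing synthetic cohort (seed=%d)", config.seed)
        cohort, latent = generate_cohort(config.generator, seed=config.seed)
        write_cohort(cohort, latent, outdir / "cohort")
    else:
        log.info("stage ingest: reading cohort tables")
        cohort = read_feature_tables(
            thickness_path=config.input_paths["thickness"],
            volumes_path=config.input_paths["volumes"],
            fa_path=config.input_paths["fa"],
            metadata_path=config.input_paths["metadata"])

    log.info("stage reduce: TIV normalisation and bilateral averaging")
    reduced = average_bilateral(normalize_volumes_by_tiv(cohort))
    reduced.to_csv(outdir / "reduced_features.csv")

    log.info("stage score: composite regional integrity scores")
    roi_defs = load_roi_definitions(config.roi_definitions_path)
    scores = composite_scores(reduced, roi_defs)
    scores.to_csv(outdir / "composite_scores.csv")
    scores.scaling.to_frame().to_csv(outdir / "scaling_params.csv", index=False)

    log.info("stage cluster: two-step clustering with BIC auto-k")
    solution = cluster_scores(
        scores, CFTreeParams(bypass_tree=config.bypass_tree),
        c1=config.c1, c2=config.c2, k_max=config.k_max, refine=config.refine)
    assign_df = scores.scores.index.to_frame(name="subject_id")
    assign_df["cluster"] = solution.assignments
    assign_df.to_csv(outdir / "assignments.csv", index=False)
    with open(outdir / "clustering_diagnostics.json", "w") as fh:
        json.dump({
            "k_selected": solution.k_selected,
            "cluster_sizes": solution.cluster_sizes.tolist(),
            "mean_silhouette": solution.mean_silhouette,
            "bic": {str(k): v for k, v in sorted(solution.bic_table.items())},
            "bic_change_ratios": {str(k): v for k, v in
                                  sorted(solution.diagnostics.bic_change_ratios.items())},
            "distance_ratios": {str(k): v for k, v in
                                sorted(solution.diagnostics.distance_ratios.items())},
        }, fh, indent=2)

    if solution.k_selected >= 2:
        log.info("stage characterise: predictor importance")
        imp = predictor_importance(scores, solution.assignments)
        imp.to_csv(outdir / "predictor_importance.csv", index=False)
        ranking = rank_predictors(imp)
        log.info("stage posthoc: cluster profiles")
        profile = cluster_profile(cohort.metadata, solution.assignments)
    else:
        imp, ranking = None, []
        profile = cluster_profile(cohort.metadata, solution.assignments)
    profile.to_json(outdir / "cluster_profile.json")
    with open(outdir / "cluster_profile.txt", "w") as fh:
        fh.write(profile.to_text() + "\n")

    if config.plots and solution.k_selected >= 2 and imp is not None:
        _write_plots(outdir, scores, solution, imp, ranking)

    report = AnalysisReport(
        k_selected=solution.k_selected,
        cluster_sizes=solution.cluster_sizes.tolist(),
        cluster_percent=[round(p, 1) for p in solution.sizes_percent],
        mean_silhouette=solution.mean_silhouette,
        bic_table={k: float(v) for k, v in sorted(solution.bic_table.items())
                   if k <= config.k_max},
        importance_ranking=ranking,
        profile=json.loads(profile.to_json()),
        provenance={"config_hash": config.digest(), "seed": config.seed,
                    "version": __version__},
    )
    report.to_json(outdir / "report.json")
    return report


def _write_plots(outdir: Path, scores, solution, importance, ranking) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    imp = importance.sort_values("importance")
    ax.barh(imp["roi"], imp["importance"])
    ax.set_xlabel("relative predictor importance")
    fig.tight_layout()
    fig.savefig(outdir / "importance_profile.png", dpi=150)
    plt.close(fig)

    top3 = ranking[:3]
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    for c in np.unique(solution.assignments):
        mask = solution.assignments == c
        ax.scatter(*[scores.scores[r][mask] for r in top3], label=f"cluster {c}", s=15)
    ax.set_xlabel(top3[0]); ax.set_ylabel(top3[1]); ax.set_zlabel(top3[2])
    ax.legend()
    fig.savefig(outdir / "cluster_scatter.png", dpi=150)
    plt.close(fig)
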