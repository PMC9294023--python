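#!/usr/bin/env python
"""Two-step clustering of the composite scores with automatic k selection.

Agglomerates the 15-score profiles under Euclidean centroid distance, selects
the number of clusters by the BIC change-ratio / distance-ratio rule, and
reports cluster sizes, silhouette cohesion, and recovery of the latent
subtypes planted by the generator.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from alsclust.twostep import cluster_scores

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scores = pd.read_csv(ROOT / "scores" / "composite_scores.csv",
                         comment="#", index_col="subject_id")
    solution = cluster_scores(scores.to_numpy(float))

    out = ROOT / "clustering"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"subject_id": scores.index, "cluster": solution.assignments}
                 ).to_csv(out / "assignments.csv", index=False)
    with open(out / "diagnostics.json", "w") as fh:
        json.dump({"k_selected": solution.k_selected,
                   "cluster_sizes": solution.cluster_sizes.tolist(),
                   "mean_silhouette": solution.mean_silhouette,
                   "bic": {str(k): v for k, v in sorted(solution.bic_table.items())
                           if k <= 15}}, fh, indent=2)

    pct = solution.sizes_percent
    print(f"selected k = {solution.k_selected}")
    for c, (n, p) in enumerate(zip(solution.cluster_sizes, pct), start=1):
        print(f"  cluster {c}: n = {n} ({p:.1f}%)")
    print(f"mean silhouette = {solution.mean_silhouette:.3f}")

    latent_path = ROOT / "cohort" / "latent_labels.csv"
    if latent_path.exists():
        from sklearn.metrics import adjusted_rand_score
        latent = pd.read_csv(latent_path, index_col="subject_id")["subtype"]
        ari = adjusted_rand_score(latent.loc[scores.index], solution.assignments)
        print(f"adjusted Rand index vs latent subtypes = {ari:.3f}")


if __name__ == "__main__":
    main()
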