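#!/usr/bin/env python
"""Reduce the raw metric tables and compute composite regional scores.

Reads the cohort written by 01_simulate_cohort.py, normalises volumes by TIV,
averages bilateral structures (133 metric columns -> 74 variables), and maps
them into the 15 regions of interest as 0-2 composite integrity scores.
"""

from pathlib import Path

from alsclust.cohort import (average_bilateral, normalize_volumes_by_tiv,
                             read_feature_tables)
from alsclust.scoring import composite_scores

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_feature_tables(
        ROOT / "cohort" / "thickness.csv", ROOT / "cohort" / "volumes.csv",
        ROOT / "cohort" / "fa.csv", ROOT / "cohort" / "metadata.csv")
    reduced = average_bilateral(normalize_volumes_by_tiv(cohort))
    scores = composite_scores(reduced)

    out = ROOT / "scores"
    out.mkdir(parents=True, exist_ok=True)
    reduced.to_csv(out / "reduced_features.csv")
    scores.to_csv(out / "composite_scores.csv")
    scores.scaling.to_frame().to_csv(out / "scaling_params.csv", index=False)

    roles = list(reduced.column_roles.values())
    print(f"{cohort.n_subjects} subjects reduced to {reduced.values.shape[1]} "
          f"variables ({roles.count('volume_fraction')} volume, "
          f"{roles.count('thickness')} thickness, {roles.count('fa')} FA)")
    print(f"composite scores: {scores.values.shape[0]} x {scores.values.shape[1]}, "
          f"range [{scores.values.min():.3f}, {scores.values.max():.3f}] -> {out}")


if __name__ == "__main__":
    main()
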