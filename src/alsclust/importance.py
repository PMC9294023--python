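"""Predictor-importance ranking of the 15 regional scores.

Ranks the ROIs by how well they separate the clusters: a one-way ANOVA F test
per ROI across clusters (equal to the pooled-variance t-test squared when
k = 2), converted to an importance in [0, 1] as -log10(p) normalised by the
best predictor.  This mirrors the significance-based importance profile that
the two-step procedure reports for continuous inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import CompositeScoreMatrix

P_FLOOR = 1e-300


def predictor_importance(scores: CompositeScoreMatrix | pd.DataFrame,
                         assignments: np.ndarray) -> pd.DataFrame:
    """Per-ROI F statistic, p-value, normalised importance and rank.

    Importance is ``-log10(p)`` scaled so the most discriminating ROI scores
    exactly 1; p-values are floored at 1e-300 so a perfectly separated ROI
    stays finite.  Requires every cluster to have at least 2 members.
    """
    df = scores.scores if isinstance(scores, CompositeScoreMatrix) else scores
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("predictor importance requires at least 2 clusters")
    for c in uniq:
        if (labels == c).sum() < 2:
            raise ValueError(f"cluster {c} has fewer than 2 members")

    rows = []
    for roi in df.columns:
        groups = [df[roi].to_numpy()[labels == c] for c in uniq]
        if all(np.ptp(g) == 0 for g in groups):
            # no within-cluster variance: perfectly separated unless means equal
            means = [g.mean() for g in groups]
            f, p = (np.inf, 0.0) if np.ptp(means) > 0 else (0.0, 1.0)
        else:
            f, p = stats.f_oneway(*groups)
            if not np.isfinite(p):  # zero between-cluster variance
                f, p = 0.0, 1.0
        p = min(max(float(p), P_FLOOR), 1.0)
        rows.append((roi, float(f), p, -np.log10(p)))
    table = pd.DataFrame(rows, columns=["roi", "F", "p", "neglog10p"])
    top = table["neglog10p"].max()
    table["importance"] = table["neglog10p"] / top if top > 0 else 0.0
    table = table.drop(columns="neglog10p")
    # deterministic tie handling: equal importances ordered alphabetically
    order = table.sort_values(["importance", "roi"], ascending=[False, True]).index
    table["rank"] = 0
    table.loc[order, "rank"] = np.arange(1, len(table) + 1)
    return table


def rank_predictors(table: pd.DataFrame) -> list[str]:
    """ROI names sorted by importance (descending), ties alphabetical."""
    ordered = table.sort_values(["importance", "roi"], ascending=[False, True])
    ties = ordered["importance"].duplicated(keep=False)
    if ties.any():
        import logging
        logging.getLogger(__name__).info(
            "importance ties broken alphabetically: %s",
            sorted(ordered.loc[ties, "roi"]))
    return list(ordered["roi"])
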