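"""Post-hoc contrasts of the clusters' demographic, clinical and genetic profiles.

Categorical variables are compared with chi-square tests on cluster x category
contingency tables: the continuity-corrected (Yates) form for 2 x 2 tables and
the uncorrected Pearson form for larger tables.  Variables with structural
missingness (genotype in the unscreened, cognitive screening in the
unassessed) can carry the missing subjects as an explicit category, which is
how the published genetics and cognition comparisons are reconstructed.
Continuous variables use a two-sample t test (Welch by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING_LABEL = "missing"


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float
    corrected: bool
    table: pd.DataFrame | None = None
    method: str = ""


def _as_table(table) -> pd.DataFrame:
    df = pd.DataFrame(table)
    counts = df.to_numpy()
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if (counts < 0).any() or counts.sum() == 0:
        raise ValueError("contingency table must hold non-negative counts, total > 0")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    return df


def yates_chi_square_2x2(table) -> TestResult:
    """Continuity-corrected chi-square for a 2 x 2 table.

    chi2 = sum (|O - E| - 0.5)^2 / E, with the correction capped at |O - E|
    so sparse cells cannot overshoot; df = 1.
    """
    df = _as_table(table)
    if df.shape != (2, 2):
        raise ValueError(f"expected a 2 x 2 table, got {df.shape}")
    res = stats.chi2_contingency(df.to_numpy(), correction=True)
    return TestResult(float(res.statistic), int(res.dof), float(res.pvalue),
                      corrected=True, table=df, method="chi-square (Yates)")


def pearson_chi_square_rxc(table) -> TestResult:
    """Uncorrected Pearson chi-square for an r x c table, df = (r-1)(c-1)."""
    df = _as_table(table)
    res = stats.chi2_contingency(df.to_numpy(), correction=False)
    return TestResult(float(res.statistic), int(res.dof), float(res.pvalue),
                      corrected=False, table=df, method="chi-square (Pearson)")


def chi_square(table) -> TestResult:
    """Dispatch: Yates for 2 x 2, Pearson otherwise."""
    df = _as_table(table)
    return yates_chi_square_2x2(df) if df.shape == (2, 2) else pearson_chi_square_rxc(df)


def build_contingency(metadata: pd.DataFrame, assignments: np.ndarray,
                      variable: str, missing_policy: str = "drop") -> pd.DataFrame:
    """Cluster x category cross-tabulation of one metadata variable.

    ``missing_policy='as_category'`` keeps subjects with a missing value as an
    explicit trailing category; ``'drop'`` excludes them.
    """
    if variable not in metadata.columns:
        raise KeyError(f"unknown metadata variable {variable!r}")
    if missing_policy not in ("drop", "as_category"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    values = metadata[variable].copy()
    labels = pd.Series(np.asarray(assignments), index=metadata.index, name="cluster")
    if missing_policy == "as_category":
        values = values.astype(object).where(values.notna(), MISSING_LABEL)
    else:
        keep = values.notna()
        values, labels = values[keep], labels[keep]
    tab = pd.crosstab(labels, values)
    tab.index = [f"cluster_{c}" for c in tab.index]
    if MISSING_LABEL in tab.columns:  # keep missing as the last category
        tab = tab[[c for c in tab.columns if c != MISSING_LABEL] + [MISSING_LABEL]]
    return tab


def two_sample_continuous(metadata: pd.DataFrame, assignments: np.ndarray,
                          variable: str, method: str = "welch") -> TestResult:
    """Two-sided two-sample t test of a continuous variable across 2 clusters."""
    if variable not in metadata.columns:
        raise KeyError(f"unknown metadata variable {variable!r}")
    if method not in ("welch", "student"):
        raise ValueError(f"unknown method {method!r}")
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("two-sample test requires exactly 2 clusters")
    x = metadata[variable].to_numpy(dtype=float)
    a, b = (x[labels == c] for c in uniq)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if min(len(a), len(b)) < 2:
        raise ValueError(f"{variable}: need >= 2 non-missing values per cluster")
    res = stats.ttest_ind(a, b, equal_var=(method == "student"))
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return TestResult(float(res.statistic), int(np.floor(df)), float(res.pvalue),
                      corrected=False, method=f"t test ({method})")


CONTINUOUS_VARS = ["age", "education", "alsfrs_r"]
CATEGORICAL_VARS = ["sex", "handedness", "onset_site", "als_ftd",
                    "ecas_impaired", "c9orf72"]
#: variables whose missingness is structural and carried as its own category
AS_CATEGORY_VARS = {"ecas_impaired", "c9orf72"}


@dataclass
class ProfileReport:
    """Per-cluster descriptive summaries plus pairwise tests."""

    cluster_sizes: dict[str, int]
    continuous: dict[str, dict] = field(default_factory=dict)
    categorical: dict[str, dict] = field(default_factory=dict)
    tests: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps({
            "cluster_sizes": self.cluster_sizes,
            "continuous": self.continuous,
            "categorical": self.categorical,
            "tests": self.tests,
        }, indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = []
        for cl, n in self.cluster_sizes.items():
            lines.append(f"{cl}: n = {n}")
            for var, per in self.continuous.items():
                m = per[cl]
                lines.append(f"  {var}: {m['mean']:.1f} +/- {m['sd']:.1f}")
            for var, per in self.categorical.items():
                for cat, cnt in per[cl].items():
                    pct = 100.0 * cnt / n
                    lines.append(f"  {var}={cat}: {cnt} ({pct:.1f}%)")
        lines.append("tests:")
        for var, t in self.tests.items():
            lines.append(f"  {var}: {t['method']} statistic={t['statistic']:.2f} "
                         f"p={t['p']:.4g}")
        return "\n".join(lines)


def cluster_profile(metadata: pd.DataFrame, assignments: np.ndarray) -> ProfileReport:
    """Describe and contrast the clusters on all clinical/genetic variables.

    Continuous variables are summarised as mean +/- SD and tested with Welch;
    categorical variables as count (percent of cluster) and tested with the
    appropriate chi-square form.  With a single cluster only the descriptive
    block is produced.
    """
    labels = np.asarray(assignments)
    uniq = sorted(np.unique(labels))
    sizes = {f"cluster_{c}": int((labels == c).sum()) for c in uniq}
    report = ProfileReport(cluster_sizes=sizes)

    for var in CONTINUOUS_VARS:
        per = {}
        for c in uniq:
            v = metadata[var].to_numpy(dtype=float)[labels == c]
            v = v[~np.isnan(v)]
            per[f"cluster_{c}"] = {"mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                                   "n": int(len(v))}
        report.continuous[var] = per

    for var in CATEGORICAL_VARS:
        policy = "as_category" if var in AS_CATEGORY_VARS else "drop"
        tab = build_contingency(metadata, labels, var, missing_policy=policy)
        report.categorical[var] = {
            row: {str(cat): int(tab.loc[row, cat]) for cat in tab.columns}
            for row in tab.index
        }

    if len(uniq) >= 2:
        for var in CONTINUOUS_VARS:
            if len(uniq) == 2:
                t = two_sample_continuous(metadata, labels, var)
                report.tests[var] = {"statistic": t.statistic, "df": t.df,
                                     "p": t.p, "method": t.method}
        for var in CATEGORICAL_VARS:
            policy = "as_category" if var in AS_CATEGORY_VARS else "drop"
            tab = build_contingency(metadata, labels, var, missing_policy=policy)
            if tab.shape[1] < 2:
                continue
            t = chi_square(tab)
            report.tests[var] = {"statistic": t.statistic, "df": t.df,
                                 "p": t.p, "method": t.method}
    return report
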