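import numpy as np
import pandas as pd
import pytest

from alsclust.cohort import ReducedFeatureMatrix, average_bilateral, normalize_volumes_by_tiv
from alsclust.scoring import composite_scores
from alsclust.simulate import default_study_params, generate_cohort, write_cohort
from alsclust.twostep import cluster_scores

ROLE_OF_PREFIX = {"th": "thickness", "vol": "volume_fraction", "fa": "fa"}


def make_reduced(df: pd.DataFrame) -> ReducedFeatureMatrix:
    """Wrap a plain DataFrame of reduced columns for scoring-level tests."""
    roles = {c: ROLE_OF_PREFIX[c.split("_", 1)[0]] for c in df.columns}
    return ReducedFeatureMatrix(values=df, column_roles=roles,
                                pairing_provenance={c: (c,) for c in df.columns})


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject synthetic cohort plus its latent subtype labels."""
    params = default_study_params()
    params.n_subjects = 12
    return generate_cohort(params, seed=7)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory, small_cohort):
    cohort, latent = small_cohort
    outdir = tmp_path_factory.mktemp("cohort12")
    write_cohort(cohort, latent, outdir)
    return outdir


@pytest.fixture(scope="session")
def default_sweep():
    """Full pipeline on 20 default synthetic cohorts (seeds 1..20).

    Shared across the slower recovery tests so the sweep runs once.
    """
    runs = []
    for seed in range(1, 21):
        cohort, latent = generate_cohort(default_study_params(), seed=seed)
        reduced = average_bilateral(normalize_volumes_by_tiv(cohort))
        scores = composite_scores(reduced)
        solution = cluster_scores(scores)
        runs.append({"seed": seed, "latent": latent, "scores": scores,
                     "solution": solution, "metadata": cohort.metadata})
    return runs


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive, point-level implementations)

def naive_centroid_agglomeration(X):
    """O(n^3) centroid-linkage agglomeration recomputing everything from raw
    members at every step.  Returns (merge sequence, partitions per k)."""
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(len(X))}
    merges, partitions = [], {len(X): {i: tuple(m) for i, m in clusters.items()}}
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                ca = X[clusters[a]].mean(axis=0)
                cb = X[clusters[b]].mean(axis=0)
                d = float(np.sqrt(((ca - cb) ** 2).sum()))
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        partitions[len(clusters)] = {i: tuple(m) for i, m in clusters.items()}
    return merges, partitions


def naive_mean_silhouette(X, labels):
    """All-pairs silhouette with explicit python loops."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    total = 0.0
    for i in range(len(X)):
        own = [j for j in range(len(X)) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = sum(np.sqrt(((X[i] - X[j]) ** 2).sum()) for j in own) / len(own)
        b = min(
            sum(np.sqrt(((X[i] - X[j]) ** 2).sum()) for j in range(len(X))
                if labels[j] == c) / sum(labels == c)
            for c in uniq if c != labels[i])
        total += (b - a) / max(a, b)
    return total / len(X)


def partition_sets(assignments):
    """Canonical label-free form of a partition, for comparing clusterings."""
    assignments = np.asarray(assignments)
    return frozenset(frozenset(np.where(assignments == c)[0].tolist())
                     for c in np.unique(assignments))
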