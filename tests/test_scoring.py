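import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alsclust.cohort import average_bilateral, normalize_volumes_by_tiv
from alsclust.scoring import (ScoringError, composite_scores,
                              load_roi_definitions, min_max_scale,
                              roi_raw_indices)

from conftest import make_reduced


def test_min_max_scale_basic():
    scaled, lo, hi = min_max_scale(np.array([1.0, 2.0, 3.0]))
    np.testing.assert_allclose(scaled, [0.0, 0.5, 1.0])
    assert (lo, hi) == (1.0, 3.0)


def test_min_max_scale_guards():
    with pytest.raises(ScoringError):
        min_max_scale(np.array([5.0, 5.0, 5.0]))
    with pytest.raises(ScoringError):
        min_max_scale(np.array([1.0]))


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50).filter(
           lambda xs: max(xs) - min(xs) > 1e-6),
       st.floats(0.01, 100.0), st.floats(-1e3, 1e3))
def test_min_max_scale_matches_recompute_and_is_affine_invariant(xs, a, b):
    x = np.array(xs)
    scaled, lo, hi = min_max_scale(x)
    np.testing.assert_allclose(scaled, (x - x.min()) / (x.max() - x.min()), atol=1e-12)
    assert scaled.min() == 0.0 and scaled.max() == 1.0
    again, _, _ = min_max_scale(a * x + b)
    np.testing.assert_allclose(again, scaled, atol=1e-6)


def _toy_matrix(n=6, seed=0):
    rng = np.random.default_rng(seed)
    cols = {
        "th_precentral": 2.4 + 0.1 * rng.standard_normal(n),
        "th_paracentral": 2.3 + 0.1 * rng.standard_normal(n),
        "fa_corticospinal_tract": 0.45 + 0.02 * rng.standard_normal(n),
        "fa_inferior_fronto_occipital_fasciculus": 0.44 + 0.02 * rng.standard_normal(n),
        "fa_superior_longitudinal_fasciculus": 0.41 + 0.02 * rng.standard_normal(n),
    }
    return make_reduced(pd.DataFrame(cols, index=[f"s{i}" for i in range(n)]))


def test_roi_raw_indices_sums_members():
    from alsclust.scoring import ROIDefinition
    m = _toy_matrix()
    motor = ROIDefinition("motor", ("th_precentral", "th_paracentral"),
                          ("fa_corticospinal_tract",))
    gm, wm = roi_raw_indices(m, motor)
    np.testing.assert_allclose(
        gm.values, m.values["th_precentral"] + m.values["th_paracentral"])
    assert len(wm) == 1
    np.testing.assert_allclose(wm[0].values, m.values["fa_corticospinal_tract"])


def test_long_association_indices_kept_separate():
    from alsclust.scoring import ROIDefinition
    m = _toy_matrix()
    laf = ROIDefinition("long_association_fibres", (),
                        ("fa_inferior_fronto_occipital_fasciculus",
                         "fa_superior_longitudinal_fasciculus"),
                        wm_scaling_mode="separate")
    gm, wm = roi_raw_indices(m, laf)
    assert gm is None and len(wm) == 2
    np.testing.assert_allclose(
        wm[0].values, m.values["fa_inferior_fronto_occipital_fasciculus"])


def test_missing_member_column_raises():
    from alsclust.scoring import ROIDefinition
    m = _toy_matrix()
    roi = ROIDefinition("motor", ("th_precentral", "th_absent"),
                        ("fa_corticospinal_tract",))
    with pytest.raises(ScoringError, match="th_absent"):
        roi_raw_indices(m, roi)


def test_commissural_membership_from_config(small_cohort):
    """The commissural ROI pools the five callosal volume fractions and the
    three callosal FA labels."""
    defs = {r.name: r for r in load_roi_definitions()}
    commissural = defs["commissural"]
    assert set(commissural.gm_members) == {
        "vol_cc_posterior", "vol_cc_middle", "vol_cc_central",
        "vol_cc_mid_anterior", "vol_cc_anterior"}
    assert set(commissural.wm_members) == {
        "fa_forceps_major", "fa_forceps_minor", "fa_body_corpus_callosum"}
    cohort, _ = small_cohort
    reduced = average_bilateral(normalize_volumes_by_tiv(cohort))
    gm, wm = roi_raw_indices(reduced, commissural)
    manual = sum(reduced.values[c] for c in commissural.gm_members)
    np.testing.assert_allclose(gm.values, manual.values)


def test_roi_definitions_cover_all_reduced_columns(small_cohort):
    cohort, _ = small_cohort
    reduced = average_bilateral(normalize_volumes_by_tiv(cohort))
    defs = load_roi_definitions()
    assert len(defs) == 15
    members = [c for r in defs for c in (*r.gm_members, *r.wm_members)]
    assert sorted(members) == sorted(reduced.values.columns)
    laf = [r for r in defs if r.wm_scaling_mode == "separate"]
    assert [r.name for r in laf] == ["long_association_fibres"]
    assert laf[0].gm_members == ()


def test_composite_score_bounds_attained(small_cohort):
    cohort, _ = small_cohort
    reduced = average_bilateral(normalize_volumes_by_tiv(cohort))
    scores = composite_scores(reduced)
    assert scores.values.shape == (cohort.n_subjects, 15)
    assert scores.values.min() >= 0.0 and scores.values.max() <= 2.0
    # a subject sitting at the cohort max of both indices of an ROI scores 2.0
    df = reduced.values.copy()
    champion = df.iloc[0].copy()
    defs = {r.name: r for r in load_roi_definitions()}
    for col in (*defs["motor"].gm_members, *defs["motor"].wm_members):
        champion[col] = df[col].max() + 1.0
    loser = df.iloc[1].copy()
    for col in (*defs["motor"].gm_members, *defs["motor"].wm_members):
        loser[col] = df[col].min() - 1.0
    df.iloc[0], df.iloc[1] = champion, loser
    s2 = composite_scores(make_reduced(df))
    assert s2.scores["motor"].iloc[0] == pytest.approx(2.0)
    assert s2.scores["motor"].iloc[1] == pytest.approx(0.0)


def spreadsheet_composite_scores(reduced_df: pd.DataFrame) -> pd.DataFrame:
    """Independent spreadsheet-style recomputation: explicit python loops and
    the packaged ROI config read directly as YAML."""
    import yaml
    from importlib import resources
    raw = yaml.safe_load(
        resources.files("alsclust.config").joinpath("roi_definitions.yaml").read_text())
    out = {}
    for roi in raw["rois"]:
        gm, wm, mode = roi.get("gm_members") or [], roi["wm_members"], roi.get("wm_scaling_mode", "pooled")
        indices = []
        if gm:
            indices.append([sum(reduced_df.loc[s, c] for c in gm) for s in reduced_df.index])
        if mode == "pooled":
            indices.append([sum(reduced_df.loc[s, c] for c in wm) for s in reduced_df.index])
        else:
            for c in wm:
                indices.append([reduced_df.loc[s, c] for s in reduced_df.index])
        total = [0.0] * len(reduced_df)
        for idx in indices:
            lo, hi = min(idx), max(idx)
            total = [t + (v - lo) / (hi - lo) for t, v in zip(total, idx)]
        out[roi["name"]] = total
    return pd.DataFrame(out, index=reduced_df.index)


def test_composite_scores_match_spreadsheet_recompute(small_cohort):
    cohort, _ = small_cohort
    reduced = average_bilateral(normalize_volumes_by_tiv(cohort))
    ours = composite_scores(reduced).scores
    oracle = spreadsheet_composite_scores(reduced.values)
    pd.testing.assert_frame_equal(ours, oracle[ours.columns], rtol=1e-10)


def test_monotone_in_member_metric(small_cohort):
    """Raising one member metric of a non-extreme subject never lowers that
    subject's ROI score (cohort extremes held fixed)."""
    cohort, _ = small_cohort
    reduced = average_bilateral(normalize_volumes_by_tiv(cohort))
    df = reduced.values.copy()
    col = "th_precentral"
    mid = df[col].rank().sub(df[col].rank().median()).abs().idxmin()
    before = composite_scores(make_reduced(df)).scores.loc[mid, "motor"]
    headroom = df[col].max() - df.loc[mid, col]
    df.loc[mid, col] += 0.5 * headroom
    after = composite_scores(make_reduced(df)).scores.loc[mid, "motor"]
    assert after >= before - 1e-12


def test_scores_invariant_to_column_translations_and_index_rescaling(small_cohort):
    """Min-max scaling of summed indices absorbs (i) translations of any raw
    column and (ii) positive affine maps applied to a whole index (in
    particular to any single-column index)."""
    cohort, _ = small_cohort
    reduced = average_bilateral(normalize_volumes_by_tiv(cohort))
    base = composite_scores(reduced).scores
    # (i) translate one member of a pooled multi-column index
    df = reduced.values.copy()
    df["th_precentral"] = df["th_precentral"] + 5.0
    np.testing.assert_allclose(composite_scores(make_reduced(df)).scores.values,
                               base.values, atol=1e-9)
    # (ii) positive affine map of a separately scaled single-column index
    df = reduced.values.copy()
    df["fa_superior_longitudinal_fasciculus"] = (
        3.0 * df["fa_superior_longitudinal_fasciculus"] + 0.2)
    np.testing.assert_allclose(
        composite_scores(make_reduced(df)).scores["long_association_fibres"].values,
        base["long_association_fibres"].values, atol=1e-9)
    # (ii') positive affine map applied uniformly to a whole pooled index
    df = reduced.values.copy()
    for c in ("fa_fornix", "fa_cingulum"):
        df[c] = 3.0 * df[c] + 0.2
    np.testing.assert_allclose(
        composite_scores(make_reduced(df)).scores["limbic"].values,
        base["limbic"].values, atol=1e-9)


def test_scaling_params_recorded(small_cohort):
    cohort, _ = small_cohort
    reduced = average_bilateral(normalize_volumes_by_tiv(cohort))
    scores = composite_scores(reduced)
    frame = scores.scaling.to_frame()
    assert len(frame) == 30  # two scaled indices per ROI
    assert (frame["max"] > frame["min"]).all()
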