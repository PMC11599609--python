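"""Matrix preparation, PCA, Ward clustering, summaries."""

import numpy as np
import pandas as pd
import pytest

from boxtess.clustering import (prepare_matrix, run_pca, correlation_panel,
                                hierarchical_clusters, cluster_summaries,
                                full_rank_distance_check, CLUSTER_VARIABLES,
                                SHIFT_CONSTANT)
from boxtess.morphometrics import MISSING_FLAG


def toy_records(n=60, seed=0, specimen="s1"):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "specimen": specimen,
        "scute_id": np.arange(1, n + 1),
        "n_neighbors": rng.integers(4, 9, n),
        "volume": np.exp(rng.normal(1, 0.3, n)),
        "area": np.exp(rng.normal(2, 0.3, n)),
        "thickness": np.exp(rng.normal(0, 0.2, n)),
        "width": np.exp(rng.normal(1.2, 0.2, n)),
        "aspect_ratio": np.exp(rng.normal(-1.2, 0.2, n)),
        "cgs": rng.normal(0.002, 0.004, n),
        "cms": rng.normal(0.05, 0.03, n),
    })
    return df


EXP = {"volume": 1.5, "area": 1.0, "thickness": 0.5, "width": 0.5,
       "aspect_ratio": 0.0, "cgs": -1.0, "cms": -0.5}
SA = {"s1": 3000.0, "s2": 9000.0}


def test_prepare_matrix_filters_and_standardizes():
    df = toy_records()
    df.loc[0, "area"] = MISSING_FLAG
    df.loc[1, "area"] = 0.0
    df.loc[2, "volume"] = 1e9  # extreme outlier after log transform
    m = prepare_matrix(df, SA, EXP)
    reasons = m.dropped.set_index("scute_id")["reason"]
    assert reasons.loc[1] == "area_missing"
    assert reasons.loc[2] == "area_zero"
    assert reasons.loc[3] == "outlier"
    assert len(m.data) + len(m.dropped) == len(df)
    assert np.allclose(m.data.mean(), 0, atol=1e-9)
    assert np.allclose(m.data.std(ddof=0), 1, atol=1e-9)


def test_shifted_log_minimum_is_finite():
    df = toy_records()
    m = prepare_matrix(df, SA, EXP, mad_factor=np.inf)
    # the column minimum maps to log(SHIFT_CONSTANT): finite
    assert np.isfinite(m.data.to_numpy()).all()
    raw_min = np.log(SHIFT_CONSTANT)
    back = m.data["cgs"] * m.column_sds["cgs"] + m.column_means["cgs"]
    assert back.min() == pytest.approx(raw_min)


def test_missing_sa_excludes_with_warning():
    df = pd.concat([toy_records(specimen="s1"),
                    toy_records(seed=1, specimen="unknown")])
    with pytest.warns(UserWarning, match="no SA"):
        m = prepare_matrix(df, SA, EXP)
    assert (m.dropped.reason == "missing_sa").sum() == 60
    assert set(m.meta.specimen) == {"s1"}


def test_pca_properties():
    m = prepare_matrix(toy_records(n=200), SA, EXP)
    scores, loadings, var_exp = run_pca(m)
    assert var_exp.sum() == pytest.approx(100.0)
    # sign convention: largest |loading| of each PC is positive
    for col in loadings.columns:
        v = loadings[col].to_numpy()
        assert v[np.argmax(np.abs(v))] > 0
    # full-rank scores preserve pairwise distances
    assert full_rank_distance_check(m, scores) < 1e-8


def test_perfectly_correlated_columns_share_pc1():
    df = toy_records(n=150)
    df["volume"] = df["width"] ** 3  # deterministic link after logs
    m = prepare_matrix(df, SA, EXP)
    _, loadings, _ = run_pca(m)
    l1 = loadings["PC1"]
    assert abs(l1["volume"] - l1["width"]) < 0.02 or \
        np.corrcoef(m.data["volume"], m.data["width"])[0, 1] > 0.999


def test_correlation_panel_symmetric_unit_diagonal():
    m = prepare_matrix(toy_records(), SA, EXP)
    corr = correlation_panel(m)
    assert np.allclose(corr, corr.T, atol=1e-12)
    assert np.allclose(np.diag(corr), 1.0)


def test_planted_covariance_recovered():
    # volume built from width: strong positive correlation, as for real
    # scutes where volume tracks in-plane size
    df = toy_records(n=300, seed=3)
    df["volume"] = df["width"] ** 3 * np.exp(
        np.random.default_rng(4).normal(0, 0.05, 300))
    m = prepare_matrix(df, SA, EXP)
    assert correlation_panel(m).loc["volume", "width"] > 0.9


def test_two_blobs_recovered_exactly():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.3, size=(40, 3))
    b = rng.normal(5, 0.3, size=(40, 3))
    scores = np.vstack([a, b])
    meta = pd.DataFrame({"specimen": ["s"] * 80,
                         "scute_id": np.arange(80)})
    model = hierarchical_clusters(scores, k=2, meta=meta)
    lab = model.assignment
    assert len(set(lab[:40])) == 1
    assert len(set(lab[40:])) == 1
    assert lab[0] != lab[-1]


def test_k_edge_cases():
    scores = np.random.default_rng(1).normal(size=(30, 4))
    meta = pd.DataFrame({"specimen": ["s"] * 30,
                         "scute_id": np.arange(30)})
    m1 = hierarchical_clusters(scores, k=1, meta=meta)
    assert set(m1.assignment) == {1}
    with pytest.raises(ValueError):
        hierarchical_clusters(scores, k=31)


def test_cluster_summaries_and_frequencies():
    df = pd.concat([toy_records(specimen="s1"),
                    toy_records(seed=2, specimen="s2")],
                   ignore_index=True)
    sa = {"s1": 3000.0, "s2": 9000.0}
    m = prepare_matrix(df, sa, EXP)
    scores, loadings, var_exp = run_pca(m)
    model = hierarchical_clusters(scores, k=3, meta=m.meta,
                                  loadings=loadings,
                                  variance_explained=var_exp)
    model = cluster_summaries(model, m)
    freq = model.frequencies.set_index("specimen")
    counts = m.meta.groupby("specimen").size()
    count_cols = [c for c in freq.columns if c.startswith("count_")]
    assert (freq[count_cols].sum(axis=1) == counts).all()
    prop_cols = [c for c in freq.columns if c.startswith("prop_")]
    assert np.allclose(freq[prop_cols].sum(axis=1), 1.0)
    assert set(model.summaries.cluster) == {1, 2, 3}
    assert {"mean", "median", "q1", "q3"} <= set(model.summaries.columns)


def test_degenerate_identical_scutes_handled():
    df = toy_records(n=20)
    for col in CLUSTER_VARIABLES:
        df[col] = df[col].iloc[0]
    m = prepare_matrix(df, SA, EXP)
    scores, *_ = run_pca(m)
    model = hierarchical_clusters(scores, k=2, meta=m.meta)
    model = cluster_summaries(model, m)  # no error on degenerate stats
    assert len(model.assignment) == 20


def test_pipeline_determinism_and_duplicate_stability():
    df = toy_records(n=250, seed=9)
    m1 = prepare_matrix(df, SA, EXP)
    m2 = prepare_matrix(df.copy(), SA, EXP)
    s1, l1, _ = run_pca(m1)
    s2, l2, _ = run_pca(m2)
    assert np.array_equal(
        hierarchical_clusters(s1, k=4, meta=m1.meta).assignment,
        hierarchical_clusters(s2, k=4, meta=m2.meta).assignment)
    # adding one duplicated row barely moves the loadings
    dup = pd.concat([df, df.iloc[[10]]], ignore_index=True)
    dup.loc[len(dup) - 1, "scute_id"] = 999
    m3 = prepare_matrix(dup, SA, EXP)
    _, l3, _ = run_pca(m3)
    assert np.max(np.abs(l3.to_numpy() - l1.to_numpy())) < 5e-2
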