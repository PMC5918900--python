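"""Decontamination, prevalence filtering and rarefaction behaviour."""

import numpy as np
import pandas as pd
import pytest

from clonalherit.preprocess import (auto_depth, expected_richness, normalize_depth,
                                    prevalence_filter, rarefaction_curve,
                                    remove_control_otus)

from conftest import build_dataset, meta_row


def test_control_otus_removed_everywhere(toy_network):
    out = remove_control_otus(toy_network)
    assert "o3" not in out.counts.columns            # in the control pot
    assert "ctrl" not in out.counts.index            # controls dropped
    assert out.counts.loc["m", "o1"] == 5            # other counts untouched


def test_decontamination_idempotent_and_warns_without_controls(toy_network):
    once = remove_control_otus(toy_network)
    twice = remove_control_otus(once)
    pd.testing.assert_frame_equal(once.counts, twice.counts)
    assert any("warning" in p for p in twice.provenance)


def test_prevalence_boundary_kept():
    counts = {f"s{i}": {"keep": 1 if i < 3 else 0, "drop": 1 if i < 2 else 0,
                        "fill": 5} for i in range(5)}
    meta = {f"s{i}": meta_row(role="internode", position="NA") for i in range(5)}
    ds = build_dataset(counts, meta)
    out = prevalence_filter(ds, min_samples=3)
    assert "keep" in out.counts.columns and "drop" not in out.counts.columns
    out1 = prevalence_filter(ds, min_samples=1)
    assert set(out1.counts.columns) == {"keep", "drop", "fill"}
    with pytest.raises(ValueError):
        prevalence_filter(ds, min_samples=6)


def test_prevalence_filter_matches_brute_force():
    rng = np.random.default_rng(7)
    mat = rng.integers(0, 3, size=(20, 50)) * (rng.random((20, 50)) < 0.3)
    counts = {f"s{i}": {f"o{j}": int(mat[i, j]) for j in range(50)} for i in range(20)}
    meta = {f"s{i}": meta_row(role="internode", position="NA") for i in range(20)}
    ds = build_dataset(counts, meta)
    for k in (1, 2, 3, 5):
        kept = set(prevalence_filter(ds, k).counts.columns)
        brute = {f"o{j}" for j in range(50) if int((mat[:, j] > 0).sum()) >= k}
        assert kept == brute


def test_rarefied_sums_hit_depth_exactly(study):
    ds, _ = study
    from clonalherit.dataset import subset_dataset
    bac = subset_dataset(ds, {"marker": "bacteria_16S"})
    out = normalize_depth(bac, 9000, seed=3)
    assert (out.counts.sum(axis=1) == 9000).all()


def test_normalize_depth_keeps_full_sample_and_drops_short():
    counts = {"a": {"o1": 600, "o2": 400}, "b": {"o1": 500, "o2": 400}}
    meta = {"a": meta_row(role="internode", position="NA"),
            "b": meta_row(role="internode", position="NA")}
    ds = build_dataset(counts, meta)
    out = normalize_depth(ds, 1000, seed=0)
    assert list(out.counts.index) == ["a"]
    assert out.counts.loc["a", "o1"] == 600  # total == depth: counts unchanged
    with pytest.raises(ValueError):
        normalize_depth(ds, 2000, seed=0)


def test_rarefied_mean_matches_hypergeometric():
    # OTU with c reads of T total: mean subsampled count = c * depth / T
    counts = {"a": {"o1": 300, "o2": 500, "o3": 200}}
    meta = {"a": meta_row(role="internode", position="NA")}
    ds = build_dataset(counts, meta)
    depth, n = 400, 400
    draws = np.array([normalize_depth(ds, depth, seed=s).counts.loc["a", "o1"]
                      for s in range(n)], dtype=float)
    expect = 300 * depth / 1000
    # hypergeometric variance for the standard error of the mean
    var = depth * 0.3 * 0.7 * (1000 - depth) / 999
    assert abs(draws.mean() - expect) < 3 * np.sqrt(var / n)


def test_rarefaction_curve_endpoints_and_monotonicity():
    counts = {"a": {"o1": 40, "o2": 5, "o3": 1}, "b": {"o1": 10}}
    meta = {k: meta_row(role="internode", position="NA") for k in counts}
    ds = build_dataset(counts, meta)
    curves = {c.sample_id: c for c in rarefaction_curve(ds, [1, 5, 20, 46])}
    a = curves["a"].expected_richness
    assert np.all(np.diff(a[~np.isnan(a)]) >= -1e-12)
    assert a[-1] == pytest.approx(3)                 # full depth = observed richness
    b = curves["b"].expected_richness
    assert b[0] == pytest.approx(1) and np.isnan(b[-1])  # one OTU; depth>total is NaN


def test_analytic_curve_agrees_with_monte_carlo():
    rng = np.random.default_rng(5)
    row = rng.integers(0, 30, size=12)
    row[0] = max(row[0], 1)
    counts = {"a": {f"o{j}": int(row[j]) for j in range(12)}}
    meta = {"a": meta_row(role="internode", position="NA")}
    ds = build_dataset(counts, meta)
    grid = [5, 20, 60]
    exact = rarefaction_curve(ds, grid)[0].expected_richness
    mc_curves = rarefaction_curve(ds, grid, n_draws=1000, seed=1)[0].expected_richness
    total = int(sum(row))
    for d, e, m in zip(grid, exact, mc_curves):
        if d > total:
            continue
        se = np.sqrt(max(e * (1 - e / 12), 0.05) / 1000)  # loose per-draw variance bound
        assert abs(e - m) < max(3 * se, 0.15)


def test_auto_depth_retains_most_samples(study):
    ds, _ = study
    from clonalherit.dataset import subset_dataset
    bac = prevalence_filter(subset_dataset(ds, {"marker": "bacteria_16S"}), 3)
    depth = auto_depth(bac)
    totals = bac.counts.sum(axis=1)
    assert (totals >= depth).mean() >= 0.9
    assert depth == int(f"{str(depth)[0]}" + "0" * (len(str(depth)) - 1))  # 1 sig digit
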