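import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from playmotion.stats import (
    PCC_GROUPINGS,
    alpha_for_planned_comparisons,
    bh_adjust,
    correlation_power,
    feature_characteristics,
    pearson_matrix,
    redundancy_prune,
    spearman_vs_scores,
)


def reference_bh(p):
    """Independently coded textbook step-up procedure."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = p[idx] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def make_fm(columns):
    """Feature matrix from {(activity, keypoint, feature): values}."""
    fm = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    fm.columns = pd.MultiIndex.from_tuples(
        fm.columns, names=["activity", "keypoint", "feature"]
    )
    fm.index = [f"c{i}" for i in range(len(fm))]
    return fm


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_single_p_unchanged():
    assert bh_adjust([0.04])[0] == pytest.approx(0.04)


def test_bh_matches_reference_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(200):
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(bh_adjust(p), reference_bh(p), atol=1e-12)


def test_bh_properties():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=30)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)


def test_bh_families_adjust_independently():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    fam = np.array(["a", "b", "a", "b"])
    adj = bh_adjust(p, fam)
    assert np.allclose(adj[[0, 2]], reference_bh(p[[0, 2]]))
    assert np.allclose(adj[[1, 3]], reference_bh(p[[1, 3]]))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_matches_scipy():
    rng = np.random.default_rng(2)
    x = rng.normal(size=20)
    s = rng.integers(0, 3, size=20)
    rho, p = spearman_vs_scores(x, s)
    ref = sps.spearmanr(x, s)
    assert rho == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
    assert abs(rho) <= 1.0


def test_spearman_handles_missing_pairwise():
    x = np.array([1.0, np.nan, 3.0, 2.0, 5.0])
    s = np.array([0, 1, 1, 2, 2])
    rho, _ = spearman_vs_scores(x, s)
    ref = sps.spearmanr([1.0, 3.0, 2.0, 5.0], [0, 1, 2, 2])
    assert rho == pytest.approx(ref.statistic)


def test_spearman_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        spearman_vs_scores([1.0, 2.0, 3.0], [0, 1, 2])  # too few pairs
    with pytest.raises(ValueError):
        spearman_vs_scores([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])  # constant scores


# ---------------------------------------------------------------------------
# Pearson matrices and redundancy pruning


def test_pearson_matrix_groupings_and_validation(small_result):
    fm = small_result.feature_matrix
    m = pearson_matrix(
        fm, "across-keypoints-same-MF-same-activity",
        activity="Table-play", feature="L_mean",
    )
    assert m.shape == (3, 3)
    assert np.allclose(np.diag(m), 1.0)
    assert np.nanmax(np.abs(m.to_numpy())) <= 1.0 + 1e-12
    with pytest.raises(ValueError):
        pearson_matrix(fm, "no-such-grouping")
    for grouping in PCC_GROUPINGS:
        with pytest.raises(ValueError):
            pearson_matrix(fm, grouping)  # missing selector kwargs


def test_pearson_constant_column_gives_nan():
    fm = make_fm(
        {
            ("A", "neck", "L_mean"): [1.0, 1.0, 1.0, 1.0],
            ("A", "mid_hip", "L_mean"): [1.0, 2.0, 3.0, 4.0],
        }
    )
    m = pearson_matrix(
        fm, "across-keypoints-same-MF-same-activity", activity="A", feature="L_mean"
    )
    assert np.isnan(m.loc["neck", "mid_hip"])


def _prune_fixture(rng):
    n = 40
    x = rng.normal(size=n)
    independent = rng.normal(size=n)
    return make_fm(
        {
            # PD block: affine copies, pairwise PCC exactly 1 -> neck only.
            ("A", "neck", "L_mean"): x,
            ("A", "right_wrist", "L_mean"): 2 * x + 1,
            ("A", "mid_hip", "L_mean"): 0.5 * x - 3,
            # IPV block: one keypoint uncorrelated -> retain all three.
            ("A", "neck", "dL_mean"): x,
            ("A", "right_wrist", "dL_mean"): x + 0.01 * rng.normal(size=n),
            ("A", "mid_hip", "dL_mean"): independent,
        }
    )


def test_redundancy_prune_selection_logic():
    fm = _prune_fixture(np.random.default_rng(3))
    retained = set(redundancy_prune(fm, threshold=0.95))
    assert {(a, k, f) for (a, k, f) in retained if f == "L_mean"} == {
        ("A", "neck", "L_mean")
    }
    assert {(a, k, f) for (a, k, f) in retained if f == "dL_mean"} == {
        ("A", "neck", "dL_mean"),
        ("A", "right_wrist", "dL_mean"),
        ("A", "mid_hip", "dL_mean"),
    }


def test_redundancy_prune_threshold_one_keeps_everything():
    rng = np.random.default_rng(4)
    fm = make_fm(
        {
            ("A", "neck", "L_mean"): rng.normal(size=20),
            ("A", "right_wrist", "L_mean"): rng.normal(size=20),
            ("A", "mid_hip", "L_mean"): rng.normal(size=20),
        }
    )
    assert len(redundancy_prune(fm, threshold=1.0)) == 3
    with pytest.raises(ValueError):
        redundancy_prune(fm, threshold=0.0)


# ---------------------------------------------------------------------------
# alpha and power


def test_alpha_for_planned_comparisons_validation():
    assert alpha_for_planned_comparisons(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        alpha_for_planned_comparisons(0.05, 0)
    with pytest.raises(ValueError):
        alpha_for_planned_comparisons(1.5, 4)


def test_power_null_effect_limit_approaches_alpha():
    assert correlation_power(52, 1e-9, 0.05) == pytest.approx(0.05, abs=1e-3)


def test_power_monotone_in_n_and_r():
    p_small = correlation_power(20, 0.5, 0.05)
    p_large = correlation_power(80, 0.5, 0.05)
    assert p_large > p_small
    assert correlation_power(40, 0.6, 0.05) > correlation_power(40, 0.3, 0.05)


def test_power_one_sided_exceeds_two_sided():
    assert correlation_power(40, 0.4, 0.05, two_sided=False) > correlation_power(
        40, 0.4, 0.05, two_sided=True
    )


def test_power_domain_errors():
    for bad in [(3, 0.5, 0.05), (40, 0.0, 0.05), (40, 1.0, 0.05), (40, 0.5, 0.0)]:
        with pytest.raises(ValueError):
            correlation_power(*bad)


def test_power_agrees_with_pingouin():
    pingouin = pytest.importorskip("pingouin")
    for n, r, alpha in [(52, 0.5, 0.0125), (30, 0.4, 0.05), (100, 0.2, 0.01)]:
        ref = float(pingouin.power_corr(r=r, n=n, alpha=alpha, alternative="two-sided"))
        assert correlation_power(n, r, alpha) == pytest.approx(ref, abs=1e-9)


# ---------------------------------------------------------------------------
# characteristics and report invariants


def test_feature_characteristics_known_values():
    stats = feature_characteristics([1.0, 2.0, 3.0, 4.0])
    assert stats["n"] == 4
    assert stats["mean"] == 2.5 and stats["median"] == 2.5
    assert stats["sd"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
    assert stats["q1"] == 1.75 and stats["q3"] == 3.25
    assert stats["min"] == 1.0 and stats["max"] == 4.0
    with pytest.raises(ValueError):
        feature_characteristics([1.0])


def test_correlation_report_invariants(small_result):
    scc = small_result.report.scc
    valid = scc.dropna(subset=["scc"])
    assert (valid.scc.abs() <= 1.0 + 1e-12).all()
    assert (valid.p_bh >= valid.p_raw - 1e-12).all()
    assert (valid.p_bh <= 1.0).all()
    power = small_result.report.power
    assert power["alpha"] == 0.0125
    assert 0.0 < power["power"] < 1.0
    # Every retained triple names an existing feature column.
    cols = set(small_result.feature_matrix.columns)
    assert set(small_result.report.retained) <= cols
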