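import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iqspr.data_model import (
    DescriptorTable,
    PropertyTable,
    RetentionSeries,
    ValidationError,
)
from iqspr.preprocess import (
    Autoscaler,
    apply_filters,
    correlation_filter,
    fit_logkw,
    kennard_stone_indices,
    kennard_stone_split,
    rsd_filter,
    zero_filter,
)


def _table(cols: dict, kinds=None):
    names = list(cols)
    values = np.column_stack([np.asarray(cols[n], dtype=float) for n in names])
    ids = [f"c{i}" for i in range(values.shape[0])]
    return DescriptorTable(ids, names, values, kinds or [])


# ---------------------------------------------------------------------------
# RSD filter


def test_rsd_removes_constant_and_all_zero_keeps_varying():
    desc = _table({
        "const": [7, 7, 7],          # RSD 0 -> removed
        "zero": [0, 0, 0],           # all-zero -> removed
        "vary": [1, 2, 3],           # RSD 50% -> kept at threshold 5
        "meanzero": [-1, 0, 1],      # mean 0, sd > 0 -> RSD undefined -> kept
    })
    assert rsd_filter(desc, 5.0) == ["const", "zero"]


def test_rsd_hand_arithmetic():
    # sd([1,2,3]) = 1, mean = 2 -> RSD = 50%; removed only above a 50% cut
    desc = _table({"v": [1, 2, 3]})
    assert rsd_filter(desc, 49.9) == []
    assert rsd_filter(desc, 50.1) == ["v"]


def test_rsd_invert_flag_removes_high_variance():
    desc = _table({"low": [100, 101, 100], "high": [1, 5, 9]})
    assert rsd_filter(desc, 5.0, remove_high=True) == ["high"]


# ---------------------------------------------------------------------------
# Correlation filter


def _props(y1, y2):
    n = len(y1)
    return PropertyTable([f"c{i}" for i in range(n)],
                         np.asarray(y1, float), np.asarray(y2, float))


def test_identical_columns_lower_y_correlation_removed():
    x = [1.0, 2.0, 3.0, 4.0]
    y_strong = [1.0, 2.1, 2.9, 4.2]
    desc = _table({"a": x, "b": x, "probe": y_strong})
    # 'a' and 'b' identical; both equally correlated with Y -> tie keeps 'a'
    props = _props(y_strong, [0.3, -0.2, 0.4, 0.1])
    assert correlation_filter(desc.subset(["a", "b"]), props, 0.8) == ["b"]


def test_orthogonal_columns_untouched():
    desc = _table({"a": [1, -1, 1, -1], "b": [1, 1, -1, -1]})
    props = _props([1, 2, 3, 4], [4, 3, 2, 1])
    assert correlation_filter(desc, props, 0.8) == []


def _brute_force_correlation_filter(desc, props, threshold):
    """Oracle: literal re-implementation with explicit pair bookkeeping."""
    X = desc.values
    p = X.shape[1]
    Y = props.Y

    def corr(u, v):
        if np.std(u, ddof=1) == 0 or np.std(v, ddof=1) == 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    ry = [max(abs(corr(X[:, j], Y[:, 0])), abs(corr(X[:, j], Y[:, 1])))
          for j in range(p)]
    pairs = [(abs(corr(X[:, i], X[:, j])), i, j)
             for i in range(p) for j in range(i + 1, p)]
    pairs = [t for t in pairs if t[0] > threshold]
    pairs.sort(key=lambda t: -t[0])
    removed = set()
    for _, i, j in pairs:
        if i in removed or j in removed:
            continue
        removed.add(j if ry[i] >= ry[j] else i)
    return [desc.descriptor_names[j] for j in sorted(removed)]


def test_planted_correlated_triple_matches_brute_force():
    rng = np.random.default_rng(7)
    base = rng.standard_normal(12)
    desc = _table({
        "t1": base,
        "t2": base + 0.01 * rng.standard_normal(12),
        "t3": -base + 0.01 * rng.standard_normal(12),
        "free": rng.standard_normal(12),
    })
    props = _props(base + 0.1 * rng.standard_normal(12),
                   rng.standard_normal(12))
    got = correlation_filter(desc, props, 0.8)
    assert got == _brute_force_correlation_filter(desc, props, 0.8)
    assert len(got) == 2  # exactly one member of the triple survives


# ---------------------------------------------------------------------------
# Zero filter


def test_zero_filter_rules():
    desc = _table(
        {"cont_zero": [0.0, 1.2, 3.4], "bin": [0, 1, 0],
         "int_zero": [0, 2, 5], "cont_pos": [1.1, 2.2, 3.3]},
        kinds=["continuous", "binary", "integer", "continuous"])
    assert zero_filter(desc) == ["cont_zero"]


def test_filter_report_partitions_names(synthetic_dataset):
    desc, props, _ = synthetic_dataset
    filtered, report = apply_filters(desc, props)
    assert sorted(report.all_names()) == sorted(desc.descriptor_names)
    assert filtered.descriptor_names == report.surviving


# ---------------------------------------------------------------------------
# Autoscaling


def test_autoscale_self_gives_mean0_sd1():
    rng = np.random.default_rng(0)
    X = rng.random((10, 4)) * 5
    s = Autoscaler().fit(X)
    Z = s.transform(X)
    np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)


def test_autoscale_roundtrip_and_mean_row():
    rng = np.random.default_rng(1)
    X = rng.random((8, 3))
    s = Autoscaler().fit(X)
    np.testing.assert_allclose(s.inverse_transform(s.transform(X)), X,
                               atol=1e-12)
    np.testing.assert_allclose(s.transform(X.mean(axis=0)[None, :]), 0,
                               atol=1e-12)


def test_autoscale_rejects_zero_variance_column():
    X = np.column_stack([np.ones(5), np.arange(5.0)])
    with pytest.raises(ValidationError, match="0"):
        Autoscaler().fit(X)


# ---------------------------------------------------------------------------
# Kennard-Stone


def _brute_force_ks(X, n_train):
    """Oracle: exhaustive max-min selection with explicit candidate scans."""
    n = X.shape[0]
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    best = max(((D[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
               key=lambda t: t[0])
    selected = [best[1], best[2]]
    while len(selected) < n_train:
        cands = [k for k in range(n) if k not in selected]
        picks = [(min(D[k, s] for s in selected), -k, k) for k in cands]
        selected.append(max(picks)[2])
    return selected


def test_ks_two_points_both_in_train():
    desc = _table({"d": [0.0, 1.0]})
    res = kennard_stone_split(desc, 2)
    assert sorted(res.train_ids) == ["c0", "c1"]
    assert res.test_ids == []


def test_ks_line_example_matches_brute_force():
    X = np.array([[0.0], [1.0], [2.0], [7.0], [10.0]])
    assert kennard_stone_indices(X, 3) == _brute_force_ks(X, 3)
    # seed pair is {0, 10}, third pick maximises min distance -> point at 7
    assert set(kennard_stone_indices(X, 3)) == {0, 4, 3}


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1),
       st.integers(min_value=4, max_value=8))
def test_ks_matches_brute_force_on_random_sets(seed, n):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3))
    n_train = rng.integers(2, n)
    assert kennard_stone_indices(X, int(n_train)) == _brute_force_ks(X, int(n_train))


def test_ks_study_scale_sizes(synthetic_dataset):
    desc, _, _ = synthetic_dataset
    res = kennard_stone_split(desc, 33)
    assert (len(res.train_ids), len(res.test_ids)) == (33, 12)
    assert set(res.train_ids) | set(res.test_ids) == set(desc.compound_ids)
    assert not set(res.train_ids) & set(res.test_ids)


def test_ks_permutation_equivariance():
    rng = np.random.default_rng(3)
    ids = [f"c{i}" for i in range(9)]
    X = rng.standard_normal((9, 2))
    desc = DescriptorTable(ids, ["a", "b"], X)
    perm = rng.permutation(9)
    desc_p = DescriptorTable([ids[i] for i in perm], ["a", "b"], X[perm])
    res = kennard_stone_split(desc, 5)
    res_p = kennard_stone_split(desc_p, 5)
    assert set(res.train_ids) == set(res_p.train_ids)


# ---------------------------------------------------------------------------
# Lipophilicity fit


def test_two_point_line_is_exact():
    fit = fit_logkw(RetentionSeries(np.array([0.2, 0.4]), np.array([3.0, 2.0])))
    assert fit.logkw == pytest.approx(4.0)
    assert fit.S == pytest.approx(-5.0)
    assert fit.residual_sse == pytest.approx(0.0, abs=1e-20)


def test_noisy_fit_matches_normal_equations():
    rng = np.random.default_rng(5)
    phi = np.array([0.1, 0.25, 0.4, 0.55, 0.7])
    logk = 4.2 - 4.0 * phi + 0.05 * rng.standard_normal(5)
    fit = fit_logkw(RetentionSeries(phi, logk))
    A = np.column_stack([np.ones(5), phi])
    beta = np.linalg.solve(A.T @ A, A.T @ logk)
    assert fit.logkw == pytest.approx(beta[0], abs=1e-12)
    assert fit.S == pytest.approx(beta[1], abs=1e-12)


def test_collinear_points_have_zero_residual():
    phi = np.array([0.1, 0.3, 0.5, 0.9])
    fit = fit_logkw(RetentionSeries(phi, 2.5 - 3.0 * phi))
    assert fit.residual_sse == pytest.approx(0.0, abs=1e-20)
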