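import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from masegc.errors import PreprocessError
from masegc.io_core import LabelTable, Modality, OmicsMatrix
from masegc.preprocess import (
    apply_minmax,
    benjamini_hochberg,
    filter_low_abundance,
    fit_minmax,
    knn_impute,
    moderated_differential_screen,
)
from masegc.synthetic_data import inject_missingness


def _matrix(values, modality=Modality.MRNA):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        modality,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
    )


# -- zero filter -----------------------------------------------------------


def test_filter_removes_strictly_above_threshold():
    row_70 = [0.0] * 7 + [1.0] * 3   # 0.7 > 0.6 -> removed
    row_60 = [0.0] * 6 + [1.0] * 4   # exactly 0.6 -> retained
    row_00 = [1.0] * 10              # retained
    m = _matrix([row_70, row_60, row_00])
    out = filter_low_abundance(m, 0.6)
    assert out.feature_ids == ["g1", "g2"]


def test_filter_all_removed_errors():
    m = _matrix([[0.0] * 10])
    with pytest.raises(PreprocessError):
        filter_low_abundance(m, 0.6)


def test_filter_preserves_order():
    rows = np.eye(5)  # each feature has 1/5 zeros... actually 4/5 zeros
    m = _matrix(rows)
    out = filter_low_abundance(m, 0.9)
    assert out.feature_ids == m.feature_ids


# -- KNN imputation --------------------------------------------------------


def test_impute_no_missing_is_identity(tiny_matrix):
    out = knn_impute(tiny_matrix, k=1)
    np.testing.assert_array_equal(out.values, tiny_matrix.values)


def test_impute_nearest_neighbor_by_hand():
    # s1 == s2 on observed features; s1 missing g3 -> copies s2's value
    vals = np.array(
        [
            [1.0, 1.0, 9.0],
            [2.0, 2.0, 8.0],
            [np.nan, 7.0, 3.0],
        ]
    )
    m = _matrix(vals, Modality.METHYLATION)
    out = knn_impute(m, k=1)
    assert out.values[2, 0] == 7.0


def test_impute_constant_matrix():
    vals = np.full((3, 6), 4.2)
    vals[1, 2] = np.nan
    out = knn_impute(_matrix(vals, Modality.METHYLATION), k=3)
    assert out.values[1, 2] == pytest.approx(4.2)


def test_impute_preserves_observed_and_stays_in_range(rng):
    base = _matrix(rng.random((20, 30)), Modality.METHYLATION)
    holey = inject_missingness(base, 0.15, seed=8)
    out = knn_impute(holey, k=5)
    obs = ~np.isnan(holey.values)
    np.testing.assert_array_equal(out.values[obs], holey.values[obs])
    imputed = out.values[~obs]
    lo = np.nanmin(holey.values, axis=1)
    hi = np.nanmax(holey.values, axis=1)
    rows = np.where(~obs)[0]
    assert ((imputed >= lo[rows]) & (imputed <= hi[rows])).all()


def test_impute_feature_missing_everywhere_errors():
    vals = np.array([[np.nan, np.nan], [1.0, 2.0]])
    with pytest.raises(PreprocessError, match="g0"):
        knn_impute(_matrix(vals, Modality.METHYLATION), k=1)


def test_impute_with_reference_uses_only_donors():
    train = _matrix(np.array([[1.0, 3.0], [10.0, 30.0]]), Modality.METHYLATION)
    test_vals = np.array([[1.0, np.nan], [np.nan, 31.0]])
    test = _matrix(test_vals, Modality.METHYLATION)
    out = knn_impute(test, k=1, reference=train)
    # column 0 matches train sample s0 on g0 -> g1 imputed from s0
    assert out.values[1, 0] == 10.0
    # column 1 matches train sample s1 on g1 -> g0 imputed from s1
    assert out.values[0, 1] == 3.0


# -- min-max scaling -------------------------------------------------------


def test_minmax_basic_formula():
    m = _matrix([[0.0, 5.0, 10.0]])
    out = apply_minmax(m, fit_minmax(m))
    np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])


def test_minmax_constant_feature_maps_to_zero():
    m = _matrix([[3.0, 3.0, 3.0]])
    out = apply_minmax(m, fit_minmax(m))
    np.testing.assert_array_equal(out.values, [[0.0, 0.0, 0.0]])


def test_minmax_clips_new_data():
    train = _matrix([[0.0, 10.0]])
    stats_ = fit_minmax(train)
    new = _matrix([[15.0, -5.0]])
    out = apply_minmax(new, stats_)
    np.testing.assert_array_equal(out.values, [[1.0, 0.0]])


def test_minmax_preserves_rank_order(rng):
    m = _matrix(rng.normal(size=(5, 12)))
    out = apply_minmax(m, fit_minmax(m))
    for i in range(5):
        np.testing.assert_array_equal(
            np.argsort(out.values[i], kind="stable"),
            np.argsort(m.values[i], kind="stable"),
        )


def test_minmax_feature_mismatch_errors(tiny_matrix):
    other = _matrix(np.ones((2, 2)))
    with pytest.raises(PreprocessError):
        apply_minmax(tiny_matrix, fit_minmax(other))


# -- Benjamini-Hochberg ----------------------------------------------------


def test_bh_worked_example():
    out = benjamini_hochberg([0.001, 0.01, 0.02, 0.9])
    np.testing.assert_allclose(out, [0.004, 0.02, 0.0266667, 0.9], rtol=1e-5)


def test_bh_all_equal_unchanged():
    out = benjamini_hochberg([0.3, 0.3, 0.3])
    np.testing.assert_allclose(out, [0.3, 0.3, 0.3])


def test_bh_single_value():
    assert benjamini_hochberg([0.42])[0] == pytest.approx(0.42)


def test_bh_domain_error():
    with pytest.raises(PreprocessError):
        benjamini_hochberg([0.5, 1.5])


def _bh_brute_force(p):
    """Literal step-up definition, written independently of the implementation."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        q = min(1.0, p[i] * m / rank)
        running_min = min(running_min, q)
        adj[i] = running_min
    return adj


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    st.lists(
        st.one_of(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            st.sampled_from([0.0, 1.0, 0.05, 0.05]),  # force ties and extremes
        ),
        min_size=1,
        max_size=30,
    )
)
def test_bh_property_matches_step_up_definition(pvals):
    out = benjamini_hochberg(pvals)
    np.testing.assert_allclose(out, _bh_brute_force(pvals), atol=1e-12)
    assert ((out >= np.asarray(pvals) - 1e-15) & (out <= 1.0)).all()
    # tied p-values receive identical adjusted values
    for i, p in enumerate(pvals):
        for j, q in enumerate(pvals):
            if p == q:
                assert out[i] == out[j]


def test_bh_matches_brute_force_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(50):
        p = rng.random(size=rng.integers(1, 40))
        ours = benjamini_hochberg(p)
        np.testing.assert_allclose(ours, _bh_brute_force(p), atol=1e-12)
        np.testing.assert_allclose(
            ours, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


# -- moderated screen ------------------------------------------------------


def _two_group_matrix(rng, n1=20, n0=20, p=50, shift_rows=(), shift=10.0):
    X = rng.normal(size=(p, n1 + n0))
    for r in shift_rows:
        X[r, :n1] += shift
    labels = LabelTable(
        [f"s{j}" for j in range(n1 + n0)],
        np.array([1] * n1 + [0] * n0),
    )
    m = OmicsMatrix(Modality.MRNA, [f"g{i}" for i in range(p)], labels.sample_ids, X)
    return m, labels


def test_screen_constant_feature_not_selected(rng):
    m, labels = _two_group_matrix(rng)
    m.values[0, :] = 5.0
    res = moderated_differential_screen(m, labels)
    assert res.pvalues[0] == pytest.approx(1.0)
    assert not res.selected[0]


def test_screen_flags_separated_classes(rng):
    m, labels = _two_group_matrix(rng, shift_rows=(3,), shift=10.0)
    res = moderated_differential_screen(m, labels, alpha=0.001)
    assert res.adjusted[3] < 0.001
    assert res.selected[3]
    assert set(res.selected_features) == {"g3"}


def test_screen_null_type_one_error(rng):
    m, labels = _two_group_matrix(rng, n1=25, n0=25, p=1000)
    res = moderated_differential_screen(m, labels, alpha=0.001)
    assert res.selected.sum() <= 5


def test_screen_adjusted_at_least_raw(rng):
    m, labels = _two_group_matrix(rng, shift_rows=(0, 1), shift=3.0)
    res = moderated_differential_screen(m, labels)
    assert (res.adjusted >= res.pvalues - 1e-15).all()
    assert ((res.adjusted >= 0) & (res.adjusted <= 1)).all()


def test_screen_needs_two_per_class(rng):
    m, labels = _two_group_matrix(rng, n1=1, n0=10)
    with pytest.raises(PreprocessError):
        moderated_differential_screen(m, labels)


def test_screen_matches_ordinary_t_when_variances_homogeneous(rng):
    """With exactly equal per-feature variances the prior df goes to infinity
    and every variance shrinks to the common value; the moderated t then
    orders features exactly like the classic pooled-variance statistic."""
    from scipy import stats as sps

    m, labels = _two_group_matrix(rng, n1=30, n0=30, p=200, shift_rows=(0, 5), shift=1.0)
    res = moderated_differential_screen(m, labels)
    t_classic, _ = sps.ttest_ind(m.values[:, :30], m.values[:, 30:], axis=1)
    ours = np.argsort(-np.abs(res.t_statistics))[:5]
    classic = np.argsort(-np.abs(t_classic))[:5]
    assert len(set(ours[:2]) & set(classic[:2])) >= 1
    assert res.prior_df > 0
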