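"""Network construction: oracle equivalence, degenerate cases, invariants."""

import numpy as np
import pytest

import oracles
from hyperfcn import (
    ConnectivityMatrix,
    RoiTimeSeries,
    average_hyperedge_series,
    build_corr_of_corr_fcn,
    build_hypergraph_hon,
    build_incidence,
    build_low_order_fcn,
)
from hyperfcn.fcn import LOW_ORDER, DegenerateCorrelationWarning


def make_subject(data, **kw):
    return RoiTimeSeries(np.asarray(data, dtype=float), **kw)


class TestLowOrder:
    def test_identical_and_negated_columns(self, rng):
        base = rng.standard_normal(20)
        data = np.column_stack([base, base, -base, rng.standard_normal(20)])
        lon = build_low_order_fcn(make_subject(data))
        assert lon.values[0, 1] == pytest.approx(1.0)
        assert lon.values[0, 2] == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        # hand-specified columns; expected entries from the closed-form sum formula
        cols = [(1, 2, 3, 4), (1, 2, 3, 5), (4, 3, 2, 1), (2, 7, 1, 8)]
        data = np.array(cols, dtype=float).T
        lon = build_low_order_fcn(make_subject(data))
        for i in range(4):
            for j in range(i + 1, 4):
                expected = oracles.pearson(data[:, i], data[:, j])
                assert lon.values[i, j] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((rng.integers(5, 50), rng.integers(4, 10)))
        lon = build_low_order_fcn(make_subject(data))
        np.testing.assert_allclose(lon.values, oracles.low_order(data), atol=1e-10)

    def test_paper_shape_170x116(self):
        data = np.random.default_rng(0).standard_normal((170, 116))
        lon = build_low_order_fcn(make_subject(data))
        assert lon.values.shape == (116, 116)

    def test_constant_column_imputed_and_flagged(self, rng):
        data = rng.standard_normal((20, 5))
        data[:, 2] = 3.14
        with pytest.warns(DegenerateCorrelationWarning):
            lon = build_low_order_fcn(make_subject(data))
        assert lon.values[2, 0] == 0.0
        assert (0, 2) in lon.degenerate_pairs
        assert lon.values[2, 2] == 1.0

    def test_rejects_nonfinite_with_location(self, rng):
        data = rng.standard_normal((10, 5))
        data[3, 2] = np.nan
        with pytest.raises(ValueError, match="timepoint 4, ROI 3"):
            make_subject(data)

    def test_scale_invariance(self, rng):
        data = rng.standard_normal((25, 6))
        scaled = data.copy()
        scaled[:, 2] *= 17.5
        a = build_low_order_fcn(make_subject(data)).values
        b = build_low_order_fcn(make_subject(scaled)).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCorrOfCorr:
    def test_identity_input_all_degenerate(self):
        lon = ConnectivityMatrix(np.eye(5), kind=LOW_ORDER)
        with pytest.warns(DegenerateCorrelationWarning):
            hon = build_corr_of_corr_fcn(lon)
        off = hon.values[~np.eye(5, dtype=bool)]
        assert (off == 0.0).all()
        assert len(hon.degenerate_pairs) == 10

    def test_rejects_three_rois(self):
        lon = ConnectivityMatrix(np.eye(3), kind=LOW_ORDER)
        with pytest.raises(ValueError, match="at least 4 ROIs"):
            build_corr_of_corr_fcn(lon)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_exclusion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lon = build_low_order_fcn(make_subject(rng.standard_normal((40, 6))))
        hon = build_corr_of_corr_fcn(lon)
        np.testing.assert_allclose(
            hon.values, oracles.corr_of_corr(lon.values), atol=1e-10
        )

    def test_scale_invariance_through_low_order(self, rng):
        data = rng.standard_normal((25, 6))
        scaled = data.copy()
        scaled[:, 4] *= 3.0
        a = build_corr_of_corr_fcn(build_low_order_fcn(make_subject(data))).values
        b = build_corr_of_corr_fcn(build_low_order_fcn(make_subject(scaled))).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestIncidence:
    def test_high_threshold_gives_identity(self, random_subject):
        lon = build_low_order_fcn(random_subject)
        off = lon.values[~np.eye(lon.n, dtype=bool)]
        t = min(0.99, off.max() + 0.001)
        H = build_incidence(lon, t).H
        np.testing.assert_array_equal(H, np.eye(lon.n, dtype=np.uint8))

    def test_zero_threshold_keeps_all_nonnegative(self):
        values = np.full((5, 5), 0.4)
        np.fill_diagonal(values, 1.0)
        lon = ConnectivityMatrix(values, kind=LOW_ORDER)
        assert build_incidence(lon, 0.0).H.all()

    def test_signed_comparison_at_default_threshold(self):
        # inclusive, signed: 0.70 passes, 0.69 and -0.8 fail at t = 0.7
        values = np.eye(5)
        entries = {(0, 1): 0.71, (0, 2): 0.69, (0, 3): 0.70, (0, 4): -0.8}
        for (i, j), v in entries.items():
            values[i, j] = values[j, i] = v
        lon = ConnectivityMatrix(values, kind=LOW_ORDER)
        H = build_incidence(lon, 0.7).H
        assert H[1, 0] == 1 and H[3, 0] == 1
        assert H[2, 0] == 0 and H[4, 0] == 0
        # absolute-value variant admits the strong negative correlation
        assert build_incidence(lon, 0.7, absolute=True).H[4, 0] == 1

    def test_threshold_monotonicity(self, random_subject):
        lon = build_low_order_fcn(random_subject)
        grid = [0.1 + 0.05 * k for k in range(18)]
        previous = build_incidence(lon, grid[0]).H
        for t in grid[1:]:
            current = build_incidence(lon, t).H
            assert (current <= previous).all()
            previous = current

    def test_rejects_out_of_range_threshold(self, random_subject):
        lon = build_low_order_fcn(random_subject)
        for t in (-0.1, 1.5):
            with pytest.raises(ValueError, match="threshold"):
                build_incidence(lon, t)


class TestHyperedgeAveraging:
    def test_identity_incidence_is_noop(self, random_subject):
        lon = build_low_order_fcn(random_subject)
        hg = build_incidence(lon, 1.0)
        if not (hg.H == np.eye(hg.n)).all():
            pytest.skip("correlations of exactly 1.0 off-diagonal; not expected")
        hs = average_hyperedge_series(random_subject, hg)
        np.testing.assert_array_equal(hs.data, random_subject.data)

    def test_all_ones_incidence_gives_global_mean(self, random_subject):
        from hyperfcn.fcn import HypergraphIncidence

        n = random_subject.n_rois
        hg = HypergraphIncidence(np.ones((n, n), dtype=int), threshold=0.0)
        hs = average_hyperedge_series(random_subject, hg)
        mean = random_subject.data.mean(axis=1)
        for j in range(n):
            np.testing.assert_allclose(hs.data[:, j], mean, atol=1e-12)

    def test_pairwise_mean_by_hand(self):
        from hyperfcn.fcn import HypergraphIncidence

        data = np.arange(16, dtype=float).reshape(4, 4)
        H = np.eye(4, dtype=int)
        H[1, 0] = 1  # e_1 = {ROI1, ROI2}
        hg = HypergraphIncidence(H, threshold=0.5)
        ts = make_subject(data)
        hs = average_hyperedge_series(ts, hg)
        np.testing.assert_allclose(hs.data[:, 0], (data[:, 0] + data[:, 1]) / 2)
        np.testing.assert_allclose(hs.data[:, 1:], data[:, 1:])

    def test_dimension_mismatch_rejected(self, random_subject):
        from hyperfcn.fcn import HypergraphIncidence

        hg = HypergraphIncidence(np.eye(5, dtype=int), threshold=0.5)
        with pytest.raises(ValueError, match="ROIs"):
            average_hyperedge_series(random_subject, hg)


class TestHypergraphHon:
    def test_degenerate_high_threshold_reduces_to_low_order(self, random_subject):
        lon = build_low_order_fcn(random_subject)
        off = lon.values[~np.eye(lon.n, dtype=bool)]
        t = min(1.0, off.max() + 1e-6)
        hg = build_incidence(lon, t)
        np.testing.assert_array_equal(hg.H, np.eye(lon.n, dtype=np.uint8))
        hchon = build_hypergraph_hon(average_hyperedge_series(random_subject, hg))
        np.testing.assert_allclose(hchon.values, lon.values, atol=1e-10)

    def test_degenerate_low_threshold_gives_unit_offdiagonal(self):
        # all pairwise correlations above t=0: a cohort of positively
        # correlated series makes every hyperedge the full ROI set
        rng = np.random.default_rng(3)
        shared = rng.standard_normal(30)
        data = shared[:, None] + 0.1 * rng.standard_normal((30, 5))
        ts = make_subject(data)
        lon = build_low_order_fcn(ts)
        assert lon.values.min() > 0.0
        hg = build_incidence(lon, 0.0)
        assert hg.H.all()
        hchon = build_hypergraph_hon(average_hyperedge_series(ts, hg))
        np.testing.assert_allclose(hchon.values, np.ones((5, 5)), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_end_to_end_matches_composed_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((20, 8))
        ts = make_subject(data)
        lon = build_low_order_fcn(ts)
        hg = build_incidence(lon, 0.3)
        hchon = build_hypergraph_hon(average_hyperedge_series(ts, hg))
        np.testing.assert_allclose(
            hchon.values, oracles.hypergraph_hon(data, 0.3), atol=1e-10
        )


@pytest.mark.parametrize("seed", range(3))
def test_permutation_equivariance(seed):
    """Relabeling ROIs permutes every network's rows/columns consistently."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((25, 7))
    perm = rng.permutation(7)
    t = 0.25
    for build in (
        lambda d: build_low_order_fcn(make_subject(d)).values,
        lambda d: build_corr_of_corr_fcn(build_low_order_fcn(make_subject(d))).values,
        lambda d: oracles_free_hchon(d, t),
    ):
        original = build(data)
        permuted = build(data[:, perm])
        np.testing.assert_allclose(permuted, original[np.ix_(perm, perm)], atol=1e-10)


def oracles_free_hchon(data, t):
    ts = make_subject(data)
    lon = build_low_order_fcn(ts)
    hg = build_incidence(lon, t)
    return build_hypergraph_hon(average_hyperedge_series(ts, hg)).values


def test_connectivity_matrix_invariants_enforced():
    bad = np.eye(4)
    bad[0, 1] = 0.5  # asymmetric
    with pytest.raises(ValueError, match="symmetric"):
        ConnectivityMatrix(bad, kind=LOW_ORDER)
    bad2 = np.eye(4)
    bad2[0, 0] = 0.9
    with pytest.raises(ValueError, match="diagonal"):
        ConnectivityMatrix(bad2, kind=LOW_ORDER)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=25, deadline=None, derandomize=True, database=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    t1=st.floats(0.0, 1.0),
    t2=st.floats(0.0, 1.0),
)
def test_incidence_monotone_in_threshold_property(seed, t1, t2):
    """t1 <= t2 implies H(t2) is an elementwise subset of H(t1)."""
    t1, t2 = min(t1, t2), max(t1, t2)
    rng = np.random.default_rng(seed)
    lon = build_low_order_fcn(make_subject(rng.standard_normal((15, 6))))
    assert (build_incidence(lon, t2).H <= build_incidence(lon, t1).H).all()
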