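import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltrank.mask import CONTROL, SALT
from saltrank.ranking import (BayesTable, ClassHistogram, NRDCurve, auc_energy,
                              balance_classes, bayes_table, binned_posterior,
                              class_histograms, mdpa, nrd_curve, rank_lines,
                              stratified_subsample, wavelength_to_energy)
from saltrank.similarity import SimilarityField


def hist_from_counts(counts):
    counts = np.asarray(counts, dtype=int)
    b = len(counts)
    values = np.concatenate([
        np.full(c, (k + 0.5) / b) for k, c in enumerate(counts)
    ]) if counts.sum() else np.array([])
    return ClassHistogram(counts, b, values)


def field_from_values(s_control, s_salt):
    s = np.concatenate([s_control, s_salt])
    labels = np.concatenate([np.full(len(s_control), CONTROL, dtype=np.int8),
                             np.full(len(s_salt), SALT, dtype=np.int8)])
    coords = np.column_stack([np.zeros(len(s), dtype=int), np.arange(len(s))])
    return SimilarityField(s, labels, coords)


def transport_cost_sorted(counts_a, counts_b):
    """Optimal pair-assignment cost between two histograms with equal
    totals: match the sorted expansions element by element."""
    ea = np.repeat(np.arange(len(counts_a)), counts_a)
    eb = np.repeat(np.arange(len(counts_b)), counts_b)
    return int(np.abs(ea - eb).sum())


def transport_cost_all_permutations(counts_a, counts_b):
    """Literal exhaustive minimal pair assignment (n! search)."""
    ea = np.repeat(np.arange(len(counts_a)), counts_a)
    eb = np.repeat(np.arange(len(counts_b)), counts_b)
    return min(sum(abs(x - y) for x, y in zip(ea, perm))
               for perm in itertools.permutations(eb))


class TestNrdCurve:
    def test_identical_classes_give_zero(self, rng):
        C = rng.random((5, 10))
        curve = nrd_curve(C, C, np.linspace(400, 800, 5))
        np.testing.assert_allclose(curve.nrd, 0.0)

    def test_arithmetic(self):
        C = np.full((1, 4), 0.5)
        S = np.full((1, 3), 0.4)
        curve = nrd_curve(C, S, [600.0])
        assert curve.nrd[0] == pytest.approx(0.2)

    def test_scale_invariance(self, rng):
        C, S = rng.random((6, 8)) + 0.1, rng.random((6, 9)) + 0.1
        wl = np.linspace(400, 900, 6)
        a = nrd_curve(C, S, wl)
        b = nrd_curve(3.2 * C, 3.2 * S, wl)
        np.testing.assert_allclose(a.nrd, b.nrd)

    def test_zero_control_mean_flagged(self):
        C = np.array([[0.0, 0.0], [0.5, 0.5]])
        S = np.array([[0.1, 0.1], [0.4, 0.4]])
        curve = nrd_curve(C, S, [500.0, 600.0])
        assert not curve.defined[0] and np.isnan(curve.nrd[0])
        assert curve.defined[1]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            nrd_curve(np.empty((3, 0)), np.ones((3, 2)), [4, 5, 6])


class TestAucEnergy:
    def test_zero_curve(self):
        curve = NRDCurve(np.zeros(5), np.linspace(400, 800, 5), np.ones(5, bool))
        assert auc_energy(curve) == 0.0

    def test_planck_two_band_area(self):
        # unit NRD between 500 and 600 nm: area = |hc/500nm - hc/600nm|
        curve = NRDCurve(np.ones(2), np.array([500.0, 600.0]),
                         np.ones(2, bool))
        h, c = 6.62607015e-34, 2.99792458e8
        expected = abs(h * c / 500e-9 - h * c / 600e-9)
        assert auc_energy(curve) == pytest.approx(expected)
        assert expected == pytest.approx(6.623e-20, rel=1e-3)

    def test_linearity_in_nrd(self, rng):
        wl = np.linspace(420, 880, 12)
        nrd = rng.normal(size=12)
        one = auc_energy(NRDCurve(nrd, wl, np.ones(12, bool)))
        two = auc_energy(NRDCurve(2 * nrd, wl, np.ones(12, bool)))
        assert two == pytest.approx(2 * one)

    def test_undefined_bands_excluded(self):
        nrd = np.array([1.0, np.nan, 1.0])
        defined = np.array([True, False, True])
        curve = NRDCurve(nrd, np.array([500.0, 550.0, 600.0]), defined)
        expected = abs(wavelength_to_energy(500) - wavelength_to_energy(600))
        assert auc_energy(curve) == pytest.approx(expected)

    def test_single_band_rejected(self):
        curve = NRDCurve(np.ones(1), np.array([500.0]), np.ones(1, bool))
        with pytest.raises(ValueError):
            auc_energy(curve)


class TestClassHistograms:
    def test_boundary_and_bin_arithmetic(self):
        field = field_from_values([0.005, 1.0], [1.0, 1.0])
        hc, hs = class_histograms(field, b=100)
        assert hc.counts[0] == 1 and hc.counts[99] == 1  # s=1 in last bin
        assert hs.counts[99] == 2
        assert hc.counts.sum() == hc.n and hs.counts.sum() == hs.n

    def test_moments_from_raw_values(self, rng):
        vals = rng.random(500)
        field = field_from_values(vals, rng.random(300))
        hc, _ = class_histograms(field, b=10)
        assert hc.mean == pytest.approx(vals.mean())
        assert hc.sd == pytest.approx(vals.std(ddof=1))

    def test_empty_class_rejected(self):
        field = field_from_values([0.5], [0.5])
        field.labels[:] = CONTROL
        with pytest.raises(ValueError):
            class_histograms(field)


class TestStratifiedSubsample:
    def test_identity_at_ratio_one(self, rng):
        h = hist_from_counts([5, 3, 2])
        out = stratified_subsample(h, 10, rng)
        np.testing.assert_array_equal(out.counts, h.counts)

    def test_exact_proportions(self, rng):
        h = hist_from_counts([100, 300])
        out = stratified_subsample(h, 200, rng)
        np.testing.assert_array_equal(out.counts, [50, 150])

    def test_largest_remainder_totals_exact(self, rng):
        h = hist_from_counts([7, 7, 7])
        out = stratified_subsample(h, 11, rng)
        assert out.n == 11
        assert np.all(np.abs(out.counts - 11 / 3) <= 1)

    def test_deterministic_under_seed(self):
        h = hist_from_counts([40, 25, 35])
        a = stratified_subsample(h, 60, seed=3)
        b = stratified_subsample(h, 60, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            stratified_subsample(hist_from_counts([4]), 0)

    def test_distribution_shape_preserved(self, rng):
        h = hist_from_counts([400, 200, 100, 300])
        out = stratified_subsample(h, 500, rng)
        np.testing.assert_allclose(out.counts / out.n, h.counts / h.n,
                                   atol=0.01)


class TestMdpa:
    def test_identity(self):
        h = hist_from_counts([2, 0, 1])
        assert mdpa(h, h) == 0.0

    def test_worked_examples(self):
        assert mdpa(hist_from_counts([2, 0, 1]),
                    hist_from_counts([1, 1, 1])) == pytest.approx(1 / 3)
        assert mdpa(hist_from_counts([3, 0, 0]),
                    hist_from_counts([0, 0, 3])) == pytest.approx(2.0)
        assert mdpa(hist_from_counts([3, 0, 0]),
                    hist_from_counts([0, 0, 3]), normalized=False) == 6.0

    def test_unequal_totals_rejected(self):
        with pytest.raises(ValueError, match="equal totals"):
            mdpa(hist_from_counts([2, 1]), hist_from_counts([1, 1]))

    def test_not_shuffling_invariant(self):
        # permuting bins changes the distance (ordinal, unlike Euclidean)
        a, b = [3, 0, 1], [1, 0, 3]
        base = mdpa(hist_from_counts(a), hist_from_counts(b))
        perm = mdpa(hist_from_counts([0, 3, 1]), hist_from_counts([0, 1, 3]))
        assert base != perm
        # Euclidean distance is identical for both arrangements
        assert np.linalg.norm(np.subtract(a, b)) == pytest.approx(
            np.linalg.norm(np.subtract([0, 3, 1], [0, 1, 3])))

    def test_matches_sorted_transport_oracle_random(self, rng):
        for _ in range(50):
            b = int(rng.integers(2, 8))
            n = int(rng.integers(1, 12))
            ca = rng.multinomial(n, np.ones(b) / b)
            cb = rng.multinomial(n, np.ones(b) / b)
            expected = transport_cost_sorted(ca, cb) / n
            assert mdpa(hist_from_counts(ca), hist_from_counts(cb)) == \
                pytest.approx(expected)

    def test_sorted_oracle_matches_permutation_search(self, rng):
        for _ in range(10):
            b = int(rng.integers(2, 5))
            n = int(rng.integers(1, 6))
            ca = rng.multinomial(n, np.ones(b) / b)
            cb = rng.multinomial(n, np.ones(b) / b)
            assert transport_cost_sorted(ca, cb) == \
                transport_cost_all_permutations(ca, cb)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_metric_properties(self, data):
        b = data.draw(st.integers(2, 6))
        n = data.draw(st.integers(1, 10))
        draw_counts = st.lists(st.integers(0, n), min_size=b, max_size=b)

        def norm(cs):
            cs = np.array(cs)
            if cs.sum() == 0:
                cs[0] = n
            # rescale to total n by largest remainder
            h = np.floor(cs * n / cs.sum()).astype(int)
            rem = n - h.sum()
            order = np.argsort(-(cs * n / cs.sum() - h))
            h[order[:rem]] += 1
            return h

        ha = norm(data.draw(draw_counts))
        hb = norm(data.draw(draw_counts))
        hc = norm(data.draw(draw_counts))
        d_ab = mdpa(hist_from_counts(ha), hist_from_counts(hb))
        d_ba = mdpa(hist_from_counts(hb), hist_from_counts(ha))
        d_ac = mdpa(hist_from_counts(ha), hist_from_counts(hc))
        d_cb = mdpa(hist_from_counts(hc), hist_from_counts(hb))
        assert d_ab == d_ba
        assert d_ab <= d_ac + d_cb + 1e-12
        assert d_ab >= 0


class TestBayesTable:
    def test_printed_component_reproduction(self):
        # class-conditional 89.77%, evidence 70.88% -> posterior 63.33%
        t = BayesTable.from_evidence(0.8977, 0.7088)
        assert round(t.posterior * 100, 2) == 63.33
        assert t.cc_control == pytest.approx(2 * 0.7088 - 0.8977)

    def test_uninformative_observation(self):
        t = BayesTable.from_conditionals(0.4, 0.4)
        assert t.posterior == pytest.approx(0.5)

    def test_perfectly_separating_observation(self):
        t = BayesTable.from_conditionals(0.6, 0.0)
        assert t.posterior == pytest.approx(1.0)

    def test_undefined_posterior_flagged(self):
        t = BayesTable.from_conditionals(0.0, 0.0)
        assert math.isnan(t.posterior)

    def test_internal_consistency(self, rng):
        for _ in range(50):
            cc_s, cc_c = rng.random(2)
            a = BayesTable.from_conditionals(cc_s, cc_c)
            b = BayesTable.from_evidence(cc_s, a.evidence)
            assert abs(a.posterior - b.posterior) < 1e-12
            assert a.evidence == pytest.approx(
                0.5 * a.cc_salt + 0.5 * a.cc_control)

    def test_field_based_table(self, rng):
        s_ctrl = rng.uniform(0, 0.6, 500)
        s_salt = rng.uniform(0.4, 1.0, 500)
        t = bayes_table(field_from_values(s_ctrl, s_salt))
        assert t.cc_salt == pytest.approx(np.mean(s_salt > 0.5))
        assert t.prior == 0.5

    def test_unbalanced_classes_rejected(self, rng):
        field = field_from_values(rng.random(10), rng.random(11))
        with pytest.raises(ValueError, match="balanced"):
            bayes_table(field)

    def test_split_rule_is_strict(self):
        field = field_from_values([0.5, 0.5], [0.5, 0.6])
        t = bayes_table(field)
        assert t.cc_salt == pytest.approx(0.5)  # s == 0.5 not counted
        assert t.cc_control == 0.0


class TestBinnedPosterior:
    def test_pure_salt_bin(self):
        field = field_from_values([0.05], [0.95])
        post = binned_posterior(field, nbins=10)
        assert post[9] == 1.0 and post[0] == 0.0
        assert np.isnan(post[5])

    def test_exchangeable_classes_near_half(self, rng):
        vals = rng.random(2000)
        field = field_from_values(vals[:1000], vals[1000:])
        post = binned_posterior(field, nbins=10)
        ok = ~np.isnan(post)
        assert np.all(np.abs(post[ok] - 0.5) < 0.15)

    def test_complement_property(self, rng):
        field = field_from_values(rng.random(300), rng.random(300))
        post = binned_posterior(field, nbins=10)
        ok = ~np.isnan(post)
        np.testing.assert_allclose(post[ok] + (1 - post[ok]), 1.0)


class TestRankLines:
    def test_smaller_posterior_is_more_tolerant(self):
        result = rank_lines({"A": 0.5021, "B": 0.6333}, "posterior")
        assert result.order == ["A", "B"]

    def test_ties_flagged(self):
        result = rank_lines({"A": 1.0, "B": 1.0, "C": 2.0}, "mdpa")
        assert ("A", "B") in result.ties
        assert result.order == ["A", "B", "C"]

    def test_invariant_under_monotone_transform(self, rng):
        vals = {f"L{i}": float(v) for i, v in enumerate(rng.random(6))}
        a = rank_lines(vals, "auc")
        b = rank_lines({k: math.exp(3 * v) for k, v in vals.items()}, "auc")
        assert a.order == b.order

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            rank_lines({"A": 1.0}, "auc")


class TestBalanceClasses:
    def test_equal_totals_after_balancing(self, rng):
        field = field_from_values(rng.random(400), rng.random(250))
        hc, hs = class_histograms(field, b=20)
        hc_b, hs_b = balance_classes(hc, hs, rng)
        assert hc_b.n == hs_b.n == 250
        np.testing.assert_array_equal(hs_b.counts, hs.counts)
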