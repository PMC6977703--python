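import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cerna_profiler.profiles import (
    GeneSeries,
    assign_profiles,
    enumerate_profiles,
    profile_significance,
    select_pattern_genes,
    to_log2_series,
)

from conftest import make_matrix


def brute_force_shapes(T, c, exclude_flat):
    """Independent enumeration: all length-T vectors from 0 with steps in [-c, c]."""
    shapes = set()
    for diffs in itertools.product(range(-c, c + 1), repeat=T - 1):
        v = [0]
        for d in diffs:
            v.append(v[-1] + d)
        shapes.add(tuple(v))
    if exclude_flat:
        shapes.discard(tuple([0] * T))
    return shapes


class TestEnumerateProfiles:
    def test_four_conditions_unit_change_gives_26(self):
        assert len(enumerate_profiles(4, 1, exclude_flat=True)) == 26

    @pytest.mark.parametrize(
        "T,c,exclude_flat,expected",
        [(2, 1, True, 2), (3, 2, True, 24), (4, 1, False, 27), (5, 2, True, 624)],
    )
    def test_closed_form_counts(self, T, c, exclude_flat, expected):
        assert len(enumerate_profiles(T, c, exclude_flat)) == expected

    def test_T2_profiles_are_up_and_down(self):
        ps = enumerate_profiles(2, 1, exclude_flat=True)
        assert set(ps.profiles) == {(0, -1), (0, 1)}

    @pytest.mark.parametrize("T", [2, 3, 4, 5])
    @pytest.mark.parametrize("c", [1, 2])
    @pytest.mark.parametrize("exclude_flat", [True, False])
    def test_matches_brute_force_enumeration(self, T, c, exclude_flat):
        ps = enumerate_profiles(T, c, exclude_flat)
        assert set(ps.profiles) == brute_force_shapes(T, c, exclude_flat)
        assert len(ps.profiles) == len(set(ps.profiles))
        assert len(ps) == (2 * c + 1) ** (T - 1) - (1 if exclude_flat else 0)

    def test_ids_are_lexicographic_and_stable(self):
        ps = enumerate_profiles(4, 1, True)
        assert list(ps.profiles) == sorted(ps.profiles)
        assert ps.id_of((0, -1, -1, -2)) == ps.profiles.index((0, -1, -1, -2))

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            enumerate_profiles(1, 1, True)


class TestLog2Series:
    def test_halving_series_in_small_pseudocount_limit(self):
        m = make_matrix([[10, 10, 5, 5, 5, 5, 2.5, 2.5]])
        (s,) = to_log2_series(m, pseudocount=1e-9)
        np.testing.assert_allclose(s.values, [0, -1, -1, -2], atol=1e-6)

    def test_constant_gene_gives_all_zero_series(self):
        m = make_matrix([[7, 7, 7, 7, 7, 7, 7, 7]])
        (s,) = to_log2_series(m)
        np.testing.assert_array_equal(s.values, [0, 0, 0, 0])

    def test_zero_reference_handled_by_pseudocount(self):
        m = make_matrix([[0, 0, 1, 1, 3, 3, 7, 7]])
        (s,) = to_log2_series(m, pseudocount=1.0)
        np.testing.assert_allclose(s.values, [0, 1, 2, 3])


class TestAssignProfiles:
    def test_series_matching_a_profile_gets_similarity_one(self):
        ps = enumerate_profiles(4, 1, True)
        (a,) = assign_profiles([GeneSeries("g", [0, -1, -1, -2])], ps)
        assert ps.profiles[a.profile_id] == (0, -1, -1, -2)
        assert a.similarity == pytest.approx(1.0)

    def test_flat_series_unassigned_with_reason(self):
        ps = enumerate_profiles(4, 1, True)
        (a,) = assign_profiles([GeneSeries("g", [0, 0, 0, 0])], ps)
        assert not a.assigned
        assert a.reason == "zero-variance"

    def test_length_mismatch_rejected(self):
        ps = enumerate_profiles(4, 1, True)
        with pytest.raises(ValueError, match="does not match T"):
            assign_profiles([GeneSeries("g", [0, 1, 2])], ps)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_argmax_scan(self, seed):
        """Assignment equals an exhaustive per-gene pearsonr scan over all profiles."""
        rng = np.random.default_rng(seed)
        ps = enumerate_profiles(4, 1, True)
        series = [
            GeneSeries(f"g{i}", np.concatenate([[0.0], rng.normal(0, 1, 3)]))
            for i in range(10)
        ]
        got = assign_profiles(series, ps)
        for s, a in zip(series, got):
            if np.ptp(s.values) == 0:
                assert not a.assigned
                continue
            best_id, best_r = None, -np.inf
            for j, shape in enumerate(ps.profiles):
                r = stats.pearsonr(s.values, np.array(shape, float)).statistic
                if r > best_r + 1e-12:
                    best_id, best_r = j, r
            assert a.profile_id == best_id
            assert a.similarity == pytest.approx(best_r)

    @settings(max_examples=50, deadline=None)
    @given(
        base=st.lists(st.floats(-4, 4), min_size=3, max_size=3),
        scale=st.floats(0.1, 10),
        shift=st.floats(-5, 5),
    )
    def test_invariant_to_positive_affine_scaling(self, base, scale, shift):
        """Pearson-based assignment ignores positive affine transforms."""
        values = np.concatenate([[0.0], np.asarray(base)])
        if np.ptp(values) < 1e-6:  # avoid float-degenerate collapse to flat
            return
        ps = enumerate_profiles(4, 1, True)
        (a1,) = assign_profiles([GeneSeries("g", values)], ps)
        scaled = values * scale + shift
        scaled = scaled - scaled[0]  # re-reference, as the transform would
        (a2,) = assign_profiles([GeneSeries("g", scaled)], ps)
        assert a1.profile_id == a2.profile_id

    def test_min_similarity_filters_with_reason(self):
        ps = enumerate_profiles(4, 1, True)
        (a,) = assign_profiles([GeneSeries("g", [0, 0.01, -0.01, 0.005])], ps, min_similarity=0.99)
        assert not a.assigned
        assert a.reason == "below-min-similarity"


class TestProfileSignificance:
    def _random_instance(self, seed, n=20):
        rng = np.random.default_rng(seed)
        ps = enumerate_profiles(4, 1, True)
        series = [
            GeneSeries(f"g{i}", np.concatenate([[0.0], rng.normal(0, 1, 3)]))
            for i in range(n)
        ]
        return ps, series

    def test_expected_count_equals_brute_force_over_24_permutations(self):
        ps, series = self._random_instance(7)
        assignments = assign_profiles(series, ps)
        sig = profile_significance(assignments, series, ps, permutations="exhaustive")
        # independent oracle: loop over all 24 permutations, re-reference,
        # re-assign with pearsonr, average the counts
        perms = list(itertools.permutations(range(4)))
        counts = np.zeros((len(perms), len(ps)))
        for k, perm in enumerate(perms):
            for s in series:
                v = s.values[list(perm)]
                v = v - v[0]
                if np.ptp(v) == 0:
                    continue
                rs = [stats.pearsonr(v, np.array(p, float)).statistic for p in ps.profiles]
                counts[k, int(np.argmax(rs))] += 1
        expected = counts.mean(axis=0)
        got = np.array([x.expected_count for x in sig])
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_observed_equal_to_expected_gives_central_p(self):
        """When a profile's observed count sits at the null mean the upper
        binomial tail cannot be small."""
        ps, series = self._random_instance(3)
        assignments = assign_profiles(series, ps)
        sig = profile_significance(assignments, series, ps)
        for s in sig:
            if s.observed_count == round(s.expected_count):
                assert s.p_value >= 0.3

    def test_p_values_in_unit_interval(self):
        ps, series = self._random_instance(11)
        assignments = assign_profiles(series, ps)
        for s in profile_significance(assignments, series, ps):
            assert 0.0 <= s.p_value <= 1.0

    def test_sampled_mode_needs_enough_draws(self):
        ps, series = self._random_instance(1)
        assignments = assign_profiles(series, ps)
        with pytest.raises(ValueError, match="at least 10 draws"):
            profile_significance(assignments, series, ps, permutations=5)

    def test_flat_null_rarely_produces_significant_profiles(self):
        """Calibration: on pure flat-noise data few profiles reach p < 0.05."""
        ps = enumerate_profiles(4, 1, True)
        frac = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            series = [
                GeneSeries(f"g{i}", np.concatenate([[0.0], rng.normal(0, 0.3, 3)]))
                for i in range(100)
            ]
            assignments = assign_profiles(series, ps)
            sig = profile_significance(assignments, series, ps)
            frac.append(np.mean([s.p_value < 0.05 for s in sig]))
        assert np.mean(frac) <= 0.12


class TestSelectPatternGenes:
    def test_noise_free_planted_genes_recovered_exactly(self):
        ps = enumerate_profiles(4, 1, True)
        planted = [GeneSeries(f"p{i}", [0, -1, -1, -2]) for i in range(5)]
        other = [GeneSeries(f"o{i}", [0, 1, 1, 2]) for i in range(5)]
        assignments = assign_profiles(planted + other, ps)
        genes, _ = select_pattern_genes(assignments, None, (0, -1, -1, -2), ps)
        assert genes == [f"p{i}" for i in range(5)]

    def test_empty_assignments_give_empty_selection(self):
        ps = enumerate_profiles(4, 1, True)
        genes, sig = select_pattern_genes([], None, (0, -1, -1, -2), ps)
        assert genes == [] and sig is None

    def test_unknown_shape_rejected(self):
        ps = enumerate_profiles(4, 1, True)
        with pytest.raises(KeyError, match="not in profile set"):
            select_pattern_genes([], None, (0, 5, 0, 0), ps)
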