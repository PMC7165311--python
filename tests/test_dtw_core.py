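import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, assume, given, settings
from hypothesis import strategies as st

from fallwarp import (
    AlignmentInfeasibleError,
    align_axis,
    asymmetric_p1,
    dtw_align,
    normalized_distance,
    warp_template,
)

from _oracles import enumerate_dtw_min

series = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=2, max_size=30
)


class TestAsymmetricP1Pattern:
    def test_has_three_rules_with_weight_sums_matching_query_advances(self):
        pat = asymmetric_p1()
        assert len(pat.rules) == 3
        assert pat.query_advances() == (1, 1, 2)
        assert pat.weight_sums() == (1.0, 1.0, 2.0)
        assert pat.normalization_kind == "query_length"

    def test_local_slope_of_every_rule_chain_within_half_and_two(self):
        """Any admissible path built from the rules keeps each rule
        application's local slope (query advance / template advance) in
        [1/2, 2]; checked by enumerating all rule chains up to length 4."""
        advances = [(r[0][0], r[0][1]) for r in asymmetric_p1().rules]
        for length in range(1, 5):
            for chain in itertools.product(advances, repeat=length):
                for dq, dt in chain:
                    assert 0.5 <= dq / dt <= 2.0


class TestDtwAlign:
    @given(series)
    @settings(deadline=None, max_examples=50, derandomize=True, suppress_health_check=[HealthCheck.filter_too_much])
    def test_self_alignment_is_zero_with_diagonal_path(self, values):
        r = dtw_align(values, values)
        assert r.cumulative_distance == 0.0
        assert r.normalized_distance == 0.0
        assert r.path == [(i, i) for i in range(len(values))]
        assert (r.template_match_start, r.template_match_end) == (0, len(values) - 1)

    def test_small_case_matches_enumeration_oracle(self):
        # frozen from the exhaustive path enumeration: the optimum applies
        # the slope-2 rule from (0,0), paying |1-2| at the chain cell
        q, t = [0.0, 1.0, 2.0], [0.0, 2.0]
        r = dtw_align(q, t)
        assert r.cumulative_distance == 1.0
        assert r.cumulative_distance == enumerate_dtw_min(q, t)
        assert r.path == [(0, 0), (1, 1), (2, 1)]

    def test_open_end_leaves_trailing_template_unmatched(self):
        r = dtw_align([5.0, 5.0], [5.0, 5.0, 9.0, 9.0], open_end=True)
        assert r.cumulative_distance == 0.0
        assert r.template_match_end == 1

    @given(series, series, st.floats(min_value=-10, max_value=10, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True, suppress_health_check=[HealthCheck.filter_too_much])
    def test_common_shift_leaves_distance_unchanged(self, q, t, c):
        try:
            base = dtw_align(q, t, open_begin=True, open_end=True)
        except AlignmentInfeasibleError:
            assume(False)
        shifted = dtw_align(
            np.asarray(q) + c, np.asarray(t) + c, open_begin=True, open_end=True
        )
        assert shifted.cumulative_distance == pytest.approx(
            base.cumulative_distance, abs=1e-9
        )

    @given(series, series, st.floats(min_value=0.01, max_value=20, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True, suppress_health_check=[HealthCheck.filter_too_much])
    def test_common_positive_scaling_scales_distance_linearly(self, q, t, s):
        try:
            base = dtw_align(q, t, open_begin=True, open_end=True)
        except AlignmentInfeasibleError:
            assume(False)
        scaled = dtw_align(
            np.asarray(q) * s, np.asarray(t) * s, open_begin=True, open_end=True
        )
        assert scaled.cumulative_distance == pytest.approx(
            s * base.cumulative_distance, rel=1e-9, abs=1e-9
        )

    @given(series, series, st.booleans(), st.booleans())
    @settings(deadline=None, max_examples=80, derandomize=True, suppress_health_check=[HealthCheck.filter_too_much])
    def test_path_invariants(self, q, t, ob, oe):
        try:
            r = dtw_align(q, t, open_begin=ob, open_end=oe)
        except AlignmentInfeasibleError:
            assume(False)
        qi = [p[0] for p in r.path]
        tj = [p[1] for p in r.path]
        assert qi == sorted(qi) and tj == sorted(tj)  # monotone
        assert sorted(set(qi)) == list(range(len(q)))  # every query index
        assert r.template_match_start == tj[0]
        assert r.template_match_end == tj[-1]
        if not ob and not oe:
            assert (tj[0], tj[-1]) == (0, len(t) - 1)
        assert r.normalized_distance == pytest.approx(
            r.cumulative_distance / len(q), abs=1e-12
        )

    @given(
        st.integers(min_value=2, max_value=40),
        st.integers(min_value=2, max_value=40),
        st.floats(min_value=0.0, max_value=3.0, allow_nan=False),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_path_weights_sum_to_query_length(self, n, m, c):
        """With a constant local cost c everywhere, any path costs
        c * (sum of weights); the optimum equals c * N, so the weights on
        every optimal path sum to the query length."""
        q = np.zeros(n)
        t = np.full(m, c)
        for ob, oe in [(False, False), (True, True)]:
            try:
                r = dtw_align(q, t, open_begin=ob, open_end=oe)
            except AlignmentInfeasibleError:
                continue
            assert r.cumulative_distance == pytest.approx(c * n, rel=1e-12, abs=1e-12)

    def test_template_stretched_by_repetition_aligns_at_zero(self):
        """Aligning a query against itself with every element repeated
        (integer time stretching) reaches distance 0 when the open end
        frees the trailing template samples."""
        q = np.sin(np.linspace(0, 3, 20))
        t = np.repeat(q, 2)
        r = dtw_align(q, t, open_begin=True, open_end=True)
        assert r.cumulative_distance == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_alignment_raises_with_both_lengths(self):
        with pytest.raises(AlignmentInfeasibleError, match="5.*20"):
            dtw_align(np.zeros(5), np.zeros(20))  # M > 2(N-1)+1, closed end
        with pytest.raises(AlignmentInfeasibleError):
            dtw_align(np.zeros(20), np.zeros(5))  # M < (N-1)/2+1

    def test_series_shorter_than_two_rejected(self):
        with pytest.raises(ValueError, match="length >= 2"):
            dtw_align([1.0], [1.0, 2.0])


class TestAlignAxis:
    def test_identical_signals_give_zero(self, simulated_fall):
        sig, _ = simulated_fall
        r = align_axis(sig, sig, "z")
        assert r.normalized_distance == 0.0

    def test_equals_manual_axis_extraction(self, simulated_fall, small_signal):
        sig, _ = simulated_fall
        for axis in ("x", "y", "z"):
            r = align_axis(sig, sig, axis, open_begin=False, open_end=False)
            manual = dtw_align(sig.axis(axis), sig.axis(axis))
            assert r.cumulative_distance == manual.cumulative_distance
            assert r.path == manual.path

    def test_unknown_axis_and_rate_mismatch_rejected(self, small_signal):
        import dataclasses

        with pytest.raises(ValueError, match="unknown axis"):
            align_axis(small_signal, small_signal, "w")
        other = dataclasses.replace(small_signal, sampling_rate_hz=50.0)
        with pytest.raises(ValueError, match="sampling rates differ"):
            align_axis(small_signal, other, "z")


class TestWarpTemplate:
    def test_diagonal_path_returns_template(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        r = dtw_align(t, t)
        np.testing.assert_array_equal(warp_template(t, r), t)

    def test_repeated_template_sample_fills_repeated_query_indices(self):
        # query nearly twice the template's length: the slope-2 rule repeats
        # template samples, so positions pairing template index k appear
        # duplicated in the warped output
        t = np.arange(7.0)
        q = np.repeat(np.arange(6.0), 2)
        r = dtw_align(q, t)
        warped = warp_template(t, r)
        assert warped.shape == (len(q),)
        for qi, tj in r.path:
            last_tj = max(b for a, b in r.path if a == qi)
            assert warped[qi] == t[last_tj]

    @given(series, series)
    @settings(deadline=None, max_examples=40, derandomize=True, suppress_health_check=[HealthCheck.filter_too_much])
    def test_output_length_equals_query_length(self, q, t):
        try:
            r = dtw_align(q, t, open_begin=True, open_end=True)
        except AlignmentInfeasibleError:
            assume(False)
        assert warp_template(t, r).shape == (len(q),)


class TestNormalizedDistance:
    def test_values_and_errors(self):
        assert normalized_distance(0.0, 17) == 0.0
        assert normalized_distance(3.7, 1) == 3.7
        with pytest.raises(ValueError):
            normalized_distance(1.0, 0)
        with pytest.raises(ValueError):
            normalized_distance(-1.0, 5)


class TestResultExport:
    def test_json_and_path_csv(self, tmp_path):
        r = dtw_align([0.0, 1.0, 2.0], [0.0, 2.0])
        jpath, cpath = tmp_path / "r.json", tmp_path / "p.csv"
        r.write_json(jpath)
        r.write_path_csv(cpath)
        import json

        payload = json.loads(jpath.read_text())
        assert payload["step_pattern_id"] == "asymmetricP1"
        assert payload["cumulative_distance"] == 1.0
        lines = cpath.read_text().splitlines()
        assert lines[0] == "query_index,template_index"
        assert len(lines) == len(r.path) + 1
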