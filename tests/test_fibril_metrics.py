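"""Orientation folding, angle conventions, concentration, thickness, t-test."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from oftquant.fibril_metrics import (
    BundleAnnotation,
    compute_orientation,
    concentration_statistic,
    fold_angle,
    mean_bundle_thickness,
    summarize_orientation,
    two_sample_t,
    zline_length_nm,
)


class TestFoldAngle:
    @pytest.mark.parametrize(
        "raw,expected",
        [(175.0, 5.0), (90.0, 90.0), (0.0, 0.0), (135.0, 45.0), (185.0, 5.0), (270.0, 90.0)],
    )
    def test_known_values(self, raw, expected):
        assert fold_angle(raw) == pytest.approx(expected)

    @given(st.floats(min_value=-720.0, max_value=720.0))
    def test_idempotent_and_mirror_symmetric(self, a):
        f = fold_angle(a)
        assert 0.0 <= f <= 90.0
        assert fold_angle(f) == pytest.approx(f, abs=1e-9)
        assert fold_angle(180.0 - a) == pytest.approx(f, abs=1e-9)


class TestComputeOrientation:
    def test_longitudinal_axis_has_phi_90(self):
        o = compute_orientation((0.0, 1.0, 0.0))
        assert o.phi == pytest.approx(90.0)
        assert o.theta is None  # zero xz projection

    def test_circumferential_axis(self):
        o = compute_orientation((1.0, 0.0, 0.0))
        assert o.phi == pytest.approx(0.0)
        assert o.theta == pytest.approx(90.0)

    def test_radial_axis_has_theta_0_phi_undefined(self):
        o = compute_orientation((0.0, 0.0, 1.0))
        assert o.theta == pytest.approx(0.0)
        assert o.phi is None

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            compute_orientation((0.0, 0.0, 0.0))

    @given(
        st.tuples(
            st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10)
        ).filter(lambda v: math.hypot(*v) > 1e-3)
    )
    def test_sign_invariance(self, v):
        o1 = compute_orientation(v)
        o2 = compute_orientation(tuple(-c for c in v))
        for a, b in [(o1.phi, o2.phi), (o1.theta, o2.theta)]:
            if a is None:
                assert b is None
            else:
                assert a == pytest.approx(b, abs=1e-9)


def _oracle_max_window(angles, width):
    """Exact maximum by trying every window anchored at a point edge."""
    arr = np.asarray(angles, dtype=float)
    starts = set()
    for a in arr:
        starts.add(min(max(a, 0.0), 90.0 - width))
        starts.add(min(max(a - width, 0.0), 90.0 - width))
    starts.add(0.0)
    best = 0
    for s in starts:
        best = max(best, int(((arr >= s) & (arr <= s + width)).sum()))
    return best / arr.size


class TestConcentrationStatistic:
    def test_identical_angles_give_one(self):
        assert concentration_statistic([37.0] * 5) == 1.0

    def test_hand_computed_small_set(self):
        # brute force over all windows: [0,20] holds {5,10,15} -> 3/5
        assert concentration_statistic([5, 10, 15, 50, 70], 20.0) == pytest.approx(0.6)

    def test_uniform_angles_approach_window_over_range(self, rng):
        angles = rng.uniform(0.0, 90.0, size=10_000)
        frac = concentration_statistic(angles, 20.0)
        assert frac == pytest.approx(20.0 / 90.0, abs=0.02)
        assert frac >= 20.0 / 90.0  # max over windows >= average occupancy

    def test_matches_anchor_oracle_on_lattice_data(self, rng):
        # half-degree lattice angles: the 0.5-degree scan is then exhaustive
        for _ in range(200):
            n = rng.integers(3, 30)
            angles = rng.integers(0, 181, size=n) * 0.5
            assert concentration_statistic(angles, 20.0) == pytest.approx(
                _oracle_max_window(angles, 20.0)
            )

    def test_appending_angle_inside_max_window_never_decreases_count(self, rng):
        angles = list(rng.uniform(0, 90, size=25))
        base = concentration_statistic(angles, 20.0)
        # locate the argmax window, then add a point at its center
        starts = np.arange(0.0, 70.5, 0.5)
        counts = [sum(1 for a in angles if s <= a <= s + 20.0) for s in starts]
        center = starts[int(np.argmax(counts))] + 10.0
        grown = concentration_statistic(angles + [center], 20.0)
        assert grown * (len(angles) + 1) >= base * len(angles) + 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            concentration_statistic([])

    def test_histogram_counts_sum_to_n(self, rng):
        angles = rng.uniform(0, 90, size=123)
        summary = summarize_orientation(angles)
        assert sum(summary.histogram) == 123


class TestThickness:
    def test_single_zline_mean_is_its_length(self):
        ann = BundleAnnotation("b0", (1, 0, 0), ((((0, 0, 0), (0, 0, 500.0))),))
        s = mean_bundle_thickness([ann])
        assert s.mean == pytest.approx(500.0)

    def test_mean_of_two_lengths(self):
        zl1 = ((0.0, 0.0, 0.0), (400.0, 0.0, 0.0))
        zl2 = ((0.0, 0.0, 0.0), (0.0, 600.0, 0.0))
        ann = BundleAnnotation("b0", (1, 0, 0), (zl1, zl2))
        s = mean_bundle_thickness([ann])
        assert s.mean == pytest.approx(500.0)
        assert s.min == pytest.approx(400.0)
        assert s.max == pytest.approx(600.0)
        assert s.min <= s.mean <= s.max

    def test_zero_length_zline_rejected(self):
        with pytest.raises(ValueError):
            zline_length_nm(((1.0, 2.0, 3.0), (1.0, 2.0, 3.0)))

    def test_unit_scaling(self):
        zl = ((0.0, 0.0, 0.0), (300.0, 400.0, 0.0))
        ann = BundleAnnotation("b", (1, 0, 0), (zl,))
        nm = mean_bundle_thickness([ann]).mean
        scaled = tuple(tuple(c / 1000.0 for c in p) for p in zl)
        um = mean_bundle_thickness(
            [BundleAnnotation("b", (1, 0, 0), (scaled,))]
        ).mean
        assert nm == pytest.approx(um * 1000.0)


class TestTwoSampleT:
    def test_identical_groups(self):
        r = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_matches_closed_form_pooled_t(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        r = two_sample_t(a, b)
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        assert r.t == pytest.approx(t_hand)
        assert r.p == pytest.approx(p_hand)

    def test_degenerate_constant_groups(self):
        r = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert (r.t, r.p) == (0.0, 1.0)
        with pytest.raises(ValueError):
            two_sample_t([2.0, 2.0], [3.0, 3.0])

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0, 1, 5)
            rejections += two_sample_t(a, b).p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.015)
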