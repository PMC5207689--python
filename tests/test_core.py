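import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rstrack import (
    ARS,
    REST,
    TRANSIT,
    RSTParams,
    Track,
    classify,
    normalize_and_residuals,
    residence_values,
    run_rst,
)
from rstrack.simulate import to_geographic

from ._oracles import brute_force_residence
from .conftest import make_planar_track


class TestResidenceValues:
    def test_collinear_interior_point(self, collinear_track):
        # focal x=2 with R=1.5 includes x=1,2,3: 2 km of path, 10 min of time
        rt, rd = residence_values(collinear_track, RSTParams(1.5))
        assert rd[2] == pytest.approx(2.0)
        assert rt[2] == pytest.approx(10.0 / 60.0)
        # endpoints include a single neighbour
        assert rd[0] == pytest.approx(1.0) and rt[0] == pytest.approx(5.0 / 60.0)

    def test_isolated_point_scores_zero(self):
        # middle fix farther than R from both neighbours
        track = Track([0, 300, 600], [0.0, 10.0, 20.0], [0.0, 0.0, 0.0], crs_mode="planar")
        rt, rd = residence_values(track, RSTParams(1.0))
        assert rt[1] == 0.0 and rd[1] == 0.0

    def test_single_point_track(self):
        track = Track([0.0], [0.0], [0.0], crs_mode="planar")
        rt, rd = residence_values(track, RSTParams(1.0))
        assert rt.tolist() == [0.0] and rd.tolist() == [0.0]

    def test_point_on_perimeter_included(self):
        # closed disc: a fix at distance exactly R counts as inside
        track = Track([0, 300], [0.0, 1.5], [0.0, 0.0], crs_mode="planar")
        rt, rd = residence_values(track, RSTParams(1.5))
        assert rd[0] == pytest.approx(1.5)

    def test_excursion_kept_iff_within_threshold(self):
        # from focal p0 the path pops 0.27 km outside the unit circle and
        # returns: p1 in, p2 out, p3 back in. outside path = |p1p2|+|p2p3|
        x = np.array([0.0, 0.9, 1.5, 0.9])
        y = np.array([0.0, 0.0, 0.0, 0.3])
        t = np.arange(4) * 300.0
        track = Track(t, x, y, crs_mode="planar")
        out_len = 0.6 + np.hypot(0.6, 0.3)  # ~1.27
        full_path = 0.9 + out_len

        rt0, rd0 = residence_values(track, RSTParams(1.0, threshold_Th=0.0))
        assert rd0[0] == pytest.approx(0.9)  # excursion dropped, run ends at p1
        assert rt0[0] == pytest.approx(5.0 / 60.0)

        rt2, rd2 = residence_values(track, RSTParams(1.0, threshold_Th=2.0))
        assert rd2[0] == pytest.approx(full_path)  # outside stretch included
        assert rt2[0] == pytest.approx(15.0 / 60.0)

        # threshold just below the outside path: excursion dropped again
        rt1, rd1 = residence_values(track, RSTParams(1.0, threshold_Th=out_len - 0.01))
        assert rd1[0] == pytest.approx(0.9)

    def test_multiple_excursions_walked_through(self):
        # two small excursions in sequence, both under Th, both kept
        x = np.array([0.0, 0.8, 1.2, 0.8, 1.2, 0.8])
        y = np.zeros(6)
        track = Track(np.arange(6) * 300.0, x, y, crs_mode="planar")
        rt, rd = residence_values(track, RSTParams(1.0, threshold_Th=1.0))
        assert rd[0] == pytest.approx(0.8 + 0.4 * 4)
        assert rt[0] == pytest.approx(25.0 / 60.0)

    def test_matches_brute_force_walker(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 60))
            track = make_planar_track(rng, n, jitter_t=True)
            radius = float(rng.uniform(0.5, 8.0))
            th = float(rng.choice([0.0, 0.0, rng.uniform(0.1, 3.0)]))
            rt, rd = residence_values(track, RSTParams(radius, th))
            ort, ord_ = brute_force_residence(track, radius, th)
            np.testing.assert_array_equal(rt, ort)
            np.testing.assert_array_equal(rd, ord_)

    def test_geographic_mode_matches_walker(self, rng):
        planar = make_planar_track(rng, 30)
        track = to_geographic(planar)
        rt, rd = residence_values(track, RSTParams(2.0))
        ort, ord_ = brute_force_residence(track, 2.0)
        np.testing.assert_array_equal(rt, ort)
        np.testing.assert_array_equal(rd, ord_)


class TestNormalizeAndResiduals:
    def test_single_point_normalisation(self):
        rt_n, rd_n, res = normalize_and_residuals(np.array([10.0]), np.array([2.0]))
        assert rt_n.tolist() == [1.0] and rd_n.tolist() == [1.0] and res.tolist() == [0.0]

    def test_direct_substitution(self):
        # RD 2 of max 4, RT 10 of max 10 -> 0.5 - 1.0 = -0.5
        _, _, res = normalize_and_residuals(np.array([10.0, 10.0]), np.array([2.0, 4.0]))
        assert res[0] == pytest.approx(-0.5)

    def test_all_zero_degenerate_track(self):
        rt_n, rd_n, res = normalize_and_residuals(np.zeros(4), np.zeros(4))
        assert not res.any() and not rt_n.any() and not rd_n.any()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            normalize_and_residuals(np.array([-1.0]), np.array([0.0]))

    def test_max_normalisation_hits_one(self, rng):
        rt = rng.uniform(0, 5, 50)
        rd = rng.uniform(0, 9, 50)
        rt_n, rd_n, res = normalize_and_residuals(rt, rd)
        assert rt_n.max() == 1.0 and rd_n.max() == 1.0
        assert np.all(res >= -1.0) and np.all(res <= 1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "residual, state",
        [(0.3, ARS), (-0.2, REST), (0.0, TRANSIT), (1e-300, ARS), (-1e-300, REST)],
    )
    def test_sign_rule_is_exact(self, residual, state):
        assert classify(np.array([residual]))[0] == state


class TestRunRST:
    def test_collinear_pipeline_all_transit_flagged(self, collinear_track):
        # constant-speed straight line: RD and RT normalise identically, so
        # every residual is exactly zero despite nonzero residence values —
        # transit by the sign rule, flagged as coincidental zeros
        res = run_rst(collinear_track, RSTParams(1.5))
        np.testing.assert_array_equal(res.residual, np.zeros(5))
        assert all(res.state == TRANSIT)
        assert res.ambiguous_zero.all()

    def test_isolated_zeros_not_flagged(self):
        track = Track([0, 300, 600], [0.0, 10.0, 20.0], [0.0, 0.0, 0.0], crs_mode="planar")
        res = run_rst(track, RSTParams(1.0))
        assert all(res.state == TRANSIT)
        assert not res.ambiguous_zero.any()

    def test_state_fractions_sum_to_one(self, random_track):
        res = run_rst(random_track, RSTParams(2.0))
        assert sum(res.state_fractions().values()) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic(self, random_track):
        a = run_rst(random_track, RSTParams(2.0))
        b = run_rst(random_track, RSTParams(2.0))
        np.testing.assert_array_equal(a.residual, b.residual)

    @given(c=st.floats(0.1, 100.0))
    @settings(max_examples=25)
    def test_planar_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        track = make_planar_track(rng, 30)
        scaled = Track(track.times, track.x * c, track.y * c, crs_mode="planar")
        base = run_rst(track, RSTParams(2.0, 0.5))
        big = run_rst(scaled, RSTParams(2.0 * c, 0.5 * c))
        np.testing.assert_allclose(big.residual, base.residual, atol=1e-9)
        assert list(big.state) == list(base.state)

    def test_time_reversal_invariance(self, random_track):
        fwd = run_rst(random_track, RSTParams(2.0))
        t = random_track.times
        rev = Track(t.max() - t[::-1], random_track.x[::-1], random_track.y[::-1], crs_mode="planar")
        bwd = run_rst(rev, RSTParams(2.0))
        np.testing.assert_allclose(bwd.rt[::-1], fwd.rt, atol=1e-9)
        np.testing.assert_allclose(bwd.rd[::-1], fwd.rd, atol=1e-9)
        np.testing.assert_allclose(bwd.residual[::-1], fwd.residual, atol=1e-9)

    def test_residence_monotone_in_radius(self, random_track):
        radii = [0.5, 1.0, 2.0, 4.0, 8.0]
        prev_rt = prev_rd = prev_isolated = None
        for r in radii:
            res = run_rst(random_track, RSTParams(r))
            if prev_rt is not None:
                assert np.all(res.rt >= prev_rt - 1e-12)
                assert np.all(res.rd >= prev_rd - 1e-12)
                assert res.isolated_fraction() <= prev_isolated + 1e-12
            prev_rt, prev_rd = res.rt, res.rd
            prev_isolated = res.isolated_fraction()

    def test_zero_residence_iff_alone_in_circle(self, rng):
        track = make_planar_track(rng, 50)
        params = RSTParams(1.5)
        rt, rd = residence_values(track, params)
        d = lambda i, j: np.hypot(track.x[i] - track.x[j], track.y[i] - track.y[j])  # noqa: E731
        for i in range(50):
            neighbour_in = (i > 0 and d(i, i - 1) <= 1.5) or (
                i < 49 and d(i, i + 1) <= 1.5
            )
            assert (rt[i] == 0.0 and rd[i] == 0.0) == (not neighbour_in)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RSTParams(0.0)
        with pytest.raises(ValueError):
            RSTParams(1.0, threshold_Th=-0.5)
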