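"""MSD, diffusion-coefficient, confinement and percent-change tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecsmap.datatypes import Trajectory, TrajectorySet
from ecsmap.diffusion import (
    ConfinementRecord,
    MSDCurve,
    compare_groups,
    compute_msd,
    confinement_area,
    ensemble_msd,
    fit_diffusion_coefficient,
    percent_change_confinement,
)
from ecsmap.synthetic import DomainSpec, SimulationConfig, simulate_cohort


def _track(xs, ys, frames=None, track_id="t"):
    xs = np.asarray(xs, dtype=float)
    frames = np.arange(xs.size) if frames is None else frames
    return Trajectory(track_id, frames, xs, np.asarray(ys, dtype=float))


class TestComputeMsd:
    def test_stationary_track_zero_msd(self):
        c = compute_msd(_track([1.0] * 10, [2.0] * 10), dt=0.03)
        assert np.all(c.msd == 0)

    def test_ballistic_track_quadratic_msd(self):
        c = compute_msd(_track([0, 1, 2, 3], [0, 0, 0, 0]), dt=1.0)
        assert np.allclose(c.lags_s, [1, 2, 3])
        assert np.allclose(c.msd, [1, 4, 9])
        assert c.n_pairs.tolist() == [3, 2, 1]

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(_track([0.0], [0.0]), dt=0.03)

    def test_gap_pairs_used_when_endpoints_exist(self):
        # frames 0,1,3: lag 1 has 1 pair (0->1), lag 2 has 1 pair (1->3),
        # lag 3 has 1 pair (0->3)
        c = compute_msd(_track([0, 1, 3], [0, 0, 0], frames=np.array([0, 1, 3])), dt=1.0)
        assert c.lags_s.tolist() == [1.0, 2.0, 3.0]
        assert c.n_pairs.tolist() == [1, 1, 1]
        assert np.allclose(c.msd, [1.0, 4.0, 9.0])

    def test_free_diffusion_matches_4dt(self):
        # ensemble MSD of free 2D Brownian motion is 4*D*tau
        dom = DomainSpec("rectangle", width=200.0, height=200.0)
        cfg = SimulationConfig(d_free=0.1, sigma_loc=0.0, n_frames=100, seed=42, n_substeps=1)
        ts = simulate_cohort(dom, cfg, 200)
        curve = ensemble_msd(ts, max_lag_frames=4)
        expected = 4 * 0.1 * curve.lags_s
        assert np.all(np.abs(curve.msd - expected) / expected < 0.05)

    def test_msd_translation_invariance(self):
        rng = np.random.default_rng(0)
        xs, ys = rng.normal(size=20), rng.normal(size=20)
        a = compute_msd(_track(xs, ys), dt=0.03)
        b = compute_msd(_track(xs + 5.0, ys - 3.0), dt=0.03)
        assert np.allclose(a.msd, b.msd)


class TestDiffusionFit:
    def test_exact_line_recovered(self):
        tau = 0.03 * np.arange(1, 5)
        curve = MSDCurve(tau, 4 * 0.05 * tau, np.ones(4, int))
        est = fit_diffusion_coefficient(curve)
        assert est.d == pytest.approx(0.05)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noise_floor_absorbed_by_intercept(self):
        tau = 0.03 * np.arange(1, 5)
        curve = MSDCurve(tau, 4 * 0.1 * tau + 0.0036, np.ones(4, int))
        est = fit_diffusion_coefficient(curve)
        assert est.d == pytest.approx(0.1)
        assert est.intercept == pytest.approx(0.0036)

    def test_zero_msd_gives_zero_d(self):
        curve = MSDCurve(0.03 * np.arange(1, 5), np.zeros(4), np.ones(4, int))
        est = fit_diffusion_coefficient(curve)
        assert est.d == 0.0 and est.intercept == 0.0

    def test_negative_slope_flagged_not_clamped(self):
        tau = 0.03 * np.arange(1, 5)
        curve = MSDCurve(tau, 0.01 - 0.02 * tau, np.ones(4, int))
        est = fit_diffusion_coefficient(curve)
        assert est.negative_slope and est.d < 0
        assert est.d_clamped == 0.0

    def test_too_few_lags_rejected(self):
        curve = MSDCurve([0.03], [0.1], [1])
        with pytest.raises(ValueError):
            fit_diffusion_coefficient(curve)


class TestConfinement:
    def test_stationary_recording_zero_area(self):
        trajs = [_track([1.0] * 40, [1.0] * 40, track_id=str(i)) for i in range(3)]
        ts = TrajectorySet(trajs, dt=0.03)
        rec = confinement_area(ts, plateau_window=(0.3, 0.5))
        assert rec.area_um2 == 0.0
        assert rec.n_trajectories == 3

    def test_window_unreachable_is_error(self):
        ts = TrajectorySet([_track([0, 1, 2], [0, 0, 0])], dt=0.03)
        with pytest.raises(ValueError, match="plateau"):
            confinement_area(ts)

    def test_disc_plateau_near_r_squared(self):
        ts = simulate_cohort(
            DomainSpec("disc", radius=0.3),
            SimulationConfig(d_free=0.1, sigma_loc=0.0, n_frames=500, seed=5),
            25,
        )
        rec = confinement_area(ts)
        assert rec.area_um2 == pytest.approx(0.09, rel=0.10)

    def test_pooled_and_per_trajectory_agree_for_identical_tracks(self):
        ts = simulate_cohort(
            DomainSpec("rectangle", width=0.6, height=0.6),
            SimulationConfig(d_free=0.1, sigma_loc=0.0, n_frames=500, seed=8),
            10,
        )
        a = confinement_area(ts, method="per_trajectory").area_um2
        b = confinement_area(ts, method="pooled").area_um2
        assert a == pytest.approx(b, rel=0.05)


def _rec(area, rec="r", region="sr", condition="c"):
    return ConfinementRecord(rec, condition, region, area, 10)


class TestPercentChange:
    def test_equal_groups_zero(self):
        vals = percent_change_confinement([_rec(0.1)], [_rec(0.1)]).values
        assert np.allclose(vals, 0.0)

    def test_tripling_gives_plus_100(self):
        vals = percent_change_confinement([_rec(0.3)], [_rec(0.1)]).values
        assert np.allclose(vals, 100.0)

    def test_third_gives_minus_100(self):
        vals = percent_change_confinement([_rec(0.1)], [_rec(0.3)]).values
        assert np.allclose(vals, -100.0)

    def test_zero_zero_pair_convention(self):
        d = percent_change_confinement([_rec(0.0)], [_rec(0.0)])
        assert d.values.tolist() == [0.0] and d.zero_pairs == 1

    def test_region_mismatch_rejected(self):
        with pytest.raises(ValueError, match="region"):
            percent_change_confinement([_rec(0.1, region="CA1")], [_rec(0.1, region="CA3")])

    @settings(deadline=None, max_examples=50)
    @given(
        t=st.lists(st.floats(1e-3, 10.0), min_size=1, max_size=4),
        u=st.lists(st.floats(1e-3, 10.0), min_size=1, max_size=4),
    )
    def test_antisymmetry_and_bounds(self, t, u):
        fwd = percent_change_confinement([_rec(v) for v in t], [_rec(v) for v in u])
        rev = percent_change_confinement([_rec(v) for v in u], [_rec(v) for v in t])
        assert np.all(np.abs(fwd.values) < 200.0)
        # cross pairing (i,j) maps to (j,i); compare as multisets
        assert np.allclose(np.sort(fwd.values), -np.sort(rev.values)[::-1])


class TestCompareGroups:
    def test_identical_constant_groups_degenerate(self):
        rep = compare_groups({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert rep.degenerate and rep.pvalue == 1.0

    def test_disjoint_samples_match_rank_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        # brute-force U oracle: count pairs where a > b (plus half-ties)
        u_oracle = sum(1.0 * (x > y) + 0.5 * (x == y) for x in a for y in b)
        rep = compare_groups({"a": a, "b": b})
        assert rep.statistic == u_oracle == 0.0

    def test_kruskal_wallis_with_dunn_posthoc(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(loc, 1.0, 20) for k, loc in [("a", 0), ("b", 0), ("c", 3)]}
        rep = compare_groups(groups, design="k_group")
        assert rep.test == "kruskal-wallis" and rep.pvalue < 0.01
        ph = rep.posthoc.set_index(["group_a", "group_b"])
        assert ph.loc[("a", "c"), "p_adj"] < 0.05
        assert ph.loc[("a", "b"), "p_adj"] > 0.05

    def test_ks_design(self):
        rng = np.random.default_rng(1)
        rep = compare_groups(
            {"a": rng.normal(0, 1, 100), "b": rng.normal(2, 1, 100)},
            design="distribution",
        )
        assert rep.test == "kolmogorov-smirnov" and rep.pvalue < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})
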