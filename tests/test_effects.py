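import numpy as np
import pytest

from trajarea.config import simple_config
from trajarea.dataset import TrialDataset
from trajarea.generator import generate_trial
from trajarea.effects import (
    EffectTrajectory,
    area_between_curves,
    leave_one_out_areas,
    pooled_within_sd,
    standardize,
    trapezium_weights,
)
from trajarea.sur import fit_sur

from conftest import make_specs


def exact_moment_sample(n, mean, sd, rng):
    """A vector with *exact* sample mean and SD (ddof=1)."""
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


def make_traj(times, d, cov_d, anchor=None):
    times = np.asarray(times, float)
    d = np.asarray(d, float)
    return EffectTrajectory(
        times=times, d=d,
        se=np.concatenate([[0.0], np.sqrt(np.diag(cov_d))]),
        sd_within=np.full(len(times), np.nan),
        beta=np.full(len(times), np.nan),
        cov_d=np.asarray(cov_d, float),
        anchor_time=float(times[0]) if anchor is None else anchor,
    )


class TestPooledWithinSd:
    def test_published_27_month_cells(self):
        # two-group contrast from the printed 27-month symptom summary cells:
        # control 6.32 (SD 6.79, n=25), intervention 4.13 (SD 3.61, n=23)
        rng = np.random.default_rng(0)
        ctrl = exact_moment_sample(25, 6.32, 6.79, rng)
        intv = exact_moment_sample(23, 4.13, 3.61, rng)
        values = np.concatenate([ctrl, intv])
        arm = np.concatenate([np.zeros(25), np.ones(23)])
        sw = pooled_within_sd(values, arm)
        assert sw == pytest.approx(5.503, abs=5e-4)
        raw_d = (4.13 - 6.32) / sw
        assert raw_d == pytest.approx(-0.398, abs=5e-4)

    def test_stratified_pooling_by_df(self):
        rng = np.random.default_rng(1)
        cells = [exact_moment_sample(n, m, s, rng)
                 for n, m, s in ((10, 0, 2.0), (8, 5, 3.0), (12, 1, 1.5), (6, 4, 2.5))]
        values = np.concatenate(cells)
        arm = np.repeat([0, 0, 1, 1], [10, 8, 12, 6]).astype(float)
        stratum = np.repeat([0, 1, 0, 1], [10, 8, 12, 6]).astype(float)
        expected = np.sqrt(
            (9 * 4.0 + 7 * 9.0 + 11 * 1.5**2 + 5 * 2.5**2) / (9 + 7 + 11 + 5)
        )
        assert pooled_within_sd(values, arm, stratum) == pytest.approx(expected, abs=1e-12)


class TestStandardize:
    def test_zero_beta_gives_zero_d(self, small_dataset):
        fit = fit_sur(small_dataset, make_specs())
        fit.beta[fit.treat_indices] = 0.0
        traj = standardize(fit, anchor_time=9.0)
        np.testing.assert_allclose(traj.d, 0.0)

    def test_scale_invariance(self, small_dataset):
        # fit both problems to (near) exact convergence: the ML optimum itself
        # is exactly scale-equivariant
        specs = make_specs()
        fit = fit_sur(small_dataset, specs, tol=1e-14, max_iter=20000)
        traj = standardize(fit, anchor_time=9.0)
        df = small_dataset.df.copy()
        for c in ("score_9", "score_15", "score_27", "score_39"):
            df[c] = df[c] * 10.0
        fit10 = fit_sur(TrialDataset(df), specs, tol=1e-14, max_iter=20000)
        traj10 = standardize(fit10, anchor_time=9.0)
        np.testing.assert_allclose(traj.d, traj10.d, atol=1e-10)

    def test_anchor_inferred_from_baseline_column(self, small_dataset):
        traj = standardize(fit_sur(small_dataset, make_specs()))
        assert traj.anchor_time == 9.0
        assert traj.d[0] == 0.0
        assert traj.se[0] == 0.0

    def test_zero_sd_rejected(self, small_dataset):
        df = small_dataset.df.copy()
        df["score_27"] = 5.0
        with pytest.raises(ValueError, match="zero variance|within-group SD"):
            standardize(fit_sur(TrialDataset(df), make_specs()), anchor_time=9.0)


class TestArea:
    def test_hand_trapezium(self):
        traj = make_traj([9, 15, 27, 39], [0, -0.2, -0.5, -0.3], np.eye(3) * 0.01)
        res = area_between_curves(traj)
        assert res.area == pytest.approx(-9.6, abs=1e-12)
        assert res.averaged_es == pytest.approx(-0.32, abs=1e-12)
        assert res.span == 30.0

    def test_matches_numeric_integration_oracle(self):
        rng = np.random.default_rng(3)
        times = np.array([9.0, 15.0, 27.0, 39.0])
        d = np.concatenate([[0.0], rng.normal(size=3)])
        res = area_between_curves(make_traj(times, d, np.eye(3)))
        grid = np.linspace(times[0], times[-1], 2_000_001)
        oracle = np.trapezoid(np.interp(grid, times, d), grid)
        assert res.area == pytest.approx(oracle, abs=1e-6)
        exact = sum(
            (times[i + 1] - times[i]) * (d[i] + d[i + 1]) / 2 for i in range(3)
        )
        assert res.area == pytest.approx(exact, abs=1e-10)

    def test_constant_d_averaged_es_exact(self):
        for c in (-0.7, 0.0, 1.3):
            traj = make_traj([9, 15, 27, 39], [c] * 4, np.eye(3))
            # constant trajectory, anchor included as a vertex with the same value
            res = area_between_curves(traj)
            assert res.averaged_es == pytest.approx(c, abs=1e-12)

    def test_variance_weight_expansion(self):
        # anchored grid 9/15/27/39 -> non-anchor weights (9, 12, 6);
        # independent d with variance v gives Var(area) = 261 v
        v = 0.037
        traj = make_traj([9, 15, 27, 39], [0, -0.1, -0.2, -0.1], np.eye(3) * v)
        res = area_between_curves(traj)
        np.testing.assert_allclose(res.weights, [3.0, 9.0, 12.0, 6.0])
        assert res.se_area**2 == pytest.approx(261 * v, rel=1e-12)

    def test_linearity_in_d(self):
        traj = make_traj([9, 15, 27, 39], [0, -0.2, -0.5, -0.3], np.eye(3) * 0.01)
        res = area_between_curves(traj)
        traj2 = make_traj([9, 15, 27, 39], 2 * traj.d, np.eye(3) * 0.04)
        res2 = area_between_curves(traj2)
        assert res2.area == pytest.approx(2 * res.area, rel=1e-12)
        assert res2.z == pytest.approx(res.z, rel=1e-12)

    def test_weights_sum_to_span(self):
        for times in ([0, 1], [9, 15, 27, 39], [1, 2, 4, 8, 16]):
            w = trapezium_weights(np.asarray(times, float))
            assert w.sum() == pytest.approx(times[-1] - times[0], rel=1e-12)

    def test_unordered_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            trapezium_weights(np.array([9.0, 27.0, 15.0]))
        with pytest.raises(ValueError, match="sorted"):
            make_traj([9, 27, 15], [0, 1, 2], np.eye(2))


class TestLeaveOneOut:
    def test_duplicated_participant_exchangeable(self):
        cfg = simple_config(n_per_arm=15, seed=3, missingness={})
        ds = generate_trial(cfg)
        df = ds.df.copy()
        dup = df.iloc[[4]].assign(participant_id="P999")
        df = __import__("pandas").concat([df, dup], ignore_index=True)
        records, _ = leave_one_out_areas(TrialDataset(df), make_specs(), anchor_time=9.0)
        by_id = {r["participant_id"]: r for r in records}
        a1 = by_id[df.loc[4, "participant_id"]]["area"].area
        a2 = by_id["P999"]["area"].area
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_all_areas_finite_at_trial_scale(self, small_dataset):
        records, max_dev = leave_one_out_areas(small_dataset, make_specs(), anchor_time=9.0)
        assert len(records) == len(small_dataset)
        areas = [r["area"].area for r in records if "area" in r]
        assert len(areas) >= 0.95 * len(records)
        assert np.isfinite(areas).all()
        assert np.isfinite(max_dev)

    def test_planted_outlier_dominates(self):
        cfg = simple_config(n_per_arm=20, seed=13, missingness={})
        ds = generate_trial(cfg)
        df = ds.df.copy()
        victim = df.index[df.arm == "intervention"][0]
        df.loc[victim, "score_27"] = 130.0  # +8 SD
        records, _ = leave_one_out_areas(TrialDataset(df), make_specs(), anchor_time=9.0)
        full = area_between_curves(
            standardize(fit_sur(TrialDataset(df), make_specs()), anchor_time=9.0)
        )
        devs = {r["participant_id"]: abs(r["area"].area - full.area)
                for r in records if "area" in r}
        assert max(devs, key=devs.get) == df.loc[victim, "participant_id"]
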