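"""Block-design ROI GLM: design construction, filtering, psc estimation."""

import numpy as np
import pytest

from tspoquant import fmri
from tspoquant.cohort import BoldNoise, simulate_bold_session


@pytest.fixture(scope="module")
def design():
    return fmri.build_design()


class TestDesign:
    def test_eight_columns(self, design):
        assert design.X.shape == (161, 8)
        assert design.names[0] == "task" and design.names[-1] == "intercept"

    def test_hrf_lag_at_half_maximum(self):
        """The convolved regressor crosses half-maximum ~5-6 s after onset."""
        x = fmri.convolved_task_regressor(np.array([2.0]), n_volumes=161)
        t = np.arange(161) * 2.0
        t_half = t[np.argmax(x >= 0.5)]
        assert 4.0 <= t_half - 2.0 <= 8.0

    def test_five_boxcar_plateaus(self):
        onsets = fmri.default_task_onsets()
        assert len(onsets) == 5
        t = np.arange(0, 322, 0.1)
        box = np.zeros_like(t)
        for on in onsets:
            box[(t >= on) & (t < on + 31.5)] = 1.0
        rises = np.sum(np.diff(box) > 0)
        assert rises == 5
        assert onsets[-1] + 31.5 + 30.5 <= 322.0 + 1e-9  # fits in the scan

    def test_onset_beyond_scan_rejected(self):
        with pytest.raises(ValueError):
            fmri.build_design(task_onsets=np.array([400.0]))

    def test_bad_motion_shape_rejected(self):
        with pytest.raises(ValueError):
            fmri.build_design(motion=np.zeros((161, 5)))


class TestHighpass:
    def test_removes_slow_sinusoid_keeps_task(self, design):
        """A 200 s-period sinusoid (any phase) loses > 99% amplitude while
        the convolved task regressor keeps > 95% of its energy."""
        t = np.arange(161) * 2.0
        for phase in np.linspace(0, np.pi, 7):
            s = np.sin(2 * np.pi * t / 200.0 + phase)
            r = design.highpass(s) - np.mean(design.highpass(s))
            assert np.linalg.norm(r) / np.linalg.norm(s) < 0.01
        x = fmri.convolved_task_regressor(fmri.default_task_onsets())
        xc = x - x.mean()
        fx = design.highpass(xc)
        fx = fx - fx.mean()  # the intercept column absorbs the mean
        kept = np.linalg.norm(fx) / np.linalg.norm(xc)
        assert kept > 0.95


class TestFirstLevel:
    def test_noiseless_psc_round_trip(self, design):
        bold, _ = simulate_bold_session(
            {"roi": 1.0}, BoldNoise(sigma_frac=0.0, motion_step_sd=0.0), seed=0
        )
        res = fmri.fit_first_level(bold["signal"].to_numpy(), design)
        assert res.percent_signal_change == pytest.approx(1.0, abs=1e-3)

    def test_perfect_fit_series(self, design):
        """A series that is exactly a multiple of the task regressor plus a
        constant fits with R^2 = 1 and a very large Z."""
        x = fmri.convolved_task_regressor(fmri.default_task_onsets())
        y = 100.0 + 7.0 * x
        res = fmri.fit_first_level(y, design)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.z > 10
        assert res.percent_signal_change == pytest.approx(
            100.0 * 7.0 * design.task_range / np.mean(y), rel=1e-6
        )

    def test_psc_invariant_to_scaling(self, design):
        bold, _ = simulate_bold_session({"roi": 0.8}, BoldNoise(), seed=5)
        y = bold["signal"].to_numpy()
        a = fmri.fit_first_level(y, design)
        b = fmri.fit_first_level(4.2 * y, design)
        assert b.percent_signal_change == pytest.approx(a.percent_signal_change,
                                                        rel=1e-9)
        assert b.t == pytest.approx(a.t, rel=1e-9)

    def test_shift_leaves_t_and_z_unchanged(self, design):
        """Adding a constant shifts the baseline (so psc rescales by the new
        mean) but cannot change the inference statistics."""
        bold, _ = simulate_bold_session({"roi": 0.8}, BoldNoise(), seed=6)
        y = bold["signal"].to_numpy()
        a = fmri.fit_first_level(y, design)
        b = fmri.fit_first_level(y + 500.0, design)
        assert b.t == pytest.approx(a.t, rel=1e-9)
        assert b.z == pytest.approx(a.z, rel=1e-9)
        assert b.beta == pytest.approx(a.beta, rel=1e-9)
        assert b.percent_signal_change == pytest.approx(
            a.percent_signal_change * np.mean(y) / np.mean(y + 500.0), rel=1e-9
        )

    def test_motion_artifact_barely_moves_psc(self):
        """A motion-coupled artifact with no task correlation changes the
        psc estimate by < 0.01 absolute when motion regressors are in."""
        bold, motion = simulate_bold_session(
            {"roi": 1.0}, BoldNoise(sigma_frac=0.0, motion_step_sd=0.0), seed=0
        )
        y = bold["signal"].to_numpy()
        rng = np.random.default_rng(8)
        mo = np.cumsum(0.02 * rng.standard_normal((161, 6)), axis=0)
        des = fmri.build_design(motion=mo)
        artifact = 3.0 * mo.sum(axis=1)
        res = fmri.fit_first_level(y + artifact, des)
        assert res.percent_signal_change == pytest.approx(1.0, abs=0.01)

    def test_collinear_task_rejected(self, design):
        broken = fmri.DesignMatrix(
            X=np.column_stack([np.ones(161), design.X[:, 1:]]),
            names=design.names, task_range=design.task_range,
            hp_basis=design.hp_basis, tr=2.0,
        )
        with pytest.raises(np.linalg.LinAlgError):
            fmri.fit_first_level(np.random.default_rng(0).random(161), broken)

    def test_nonfinite_series_rejected(self, design):
        y = np.ones(161)
        y[5] = np.nan
        with pytest.raises(ValueError):
            fmri.fit_first_level(y, design)


class TestGenerator:
    def test_zero_effect_zero_noise_is_constant(self):
        bold, _ = simulate_bold_session(
            {"roi": 0.0}, BoldNoise(sigma_frac=0.0, motion_step_sd=0.0), seed=0
        )
        assert np.allclose(bold["signal"], bold["signal"].iloc[0])

    def test_session_geometry(self):
        bold, motion = simulate_bold_session({"a": 0.5, "b": 1.0}, seed=1)
        assert set(bold["roi"]) == {"a", "b"}
        assert bold.groupby("roi").size().eq(161).all()
        assert motion.shape == (161, 7)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            simulate_bold_session({"r": 1.0}, baseline=0.0)

    def test_nonfinite_effect_rejected(self):
        with pytest.raises(ValueError):
            simulate_bold_session({"r": np.inf})


class TestGroup:
    def test_degenerate_equal_psc_flagged(self):
        out = fmri.group_activation(np.full(5, 1.0))
        assert out["degenerate"] and out["mean_psc"] == pytest.approx(1.0)

    def test_two_group_welch(self):
        rng = np.random.default_rng(2)
        psc = np.concatenate([rng.normal(1.0, 0.2, 5), rng.normal(0.5, 0.2, 4)])
        labels = np.array(["rCI"] * 5 + ["rNC"] * 4)
        out = fmri.group_activation(psc, labels)
        assert out["group_comparison"]["t"] != 0
        assert 0 < out["p"] <= 1

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            fmri.group_activation(np.array([1.0, 2.0]))
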