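import numpy as np
import pandas as pd
import pytest

from infoconn.design import StudyDesign
from infoconn.errors import IllPosedError, InvalidArgumentError
from infoconn.estimation import (
    CensorMask,
    build_lss_design,
    censor,
    censor_mask_from_motion,
    convolve_events,
    double_gamma_hrf,
    estimate_run,
    framewise_displacement,
    lss_fit,
)
from infoconn.synthetic import GenerativeModel, generate_atlas, generate_bold_session

TR = 1.56


class TestHrf:
    def test_zero_at_origin(self):
        h = double_gamma_hrf(tr=0.1)
        assert h[0] == 0.0

    def test_peak_near_five_seconds(self):
        dt = 0.01
        h = double_gamma_hrf(tr=dt)
        t_peak = np.argmax(h) * dt
        assert abs(t_peak - 5.0) <= dt + 1e-9

    def test_single_sign_change(self):
        h = double_gamma_hrf(tr=0.05)
        signs = np.sign(h[np.abs(h) > 1e-12])
        changes = np.sum(np.diff(signs) != 0)
        assert changes == 1

    def test_peak_normalized(self):
        h = double_gamma_hrf(tr=0.01)
        assert np.max(h) == pytest.approx(1.0)

    def test_bad_tr_rejected(self):
        with pytest.raises(InvalidArgumentError):
            double_gamma_hrf(tr=0.0)


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        fd = framewise_displacement(np.zeros((10, 6)))
        assert np.all(fd == 0)

    def test_translation_step(self):
        m = np.zeros((5, 6))
        m[2:, 0] = 0.5  # 0.5 mm x step between frames 1 and 2
        fd = framewise_displacement(m)
        assert fd[2] == pytest.approx(0.5)
        assert fd[1] == 0.0 and fd[3] == 0.0

    def test_rotation_step_scaled_by_radius(self):
        m = np.zeros((4, 6))
        m[1:, 4] = 0.01  # 0.01 rad pitch -> 0.01 * 50 = 0.5 mm
        fd = framewise_displacement(m)
        assert fd[1] == pytest.approx(0.5)

    def test_first_frame_zero(self):
        rng = np.random.default_rng(0)
        fd = framewise_displacement(rng.standard_normal((8, 6)))
        assert fd[0] == 0.0

    def test_malformed_trace_rejected(self):
        with pytest.raises(InvalidArgumentError):
            framewise_displacement(np.zeros((5, 4)))
        with pytest.raises(InvalidArgumentError):
            framewise_displacement(np.full((5, 6), np.nan))


class TestCensorMask:
    def test_spike_flagged(self):
        m = np.zeros((50, 6))
        m[20, 0] = 0.75  # FD = 0.75 up and 0.75 back: both > 0.9? no
        m[20, 1] = 0.75  # combined FD = 1.5 at frames 20 and 21
        mask = censor_mask_from_motion(m)
        assert mask.censored[20] and mask.censored[21]
        assert not mask.run_excluded

    def test_run_excluded_by_fraction(self):
        m = np.zeros((100, 6))
        m[1::4, 0] = 1.0  # alternating jumps censor > 20% of frames
        mask = censor_mask_from_motion(m)
        assert mask.censored_fraction > 0.2
        assert mask.run_excluded
        assert "FD" in mask.reason

    def test_run_excluded_by_absolute_displacement(self):
        m = np.zeros((100, 6))
        m[50:, 2] = np.linspace(0, 1.5, 50)  # slow 1.5 mm drift, low FD
        mask = censor_mask_from_motion(m)
        assert not mask.censored.any()
        assert mask.run_excluded
        assert "absolute" in mask.reason


class TestBuildLssDesign:
    @pytest.fixture()
    def run(self):
        design = StudyDesign(trials_per_encoding_run=5, trials_per_retrieval_run=4)
        atlas = generate_atlas(2, 30, 30, seed=0)
        model = GenerativeModel(n_rois=2, seed=0, noise_sd=0.0, gain_sd=0.0)
        return design, generate_bold_session(
            design, atlas, model, seed=0, phase="encoding"
        )[0]

    def test_one_design_per_trial_with_disjoint_interest_windows(self, run):
        design, r = run
        n = r.signal.shape[0]
        supports = []
        for tri in range(5):
            d = build_lss_design(r.events, tri, "encoding", n, TR, drift_cutoff_s=None)
            col = d.column("trial_of_interest")
            onset = r.events[
                (r.events.trial_type == "encode") & (r.events.trial == tri)
            ].iloc[0]["onset"]
            assert np.argmax(col > 1e-6) * TR >= onset - TR
            supports.append(col)
        # each trial's regressor differs
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.allclose(supports[i], supports[j])

    def test_interest_plus_others_invariant(self, run):
        """Different trials split the same total between columns 1 and 2."""
        design, r = run
        n = r.signal.shape[0]
        d0 = build_lss_design(r.events, 0, "encoding", n, TR)
        d3 = build_lss_design(r.events, 3, "encoding", n, TR)
        total0 = d0.column("trial_of_interest") + d0.column("other_trials")
        total3 = d3.column("trial_of_interest") + d3.column("other_trials")
        np.testing.assert_allclose(total0, total3, atol=1e-12)

    def test_no_spike_columns_without_censoring(self, run):
        design, r = run
        d = build_lss_design(r.events, 0, "encoding", r.signal.shape[0], TR)
        assert not any(lbl.startswith("spike") for lbl in d.labels)

    def test_spike_columns_added(self, run):
        design, r = run
        n = r.signal.shape[0]
        censored = np.zeros(n, dtype=bool)
        censored[[4, 9]] = True
        mask = CensorMask(fd=np.zeros(n), censored=censored)
        d = build_lss_design(r.events, 0, "encoding", n, TR, censor=mask)
        assert "spike_4" in d.labels and "spike_9" in d.labels

    def test_missing_trial_rejected(self, run):
        design, r = run
        with pytest.raises(InvalidArgumentError):
            build_lss_design(r.events, 99, "encoding", r.signal.shape[0], TR)

    def test_missing_rt_rejected(self, run):
        design, r = run
        ev = r.events.copy()
        ev.loc[ev.trial_type == "rating", "response_time"] = np.nan
        with pytest.raises(InvalidArgumentError):
            build_lss_design(ev, 0, "encoding", r.signal.shape[0], TR)

    def test_overlong_rt_clipped_with_warning(self, run):
        design, r = run
        ev = r.events.copy()
        idx = ev.index[ev.trial_type == "rating"][0]
        ev.loc[idx, "response_time"] = 99.0
        with pytest.warns(UserWarning):
            build_lss_design(ev, 0, "encoding", r.signal.shape[0], TR)


class TestLssFit:
    def _design(self, n_frames=80, n_trials=4, spacing=12.0):
        rows = [(0.0, 2.0, "instruction", None, np.nan, np.nan, np.nan, 0)]
        for k in range(n_trials):
            onset = 4.0 + k * spacing
            rows.append((onset, 6.0, "encode", "spatial", np.nan, np.nan, k, 0))
            rows.append((onset + 6.0, 4.0, "rating", "spatial", 1.5, np.nan, k, 0))
            rows.append((onset + 10.0, 2.0, "iti", None, np.nan, np.nan, k, 0))
        ev = pd.DataFrame(
            rows,
            columns=["onset", "duration", "trial_type", "context",
                     "response_time", "accuracy", "trial", "run"],
        )
        return ev, build_lss_design(ev, 0, "encoding", n_frames, TR)

    def test_exact_recovery_from_design(self, rng):
        _, d = self._design()
        b = rng.standard_normal((d.matrix.shape[1], 20))
        y = d.matrix @ b
        est = lss_fit(y, d)
        np.testing.assert_allclose(est.beta, b[0], atol=1e-8)

    def test_scale_equivariance(self, rng):
        _, d = self._design()
        y = d.matrix @ rng.standard_normal(d.matrix.shape[1]) + 0.3 * rng.standard_normal(
            d.matrix.shape[0]
        )
        e1 = lss_fit(y, d)
        e2 = lss_fit(2.0 * y, d)
        assert e2.beta == pytest.approx(2.0 * e1.beta)
        assert e2.t == pytest.approx(e1.t, rel=1e-9)

    def test_null_t_distribution(self):
        rng = np.random.default_rng(99)
        _, d = self._design()
        y = rng.standard_normal((d.matrix.shape[0], 500))
        est = lss_fit(y, d)
        assert abs(est.t.mean()) < 0.15

    def test_rank_deficiency_reported(self):
        ev, d = self._design()
        X = np.hstack([d.matrix, d.matrix[:, [0]]])
        from infoconn.estimation import DesignMatrix

        dd = DesignMatrix(matrix=X, labels=d.labels + ["dup"], tr=TR)
        with pytest.raises(IllPosedError):
            lss_fit(np.zeros(X.shape[0]), dd)

    def test_lss_matches_all_trials_glm_on_orthogonal_windows(self, rng):
        """Widely spaced trials: LS-S betas equal a single GLM's betas."""
        n_frames, n_trials = 160, 3
        spacing = 50.0  # > HRF duration + trial: regressors orthogonal
        regs = [
            convolve_events([(10.0 + k * spacing, 6.0)], n_frames, TR)
            for k in range(n_trials)
        ]
        # disjoint supports make the trial regressors mutually orthogonal
        X_all = np.column_stack(regs)
        b_true = np.array([1.5, -0.7, 2.2])
        y = X_all @ b_true
        # all-trials GLM oracle
        b_hat_all = np.linalg.lstsq(X_all, y, rcond=None)[0]
        for k in range(n_trials):
            others = np.sum([regs[j] for j in range(n_trials) if j != k], axis=0)
            X_lss = np.column_stack([regs[k], others])
            b_lss = np.linalg.lstsq(X_lss, y, rcond=None)[0][0]
            assert b_lss == pytest.approx(b_hat_all[k], abs=1e-6)


class TestCensor:
    def _events(self, n_trials=4):
        rows = []
        for k in range(n_trials):
            onset = 5.0 + k * 15.0
            rows.append((onset, 6.0, "encode", "spatial", np.nan, np.nan, k, 0))
        return pd.DataFrame(
            rows,
            columns=["onset", "duration", "trial_type", "context",
                     "response_time", "accuracy", "trial", "run"],
        )

    def test_no_censoring_all_retained(self):
        ev = self._events()
        mask = CensorMask(fd=np.zeros(60), censored=np.zeros(60, dtype=bool))
        flags, excluded = censor(ev, mask, 60, TR)
        assert flags["included"].all()
        assert not excluded

    def test_single_frame_excludes_only_hit_trial(self):
        ev = self._events()
        censored = np.zeros(60, dtype=bool)
        # trial 2 spans [35, 41] s -> frame 24 at 37.4 s is inside
        censored[24] = True
        mask = CensorMask(fd=np.zeros(60), censored=censored)
        flags, _ = censor(ev, mask, 60, TR)
        assert flags["included"].tolist() == [True, True, False, True]

    def test_run_exclusion_flags_all_trials(self):
        ev = self._events()
        censored = np.zeros(60, dtype=bool)
        censored[:13] = True  # 21.7% > 20%
        mask = CensorMask(
            fd=np.zeros(60), censored=censored, run_excluded=True,
            reason="21.7% of frames exceed FD 0.9 mm",
        )
        flags, excluded = censor(ev, mask, 60, TR)
        assert excluded
        assert (~flags["included"]).all()

    def test_censoring_monotone(self):
        """Adding censored frames never un-excludes a trial."""
        ev = self._events()
        rng = np.random.default_rng(4)
        base = np.zeros(60, dtype=bool)
        base[rng.choice(60, 5, replace=False)] = True
        more = base.copy()
        more[rng.choice(60, 5, replace=False)] = True
        f1, _ = censor(ev, CensorMask(fd=np.zeros(60), censored=base), 60, TR)
        f2, _ = censor(ev, CensorMask(fd=np.zeros(60), censored=more), 60, TR)
        assert np.all(f1["included"].to_numpy() | ~f2["included"].to_numpy())


class TestEndToEnd:
    def test_noiseless_recovery_via_bold(self):
        design = StudyDesign(trials_per_encoding_run=4, trials_per_retrieval_run=4)
        atlas = generate_atlas(2, 30, 30, seed=1)
        model = GenerativeModel(n_rois=2, seed=1, noise_sd=0.0, gain_sd=0.0)
        r = generate_bold_session(design, atlas, model, seed=0, phase="encoding")[0]
        ests = estimate_run(r.signal, r.events, "encoding", TR)
        sl = atlas.voxel_slices()[1]
        ctx = r.events[r.events.trial_type == "encode"].iloc[0]["context"]
        u = model.template(atlas, 1, ctx)
        for est in ests:
            np.testing.assert_allclose(
                est.beta[sl], r.true_amplitudes[1][est.trial] * u, atol=1e-8
            )

    def test_injected_spike_censors_trial(self):
        design = StudyDesign(trials_per_encoding_run=4, trials_per_retrieval_run=4)
        atlas = generate_atlas(2, 30, 30, seed=1)
        model = GenerativeModel(n_rois=2, seed=1, noise_sd=0.0, gain_sd=0.0)
        r = generate_bold_session(
            design, atlas, model, seed=0, phase="encoding",
            motion_spikes={0: [10]}, spike_mm=1.5,
        )[0]
        fd = framewise_displacement(r.motion)
        assert fd[10] > 0.9
        mask = censor_mask_from_motion(r.motion)
        assert mask.censored[10]

    def test_high_motion_run_flagged(self):
        design = StudyDesign(trials_per_encoding_run=4, trials_per_retrieval_run=4)
        atlas = generate_atlas(2, 30, 30, seed=1)
        model = GenerativeModel(n_rois=2, seed=1, noise_sd=0.0, gain_sd=0.0)
        runs = generate_bold_session(design, atlas, model, seed=0, phase="encoding")
        n = runs[0].signal.shape[0]
        spikes = list(range(1, n, 4))  # 25% of frames
        r = generate_bold_session(
            design, atlas, model, seed=0, phase="encoding",
            motion_spikes={0: spikes}, spike_mm=1.0,
        )[0]
        mask = censor_mask_from_motion(r.motion)
        assert mask.censored_fraction > 0.2
        assert mask.run_excluded
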