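import numpy as np
import pandas as pd
import pytest

from revlearn import (
    AgentParams,
    ConvolutionGLM,
    baseline_normalize,
    build_design,
    collinearity_screen,
    fit_convolution_glm,
    generate_neural,
    generate_schedule,
    morlet_tf,
    simulate_agent,
    trajectory_regressors,
)
from revlearn.simulate import SyntheticNeuralSpec
from revlearn.tfglm import ResponseImage, fourier_basis

SFREQ = 250.0


def events_frame(onsets, types, values=None):
    return pd.DataFrame(
        {
            "onset_s": np.asarray(onsets, dtype=float),
            "type": types,
            "value": 1.0 if values is None else np.asarray(values, dtype=float),
        }
    )


class TestMorlet:
    def test_pure_tone_concentrates(self):
        t = np.arange(0, 20, 1 / SFREQ)
        tf = morlet_tf(np.sin(2 * np.pi * 20 * t), SFREQ, band="low")
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        mean_amp = tf.values[:, mid].mean(axis=1)
        peak = tf.freqs[np.argmax(mean_amp)]
        assert peak == 20.0
        far = np.abs(tf.freqs - 20) >= 10
        assert mean_amp.max() >= 3 * mean_amp[far].max()

    def test_silence_is_zero(self):
        tf = morlet_tf(np.zeros(5000), SFREQ, band="gamma")
        assert np.allclose(tf.values, 0.0)

    def test_envelope_tracking(self):
        t = np.arange(0, 30, 1 / SFREQ)
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        tf = morlet_tf(env * np.cos(2 * np.pi * 40 * t), SFREQ, band="gamma")
        bin40 = np.argmin(np.abs(tf.freqs - 40))
        inner = slice(int(2 * SFREQ), int(28 * SFREQ))
        r = np.corrcoef(tf.values[bin40, inner], env[inner])[0, 1]
        assert r > 0.95

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="wavelet"):
            morlet_tf(np.zeros(100), SFREQ, band="low")


class TestDesign:
    def test_resolution_law_numbers(self):
        # order 20 over 2.3 s resolves up to 20/2.3 ~ 8.7 Hz;
        # order 40 gives 2300/40 = 57.5 ms temporal resolution
        assert 20 / 2.3 == pytest.approx(8.7, abs=0.01)
        assert 2300 / 40 == pytest.approx(57.5)
        B, times = fourier_basis(20, (-0.5, 1.8), SFREQ)
        assert B.shape == (int(2.3 * SFREQ), 40)
        assert times[0] == pytest.approx(-0.5)

    def test_single_event_order_one(self):
        ev = events_frame([2.0], ["outcome"])
        d = build_design(ev, duration_s=6.0, sfreq=SFREQ, order=1, window=(0.0, 1.0))
        onset = int(2.0 * SFREQ)
        tau = np.arange(int(SFREQ)) / SFREQ
        assert np.allclose(
            d.X[onset : onset + int(SFREQ), 0], np.sin(2 * np.pi * tau)
        )
        assert np.allclose(d.X[: onset, :2], 0.0)
        assert np.all(d.X[:, -1] == 1.0)  # intercept

    def test_overlapping_same_sample_events_merged(self):
        ev = events_frame([1.0, 1.0], ["a", "a"], [1.0, 2.0])
        with pytest.warns(UserWarning, match="merged"):
            d = build_design(ev, duration_s=4.0, sfreq=SFREQ, order=2, window=(0, 1))
        assert d.U[int(SFREQ), 0] == 3.0

    def test_out_of_range_onsets_rejected(self):
        ev = events_frame([5.0], ["a"])
        with pytest.raises(ValueError, match="duration"):
            build_design(ev, duration_s=4.0, sfreq=SFREQ, order=2, window=(0, 1))


def slice_traj(traj, n):
    import dataclasses

    fields = {
        f.name: getattr(traj, f.name)[:n]
        for f in dataclasses.fields(traj)
        if f.name not in ("params", "levels")
    }
    return dataclasses.replace(traj, **fields)


def baseline_sub(x, times, window=(-0.25, -0.05)):
    sel = (times >= window[0]) & (times <= window[1])
    return x - x[sel].mean()


def synth_tf_and_truth(noise=0.0, gains=None, seed=0, n_trials=60, band="gamma"):
    """Forward-simulate an oscillatory series from an HGF session."""
    sched = generate_schedule(1, 160, seed=seed)
    trials, traj = simulate_agent(AgentParams(), sched, "hgf3_mu3", seed=seed + 1)
    trials, traj = trials.iloc[:n_trials], slice_traj(traj, n_trials)
    spec = SyntheticNeuralSpec(
        sampling_rate=SFREQ,
        carriers=[
            {
                "freq": 76.0,
                "event_type": "outcome",
                "base_amplitude": 1.0,
                "gains": gains or {},
                "latency_s": 0.3,
                "duration_s": 0.4,
            }
        ],
        noise_sd=noise,
        seed=seed,
    )
    series, events, truth = generate_neural(trials, traj, spec)
    tf = morlet_tf(series, SFREQ, band=band)
    return trials, traj, series, events, truth, tf


class TestConvolutionGLM:
    def test_noise_free_single_event_recovery(self):
        """With no noise and discrete events only, the deconvolved response
        at the carrier bin matches the TF transform of one isolated event."""
        trials, traj, series, events, truth, tf = synth_tf_and_truth()
        discrete = events[events["value"] == 1.0]
        images = fit_convolution_glm(tf, discrete, order=20, window=(-0.5, 1.8))
        # reference: isolated single event, same transform
        ref_spec = SyntheticNeuralSpec(
            sampling_rate=SFREQ,
            carriers=[
                {
                    "freq": 76.0,
                    "event_type": "outcome",
                    "base_amplitude": 1.0,
                    "gains": {},
                    "latency_s": 0.3,
                    "duration_s": 0.4,
                }
            ],
        )
        t_iso = np.arange(0, 8, 1 / SFREQ)
        iso = np.zeros_like(t_iso)
        env = truth["discrete_outcome"]["envelope"]
        peri = truth["discrete_outcome"]["times"]
        i0 = int(4.0 * SFREQ)
        iso[i0 : i0 + len(peri)] += env * np.cos(2 * np.pi * 76.0 * t_iso[i0 : i0 + len(peri)])
        tf_iso = morlet_tf(iso, SFREQ, band="gamma")
        bin76 = np.argmin(np.abs(tf_iso.freqs - 76))
        sel = (np.arange(len(t_iso)) / SFREQ >= 4.0 - 0.5) & (
            np.arange(len(t_iso)) / SFREQ < 4.0 + 1.8
        )
        ref = tf_iso.values[bin76, sel]

        img = images["outcome_win"]
        # response images carry an arbitrary window-DC offset (no per-
        # regressor constant in the basis); compare after baseline-mean
        # subtraction exactly as the analysis pipeline normalises them
        rec = baseline_sub(img.values[bin76], img.times)
        ref = baseline_sub(ref, img.times)
        inner = slice(30, len(ref) - 30)
        rel_err = np.abs(rec[inner] - ref[inner]).max() / ref.max()
        assert rel_err < 0.05

    def test_parametric_response_scales_linearly_with_gain(self):
        recovered = {}
        for g in (0.5, 1.0, 2.0):
            trials, traj, series, events, truth, tf = synth_tf_and_truth(
                gains={"abs_eps2": g}, seed=3
            )
            keep = events["type"].isin(
                ["outcome_win", "outcome_lose", "outcome_none", "abs_eps2"]
            )
            images = fit_convolution_glm(tf, events[keep], order=20, window=(-0.5, 1.8))
            bin76 = np.argmin(np.abs(tf.freqs - 76))
            img = images["abs_eps2"]
            recovered[g] = baseline_sub(img.values[bin76], img.times).max()
        assert recovered[1.0] / recovered[0.5] == pytest.approx(2.0, rel=0.1)
        assert recovered[2.0] / recovered[1.0] == pytest.approx(2.0, rel=0.1)

    def test_parametric_gamma_gain_lands_in_gamma_bins(self):
        trials, traj, series, events, truth, tf = synth_tf_and_truth(
            gains={"abs_eps2": 1.0}, seed=5
        )
        keep = events["type"].isin(
            ["outcome_win", "outcome_lose", "outcome_none", "abs_eps2"]
        )
        images = fit_convolution_glm(tf, events[keep], order=20, window=(-0.5, 1.8))
        img = np.array(
            [
                baseline_sub(row, images["abs_eps2"].times)
                for row in images["abs_eps2"].values
            ]
        )
        prof = np.abs(img).max(axis=1)
        peak_freq = tf.freqs[np.argmax(prof)]
        assert 70 <= peak_freq <= 82

    def test_intercept_absorbs_global_offset(self):
        trials, traj, series, events, truth, tf = synth_tf_and_truth(seed=7)
        discrete = events[events["value"] == 1.0]
        im1 = fit_convolution_glm(tf, discrete, order=10, window=(-0.5, 1.8))
        tf2 = ResponseImage  # noqa: F841 (clarity only)
        shifted = type(tf)(
            freqs=tf.freqs, times=tf.times, values=tf.values + 3.0, sfreq=tf.sfreq
        )
        im2 = fit_convolution_glm(shifted, discrete, order=10, window=(-0.5, 1.8))
        for k in im1:
            assert np.allclose(im1[k].values, im2[k].values, atol=1e-6)

    def test_rank_deficient_design_reports_columns(self):
        ev = events_frame([1.0, 1.0], ["a", "b"])  # identical impulse trains
        t = np.arange(0, 4, 1 / SFREQ)
        tf = morlet_tf(np.sin(2 * np.pi * 20 * t), SFREQ, band="low")
        with pytest.raises(ValueError, match="collinear"):
            fit_convolution_glm(tf, ev, order=4, window=(0, 1))


class TestDeconvolutionVsAveraging:
    def test_overlapping_events_separated(self):
        """Two event types with overlapping epochs: the GLM separates the
        injected responses while epoch averaging mixes them."""
        rng = np.random.default_rng(0)
        dur = 180.0
        t = np.arange(0, dur, 1 / SFREQ)
        onsets_a = 5.0 + np.cumsum(rng.uniform(2.4, 3.6, 60))
        onsets_a = onsets_a[onsets_a < dur - 5]
        onsets_b = onsets_a + rng.uniform(0.45, 0.75, len(onsets_a))
        peri = np.arange(0, 0.8 + 1 / SFREQ, 1 / SFREQ)

        def hann(lat, wid):
            tau = (peri - lat) / wid
            e = np.zeros_like(peri)
            m = (tau >= 0) & (tau <= 1)
            e[m] = 0.5 * (1 - np.cos(2 * np.pi * tau[m]))
            return e

        env_a, env_b = hann(0.1, 0.4), hann(0.2, 0.5)
        series = np.zeros_like(t)
        for o in onsets_a:
            i0 = int(round(o * SFREQ))
            series[i0 : i0 + len(peri)] += env_a * np.cos(2 * np.pi * 50 * t[i0 : i0 + len(peri)])
        for o in onsets_b:
            i0 = int(round(o * SFREQ))
            series[i0 : i0 + len(peri)] += 0.6 * env_b * np.cos(
                2 * np.pi * 50 * t[i0 : i0 + len(peri)]
            )
        tf = morlet_tf(series, SFREQ, band="gamma")
        bin50 = np.argmin(np.abs(tf.freqs - 50))

        ev = pd.concat(
            [events_frame(onsets_a, "a"), events_frame(onsets_b, "b")],
            ignore_index=True,
        )
        # per-regressor DC column so responses are recovered in absolute
        # units rather than up to a window constant
        images = fit_convolution_glm(tf, ev, order=20, window=(-0.3, 1.2), dc=True)
        n_peri = images["a"].values.shape[1]

        # reference: isolated transform of the a-injection
        x = np.zeros(int(10 * SFREQ))
        i0 = int(5 * SFREQ)
        x[i0 : i0 + len(peri)] = env_a * np.cos(
            2 * np.pi * 50 * np.arange(i0, i0 + len(peri)) / SFREQ
        )
        tfx = morlet_tf(x, SFREQ, band="gamma")
        sel0 = int((5 - 0.3) * SFREQ)
        ref_a = tfx.values[bin50, sel0 : sel0 + n_peri]

        def err(xv, ref):
            inner = slice(20, len(ref) - 20)
            return np.abs(xv[inner] - ref[inner]).max() / ref.max()

        glm_err = err(images["a"].values[bin50], ref_a)

        # naive epoch average around a-onsets
        ep = []
        for o in onsets_a:
            i0 = int((o - 0.3) * SFREQ)
            ep.append(tf.values[bin50, i0 : i0 + n_peri])
        avg_err = err(np.mean(ep, axis=0), ref_a)
        assert glm_err < 0.05
        assert avg_err > 5 * glm_err

    def test_resolution_law_by_injected_envelopes(self):
        """Envelope modulation below the order/window limit is recovered;
        above it, the basis cannot represent it."""
        dur = 200.0
        t = np.arange(0, dur, 1 / SFREQ)
        onsets = np.arange(4.0, dur - 4, 3.9)
        window = (-0.5, 1.8)
        T = window[1] - window[0]
        peri = np.arange(0, 1.8, 1 / SFREQ)

        def run(cycles_in_window):
            f_mod = cycles_in_window / T
            env = 1.0 + 0.8 * np.sin(2 * np.pi * f_mod * peri)
            series = np.zeros_like(t)
            for o in onsets:
                i0 = int(o * SFREQ)
                series[i0 : i0 + len(peri)] += env * np.cos(
                    2 * np.pi * 44 * t[i0 : i0 + len(peri)]
                )
            tf = morlet_tf(series, SFREQ, band="gamma")
            ev = events_frame(onsets, "e")
            img = fit_convolution_glm(tf, ev, order=20, window=window)["e"]
            bin44 = np.argmin(np.abs(tf.freqs - 44))
            rec = img.values[bin44]
            sel = (img.times >= 0.15) & (img.times <= 1.65)
            ref_env = 1.0 + 0.8 * np.sin(2 * np.pi * f_mod * (img.times[sel] - 0.0))
            # modulation amplitude via projection on the known sin/cos pair
            def mod_amp(x, times):
                s = np.sin(2 * np.pi * f_mod * times)
                c = np.cos(2 * np.pi * f_mod * times)
                s -= s.mean()
                c -= c.mean()
                xs = x - x.mean()
                return 2 * np.hypot(xs @ s / len(s), xs @ c / len(c))
            return (
                mod_amp(rec[sel], img.times[sel]),
                mod_amp(ref_env, img.times[sel]),
            )

        rec_lo, ref_lo = run(14)   # ~6.1 Hz < 8.7 Hz limit
        rec_hi, ref_hi = run(28)   # ~12.2 Hz > 8.7 Hz limit
        assert rec_lo / ref_lo > 0.5
        assert rec_hi / ref_hi < 0.3 * (rec_lo / ref_lo)


class TestBaseline:
    def img(self):
        rng = np.random.default_rng(1)
        times = np.arange(-0.5, 1.8, 1 / SFREQ)
        values = rng.normal(2.0, 0.3, size=(5, len(times)))
        return ResponseImage("x", times, np.arange(5.0), values)

    def test_definition_and_roundtrip(self):
        r = self.img()
        n = baseline_normalize(r)
        sel = (n.times >= -0.3) & (n.times <= -0.05)
        assert np.allclose(n.values[:, sel].mean(axis=1), 0.0, atol=1e-10)
        assert n.units == "SD"
        back = n.values * n.baseline_sd[:, None] + n.baseline_mean[:, None]
        assert np.allclose(back, r.values)

    def test_constant_in_time_becomes_zero(self):
        times = np.arange(-0.5, 1.0, 1 / SFREQ)
        vals = np.tile(np.array([[3.0], [5.0]]), (1, len(times)))
        vals += np.random.default_rng(0).normal(0, 0.1, vals.shape)
        r = ResponseImage("x", times, np.arange(2.0), vals)
        n = baseline_normalize(r)
        assert np.abs(n.values.mean()) < 0.5

    def test_zero_baseline_sd_rejected(self):
        times = np.arange(-0.5, 1.0, 1 / SFREQ)
        vals = np.ones((2, len(times)))
        with pytest.raises(ValueError, match="SD"):
            baseline_normalize(ResponseImage("x", times, np.arange(2.0), vals))

    def test_window_outside_axis_rejected(self):
        r = self.img()
        with pytest.raises(ValueError, match="window"):
            baseline_normalize(r, window=(-2.0, -1.5))


class TestCollinearity:
    def test_orthogonal_regressors_all_retained(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 3))
        q, _ = np.linalg.qr(x)
        df = pd.DataFrame(q, columns=["r1", "r2", "r3"])
        out = collinearity_screen(df)
        assert out["retained"] == ["r1", "r2", "r3"]
        assert not out["report"]["flagged"].any()

    def test_hgf_eps3_flagged_and_excluded(self, session_mu3):
        _, traj = session_mu3
        regs = trajectory_regressors(traj)
        out = collinearity_screen(regs)
        pair_rows = out["report"][
            out["report"]["pair"].apply(lambda p: set(p) == {"abs_eps2", "eps3"})
        ]
        assert pair_rows["flagged"].all()
        assert abs(pair_rows["r"].iloc[0]) > 0.2
        assert "eps3" not in out["retained"]
        assert {"abs_eps2", "sigma2", "sigma3"} <= set(out["retained"])

    def test_constant_regressor_degenerate(self):
        df = pd.DataFrame({"a": np.ones(50), "b": np.random.default_rng(0).normal(size=50)})
        out = collinearity_screen(df)
        assert out["degenerate"] == ["a"]
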