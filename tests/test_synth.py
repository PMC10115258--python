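"""Generator contracts: speed process, oscillators, phase-locked spiking."""

import numpy as np
import pytest
from scipy import stats as sps

from fourhz import (
    InvalidArgumentError,
    SynthConfig,
    gen_lfp,
    gen_session,
    gen_speed,
    gen_spikes,
    welch_psd,
    peak_frequency,
    band_power,
)


class TestGenSpeed:
    def test_degenerate_ou_is_constant(self):
        cfg = SynthConfig(speed_sd=0.0, speed_mean_wheel=60.0)
        v = gen_speed("wheel", "pre", 10.0, cfg, seed=0)
        assert np.allclose(v, 60.0)

    def test_determinism(self):
        cfg = SynthConfig()
        a = gen_speed("maze", "pre", 20.0, cfg, seed=7)
        b = gen_speed("maze", "pre", 20.0, cfg, seed=7)
        assert np.array_equal(a, b)

    def test_nonnegative_and_correct_length(self):
        cfg = SynthConfig()
        v = gen_speed("wheel", "post", 12.5, cfg, seed=1)
        assert (v >= 0).all()
        assert len(v) == int(12.5 * cfg.fs_beh)

    def test_invalid_duration(self):
        with pytest.raises(InvalidArgumentError):
            gen_speed("wheel", "pre", 0.0, SynthConfig(), seed=0)

    def test_post_muscimol_slows_running(self):
        """Post-condition wheel speeds drop (rank-sum p < 0.01, 500 trials)."""
        cfg = SynthConfig()
        pre = [gen_speed("wheel", "pre", 2.0, cfg, seed=i).mean() for i in range(500)]
        post = [gen_speed("wheel", "post", 2.0, cfg, seed=10_000 + i).mean() for i in range(500)]
        assert np.mean(post) < np.mean(pre)
        p = sps.mannwhitneyu(pre, post, alternative="greater").pvalue
        assert p < 0.01

    def test_maze_stops_reach_near_zero(self):
        cfg = SynthConfig(maze_stop_rate=3.0)
        v = gen_speed("maze", "pre", 15.0, cfg, seed=11)
        assert v.min() < 1.0  # at least one stop dips to ~0


class TestGenLfp:
    def test_pure_sinusoids_without_noise(self):
        cfg = SynthConfig(noise_scale=0.0, g_slow_speed=0.0, g_theta_speed=0.0,
                          h_slow_speed=0.0, h_theta_speed=0.0)
        v = np.full(int(20 * cfg.fs_beh), 60.0)
        lfp, truth = gen_lfp(v, cfg, "pre", seed=0)
        psd = welch_psd(lfp, cfg.fs_lfp, window_s=4.0)
        assert abs(peak_frequency(psd, (3.0, 5.0)) - cfg.f_slow) < 0.1
        assert abs(peak_frequency(psd, (6.0, 10.0)) - cfg.f_theta) < 0.1
        # closed-form amplitude of each component
        assert np.allclose(truth.amp_slow, cfg.a_slow0)
        assert np.allclose(truth.amp_theta, cfg.a_theta0)

    def test_muscimol_abolishes_theta_preserves_slow(self):
        """Theta-scale 0 drops 6-10 Hz power to the noise floor; 3-5 Hz
        power stays within 10% of the pre run with the same seed."""
        cfg = SynthConfig()
        v = gen_speed("wheel", "pre", 60.0, cfg, seed=3)
        lfp_pre, _ = gen_lfp(v, cfg, "pre", seed=5, speed_ref=60.0)
        lfp_post, _ = gen_lfp(v, cfg, "post", seed=5, speed_ref=60.0)
        noise_only, _ = gen_lfp(v, cfg.replace(a_slow0=0.0, a_theta0=0.0,
                                               g_slow_speed=0.0), "pre", seed=5)
        psd = lambda x: welch_psd(x, cfg.fs_lfp)
        # post condition shifts f_slow to 3.72 Hz, still inside 3-5 Hz
        assert band_power(psd(lfp_post), (6, 10)) <= 1.1 * band_power(psd(noise_only), (6, 10))
        r = band_power(psd(lfp_post), (3, 5)) / band_power(psd(lfp_pre), (3, 5))
        assert 0.9 < r < 1.1

    def test_amplitude_tracks_speed_monotonically(self):
        cfg = SynthConfig(g_slow_speed=0.8)
        v = gen_speed("wheel", "pre", 30.0, cfg, seed=9)
        _, truth = gen_lfp(v, cfg, "pre", seed=9)
        v_lfp = np.interp(np.arange(len(truth.amp_slow)) / cfg.fs_lfp,
                          np.arange(len(v)) / cfg.fs_beh, v)
        rho = sps.spearmanr(truth.amp_slow, v_lfp).statistic
        assert rho > 0.9999  # exact monotone map before noise

    def test_slow_scale_length_mismatch(self):
        cfg = SynthConfig()
        v = np.full(100, 60.0)
        with pytest.raises(InvalidArgumentError):
            gen_lfp(v, cfg, "pre", seed=0, slow_scale=np.ones(10))


class TestGenSpikes:
    @staticmethod
    def _truth(cfg, duration=300.0, seed=0):
        v = gen_speed("wheel", "pre", duration, cfg, seed=seed)
        _, truth = gen_lfp(v, cfg, "pre", seed=seed, speed_ref=60.0)
        return truth

    def test_unmodulated_limit_recovers_rate(self):
        cfg = SynthConfig(kappa_slow_pyr=0.0, kappa_theta_pyr=0.0, base_rate_pyr=10.0)
        truth = self._truth(cfg)
        st = gen_spikes(truth, cfg, "pyramidal", "pre", seed=2)
        n_expected = 10.0 * 300.0
        assert abs(len(st) - n_expected) < 3 * np.sqrt(n_expected)

    def test_preferred_phase_recovered(self):
        """kappa_slow=2 spikes concentrate at the preferred slow phase."""
        mu = 0.7
        cfg = SynthConfig(kappa_slow_pyr=2.0, kappa_theta_pyr=0.0,
                          base_rate_pyr=10.0, mu_slow=mu)
        truth = self._truth(cfg)
        st = gen_spikes(truth, cfg, "pyramidal", "pre", seed=4)
        idx = np.minimum((st * cfg.fs_lfp).astype(int), len(truth.phase_slow) - 1)
        phases = np.mod(truth.phase_slow[idx], 2 * np.pi)
        circ_mean = np.angle(np.exp(1j * phases).mean())
        assert abs(np.angle(np.exp(1j * (circ_mean - mu)))) < 0.1

    def test_thinning_envelope_bound(self):
        """Peak modulated rate never exceeds r0·exp(κ_s+κ_θ)/Z."""
        cfg = SynthConfig(base_rate_int=20.0)
        truth = self._truth(cfg, duration=30.0)
        k = cfg.kappa_slow_int + cfg.kappa_theta_int
        log_mod = (cfg.kappa_slow_int * np.cos(truth.phase_slow)
                   + cfg.kappa_theta_int * np.cos(truth.phase_theta))
        z = np.exp(log_mod).mean()
        lam_max = cfg.base_rate_int * np.exp(log_mod).max() / z
        assert lam_max <= cfg.base_rate_int * np.exp(k) / z + 1e-9

    def test_invalid_rate(self):
        cfg = SynthConfig(base_rate_pyr=1.0)
        truth = self._truth(cfg, duration=10.0)
        with pytest.raises(InvalidArgumentError):
            gen_spikes(truth, cfg, "pyramidal", "pre", seed=0, base_rate=0.0)

    def test_determinism(self):
        cfg = SynthConfig()
        truth = self._truth(cfg, duration=20.0)
        a = gen_spikes(truth, cfg, "interneuron", "pre", seed=5)
        b = gen_spikes(truth, cfg, "interneuron", "pre", seed=5)
        assert np.array_equal(a, b)


class TestGenSession:
    def test_trial_layout(self, tiny_cfg):
        s = gen_session(tiny_cfg, "pre", 1)
        maze = s.trials_in("maze")
        wheel = s.trials_in("wheel")
        assert len(maze) == 2 and len(wheel) == 2
        ordered = sorted(s.trials, key=lambda t: t.t_start)
        for a, b in zip(ordered[:-1], ordered[1:]):
            assert a.t_end <= b.t_start  # non-overlapping
        assert all(t.t_end <= s.duration for t in s.trials)

    def test_determinism(self, tiny_cfg):
        a = gen_session(tiny_cfg, "pre", 3)
        b = gen_session(tiny_cfg, "pre", 3)
        assert np.array_equal(a.lfp, b.lfp)
        assert np.array_equal(a.speed, b.speed)
        for na, nb in zip(a.neurons, b.neurons):
            assert np.array_equal(na.spike_times, nb.spike_times)

    def test_ground_truth_attached_and_aligned(self, tiny_cfg):
        s = gen_session(tiny_cfg, "pre", 2)
        assert s.ground_truth is not None
        assert len(s.ground_truth.amp_slow) == len(s.lfp)
        # lfp and speed cover the same span within one behavioral sample
        assert abs(len(s.lfp) / s.fs_lfp - len(s.speed) / s.fs_beh) <= 1.0 / s.fs_beh

    def test_maze_slow_component_silenced(self, tiny_cfg):
        s = gen_session(tiny_cfg, "pre", 2)
        gt = s.ground_truth
        fs = s.fs_lfp
        for tr in s.trials:
            a, b = int(tr.t_start * fs) + 10, int(tr.t_end * fs) - 10
            if tr.context == "maze":
                assert np.allclose(gt.amp_slow[a:b], 0.0)
            else:
                assert gt.amp_slow[a:b].min() > 0

    def test_choice_labels_follow_condition_rate(self):
        cfg = SynthConfig(n_trials_per_context=40, n_interneurons=0, n_pyramidal=0,
                          trial_duration=1.0, gap_duration=0.2)
        pre = gen_session(cfg, "pre", 5)
        post = gen_session(cfg, "post", 5)
        frac = lambda s: np.mean([t.choice == "correct" for t in s.trials])
        assert frac(pre) > frac(post)
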