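"""Synthetic recording sessions with known ground truth.

The generator emulates a rat alternating between translational maze runs and
stationary wheel runs (~15 s each), recorded before ("pre") or after
("post") muscimol inactivation of the medial septum:

* running speed is an Ornstein–Uhlenbeck process reflected at zero, with
  near-zero "stop" segments inserted into maze runs so the 10 cm/s gate is
  exercised;
* the LFP is the sum of two oscillators over 1/f noise — a slow (~4 Hz)
  component whose amplitude grows with speed and a theta (~8 Hz) component
  decoupled from speed by default — with both instantaneous frequencies
  weakly coupled to speed deviations;
* the slow component is present during wheel runs and scaled by
  ``maze_slow_scale`` (default 0) during maze runs, reproducing the
  context dissociation;
* spike trains are inhomogeneous Poisson processes phase-locked to both
  rhythms via a double von Mises rate modulation, simulated by thinning;
* the post-muscimol transform abolishes theta (amplitude scale 0), slows
  both rhythms (×0.93), lowers running speed, reduces interneuron rates and
  weakens phase modulation.

Every operation is deterministic given its ``(cfg, seed)`` pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SynthConfig, check_condition, check_context
from .errors import InvalidArgumentError

__all__ = [
    "TrialEpoch",
    "NeuronRecord",
    "GroundTruth",
    "SessionRecording",
    "gen_speed",
    "gen_pink_noise",
    "gen_lfp",
    "gen_spikes",
    "gen_session",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TrialEpoch:
    """One labeled run epoch: [t_start, t_end) in session seconds."""

    t_start: float
    t_end: float
    context: str  # maze | wheel
    choice: str  # correct | incorrect | na
    condition: str  # pre | post

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise InvalidArgumentError("trial epoch requires t_end > t_start")
        check_context(self.context)
        check_condition(self.condition)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class NeuronRecord:
    id: str
    cell_type: str  # interneuron | pyramidal
    spike_times: np.ndarray  # sorted, strictly increasing (s)

    def __post_init__(self) -> None:
        if self.cell_type not in ("interneuron", "pyramidal"):
            raise InvalidArgumentError(f"unknown cell_type {self.cell_type!r}")
        st = np.asarray(self.spike_times, dtype=float)
        if st.size > 1 and not np.all(np.diff(st) > 0):
            raise InvalidArgumentError("spike_times must be strictly increasing")
        self.spike_times = st


@dataclass
class GroundTruth:
    """Realized generator state: per-LFP-sample component amplitudes/phases."""

    config: SynthConfig
    amp_slow: np.ndarray  # µV
    amp_theta: np.ndarray
    phase_slow: np.ndarray  # rad, unwrapped
    phase_theta: np.ndarray
    slow_scale: np.ndarray | None = None  # per-sample maze/wheel scaling


@dataclass
class SessionRecording:
    """One synthetic (or adapted real) session."""

    lfp: np.ndarray  # µV at fs_lfp
    fs_lfp: float
    speed: np.ndarray  # cm/s at fs_beh
    fs_beh: float
    neurons: list[NeuronRecord] = field(default_factory=list)
    trials: list[TrialEpoch] = field(default_factory=list)
    condition: str = "pre"
    ground_truth: GroundTruth | None = None

    @property
    def duration(self) -> float:
        return len(self.lfp) / self.fs_lfp

    def trials_in(self, context: str | None = None) -> list[TrialEpoch]:
        return [t for t in self.trials if context is None or t.context == context]


# ---------------------------------------------------------------------------
# speed


def gen_speed(
    context: str,
    condition: str,
    duration: float,
    cfg: SynthConfig,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Ornstein–Uhlenbeck running-speed trace at ``cfg.fs_beh``, reflected at 0.

    Maze traces get Poisson-placed near-zero stop segments (raised-cosine
    dips) so downstream speed gating has work to do. The post condition
    scales the OU mean by ``muscimol_speed_scale``.
    """
    check_context(context)
    check_condition(condition)
    if not duration > 0:
        raise InvalidArgumentError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * cfg.fs_beh))
    mean = cfg.speed_mean(context)
    if condition == "post":
        mean *= cfg.muscimol_speed_scale
    dt = 1.0 / cfg.fs_beh
    # exact OU discretization
    a = np.exp(-dt / cfg.speed_tau)
    b = cfg.speed_sd * np.sqrt(max(0.0, 1.0 - a * a))
    x = np.empty(n)
    noise = rng.standard_normal(n)
    v = mean
    for i in range(n):
        v = mean + (v - mean) * a + b * noise[i]
        x[i] = v
    x = np.abs(x)  # reflect at zero

    if context == "maze":
        n_stops = rng.poisson(cfg.maze_stop_rate)
        env = np.ones(n)
        ramp = max(1, int(round(0.3 * cfg.fs_beh)))
        width = int(round(cfg.maze_stop_duration * cfg.fs_beh))
        for _ in range(n_stops):
            start = rng.integers(0, max(1, n - width))
            stop = min(n, start + width)
            seg = np.zeros(stop - start)
            k = min(ramp, len(seg) // 2)
            if k > 0:
                edge = 0.5 * (1 + np.cos(np.linspace(0, np.pi, k)))
                seg[:k] = edge
                seg[len(seg) - k :] = edge[::-1]
            env[start:stop] = np.minimum(env[start:stop], seg)
        x = x * env
    return x


# ---------------------------------------------------------------------------
# LFP


def gen_pink_noise(
    n: int, exponent: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, normalized to RMS = scale."""
    if scale == 0 or n == 0:
        # keep the rng stream identical whether or not noise is audible
        rng.standard_normal(n)
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (scale / rms)


def _resample_speed(speed: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    n_out = int(round(len(speed) / fs_in * fs_out))
    t_in = np.arange(len(speed)) / fs_in
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, speed)


def gen_lfp(
    speed: np.ndarray,
    cfg: SynthConfig,
    condition: str = "pre",
    seed: int | np.random.SeedSequence = 0,
    speed_fs: float | None = None,
    slow_scale: float | np.ndarray = 1.0,
    speed_ref: float | np.ndarray | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Two speed-coupled oscillators over 1/f noise.

    ``lfp(t) = A_s(t) sin(φ_s(t)) + A_θ(t) sin(φ_θ(t)) + pink noise`` with
    ``A_x(t) = max(0, a_x0 + g_x · v(t))`` and instantaneous frequency
    ``f_x + h_x · (v(t) − v_ref)`` integrated as a phase ODE (``speed_ref``
    defaults to the trace mean; pass the context's configured mean speed so
    ``f_x`` stays the realized center frequency during running even when the
    trace contains stops, while frequency and speed remain positively
    correlated). The post condition multiplies the
    theta amplitude by ``muscimol_theta_scale`` and both center frequencies
    by ``muscimol_freq_scale``. ``slow_scale`` (scalar or per-sample array)
    scales the slow component's amplitude, e.g. to silence it in the maze.
    """
    check_condition(condition)
    rng = np.random.default_rng(seed)
    fs = cfg.fs_lfp
    v = _resample_speed(np.asarray(speed, float), speed_fs or cfg.fs_beh, fs)
    n = len(v)
    if np.ndim(slow_scale):
        scale = np.asarray(slow_scale, float)
        if len(scale) != n:
            raise InvalidArgumentError(
                f"slow_scale length {len(scale)} != LFP length {n}"
            )
    else:
        scale = np.full(n, float(slow_scale))

    freq_fac = cfg.muscimol_freq_scale if condition == "post" else 1.0
    theta_amp_fac = cfg.muscimol_theta_scale if condition == "post" else 1.0

    if speed_ref is None:
        ref = v.mean() if n else 0.0
    elif np.ndim(speed_ref):
        ref = np.asarray(speed_ref, float)
        if len(ref) != n:
            raise InvalidArgumentError(f"speed_ref length {len(ref)} != LFP length {n}")
    else:
        ref = float(speed_ref)
    v_dev = v - ref
    amp_slow = np.maximum(0.0, cfg.a_slow0 + cfg.g_slow_speed * v) * scale
    amp_theta = np.maximum(0.0, cfg.a_theta0 + cfg.g_theta_speed * v) * theta_amp_fac
    f_inst_slow = cfg.f_slow * freq_fac + cfg.h_slow_speed * v_dev
    f_inst_theta = cfg.f_theta * freq_fac + cfg.h_theta_speed * v_dev

    phi0 = rng.uniform(0, 2 * np.pi, size=2)
    phase_slow = phi0[0] + 2 * np.pi * np.cumsum(f_inst_slow) / fs
    phase_theta = phi0[1] + 2 * np.pi * np.cumsum(f_inst_theta) / fs

    noise = gen_pink_noise(n, cfg.noise_exponent, cfg.noise_scale, rng)
    lfp = amp_slow * np.sin(phase_slow) + amp_theta * np.sin(phase_theta) + noise
    truth = GroundTruth(
        config=cfg,
        amp_slow=amp_slow,
        amp_theta=amp_theta,
        phase_slow=phase_slow,
        phase_theta=phase_theta,
        slow_scale=np.asarray(scale, float),
    )
    return lfp, truth


# ---------------------------------------------------------------------------
# spikes


def gen_spikes(
    truth: GroundTruth,
    cfg: SynthConfig,
    cell_type: str,
    condition: str = "pre",
    seed: int | np.random.SeedSequence = 0,
    base_rate: float | None = None,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike train phase-locked to both rhythms.

    Rate model: ``λ(t) = r0 · exp(κ_s s(t) cos(φ_s−μ_s) + κ_θ cos(φ_θ−μ_θ)) / Z``
    where ``s(t)`` is the ground-truth slow-component scale (so spikes are
    only slow-entrained where the slow rhythm exists) and ``Z`` is the
    time-average of the exponential, making ``r0`` the mean rate. Simulated
    by thinning a homogeneous process at ``max λ``. The post condition
    scales both κ by ``muscimol_kappa_scale`` and interneuron ``r0`` by
    ``muscimol_rate_scale_int``.
    """
    check_condition(condition)
    r0 = cfg.base_rate(cell_type) if base_rate is None else base_rate
    if condition == "post" and cell_type == "interneuron":
        r0 = r0 * cfg.muscimol_rate_scale_int
    if r0 <= 0:
        raise InvalidArgumentError("base rate must be positive")
    kfac = cfg.muscimol_kappa_scale if condition == "post" else 1.0
    k_s = cfg.kappa(cell_type, "slow") * kfac
    k_t = cfg.kappa(cell_type, "theta") * kfac

    fs = cfg.fs_lfp
    s = truth.slow_scale if truth.slow_scale is not None else np.ones_like(truth.phase_slow)
    log_mod = k_s * s * np.cos(truth.phase_slow - cfg.mu_slow) + k_t * np.cos(
        truth.phase_theta - cfg.mu_theta
    )
    mod = np.exp(log_mod)
    z = mod.mean()
    lam = r0 * mod / z
    lam_max = lam.max()
    duration = len(lam) / fs

    rng = np.random.default_rng(seed)
    n_cand = rng.poisson(lam_max * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.minimum((t_cand * fs).astype(int), len(lam) - 1)
    keep = rng.uniform(size=n_cand) < lam[idx] / lam_max
    spikes = t_cand[keep]
    # enforce strictly increasing times (duplicates are measure-zero but
    # possible at float resolution)
    if spikes.size > 1:
        spikes = spikes[np.concatenate(([True], np.diff(spikes) > 0))]
    return spikes


# ---------------------------------------------------------------------------
# session assembly


def gen_session(
    cfg: SynthConfig,
    condition: str = "pre",
    seed: int | None = None,
    contexts: tuple[str, ...] = ("maze", "wheel"),
) -> SessionRecording:
    """Assemble a full session: alternating maze/wheel trials with gaps.

    Trials alternate maze → wheel (the wheel run fills the intertrial
    interval of the alternation task), separated by ``gap_duration`` of
    near-zero speed; ``contexts`` restricts the cycle, e.g. ``("wheel",)``
    for a wheel-only session. Choice labels are drawn per trial cycle with
    the condition's correct rate. The LFP and all spike trains are
    generated over the concatenated session so oscillator phases are
    continuous.
    """
    check_condition(condition)
    for c in contexts:
        check_context(c)
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    n_pairs = cfg.n_trials_per_context
    n_ctx = len(contexts)
    n_neurons = cfg.n_interneurons + cfg.n_pyramidal
    children = ss.spawn(n_ctx * n_pairs + 2 + n_neurons)
    speed_seeds = children[: n_ctx * n_pairs]
    lfp_seed = children[n_ctx * n_pairs]
    choice_seed = children[n_ctx * n_pairs + 1]
    neuron_seeds = children[n_ctx * n_pairs + 2 :]

    fs_beh, fs_lfp = cfg.fs_beh, cfg.fs_lfp
    ratio = fs_lfp / fs_beh
    n_gap = int(round(cfg.gap_duration * fs_beh))
    n_trial = int(round(cfg.trial_duration * fs_beh))

    segments: list[np.ndarray] = [np.zeros(n_gap)]
    seg_context: list[str | None] = [None]
    trials: list[TrialEpoch] = []
    choice_rng = np.random.default_rng(choice_seed)
    p_ok = cfg.p_correct(condition)

    cursor = n_gap
    k = 0
    for _ in range(n_pairs):
        choice = "correct" if choice_rng.uniform() < p_ok else "incorrect"
        for context in contexts:
            sp = gen_speed(context, condition, cfg.trial_duration, cfg, speed_seeds[k])
            k += 1
            segments.append(sp)
            seg_context.append(context)
            t0, t1 = cursor / fs_beh, (cursor + n_trial) / fs_beh
            trials.append(TrialEpoch(t0, t1, context, choice, condition))
            cursor += n_trial
            segments.append(np.zeros(n_gap))
            seg_context.append(None)
            cursor += n_gap

    speed = np.concatenate(segments) if segments else np.zeros(0)
    # per-LFP-sample slow-component scale: maze_slow_scale inside maze trials
    scale_beh = np.concatenate(
        [
            np.full(len(seg), cfg.maze_slow_scale if ctx == "maze" else 1.0)
            for seg, ctx in zip(segments, seg_context)
        ]
    )
    # frequency-coupling reference: the context's configured mean speed
    speed_fac = cfg.muscimol_speed_scale if condition == "post" else 1.0
    ref_beh = np.concatenate(
        [
            np.full(len(seg), cfg.speed_mean(ctx or "wheel") * speed_fac)
            for seg, ctx in zip(segments, seg_context)
        ]
    )
    n_lfp = int(round(len(speed) * ratio))
    idx_beh = np.minimum((np.arange(n_lfp) / ratio).astype(int), len(speed) - 1)
    slow_scale = scale_beh[idx_beh]
    speed_ref = ref_beh[idx_beh]

    lfp, truth = gen_lfp(
        speed, cfg, condition, lfp_seed, slow_scale=slow_scale, speed_ref=speed_ref
    )

    neurons: list[NeuronRecord] = []
    for i in range(cfg.n_interneurons):
        st = gen_spikes(truth, cfg, "interneuron", condition, neuron_seeds[i])
        neurons.append(NeuronRecord(f"int{i:02d}", "interneuron", st))
    for j in range(cfg.n_pyramidal):
        st = gen_spikes(
            truth, cfg, "pyramidal", condition, neuron_seeds[cfg.n_interneurons + j]
        )
        neurons.append(NeuronRecord(f"pyr{j:02d}", "pyramidal", st))

    return SessionRecording(
        lfp=lfp,
        fs_lfp=fs_lfp,
        speed=speed,
        fs_beh=fs_beh,
        neurons=neurons,
        trials=trials,
        condition=condition,
        ground_truth=truth,
    )
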