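"""Generative parameterization of a synthetic recording session.

``SynthConfig`` holds every knob of the generator: the two oscillators
(center frequency, baseline amplitude, amplitude- and frequency-speed
coupling), the Ornstein–Uhlenbeck speed process per context, the 1/f
background noise, the phase-locked spiking populations, and the multipliers
that realize the post-muscimol condition (theta abolished, slightly slower
rhythms, lower speed, weaker entrainment, reduced interneuron rates).

Defaults are chosen to emulate the study conditions: wheel runs of ~15 s at
~60 cm/s with a speed-coupled slow oscillator plus theta over pink noise;
maze runs at lower speed with theta only; post-muscimol theta scale 0,
frequency factor 0.93 and correct-choice rates 0.94 (pre) / 0.60 (post).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from .errors import InvalidArgumentError

CONDITIONS = ("pre", "post")
CONTEXTS = ("maze", "wheel")


@dataclass
class SynthConfig:
    # sampling
    fs_lfp: float = 1250.0  # Hz
    fs_beh: float = 50.0  # Hz, speed trace

    # session structure
    n_trials_per_context: int = 20
    trial_duration: float = 15.0  # s, wheel runs last ~15 s
    gap_duration: float = 2.0  # s between trials (speed ~0, below the gate)

    # oscillators
    f_slow: float = 4.0  # Hz
    f_theta: float = 8.0  # Hz
    a_slow0: float = 20.0  # µV baseline amplitude at zero speed
    a_theta0: float = 40.0  # µV
    g_slow_speed: float = 0.8  # µV per cm/s, amplitude-speed gain (positive)
    g_theta_speed: float = 0.0  # µV per cm/s (theta decoupled by default)
    h_slow_speed: float = 0.01  # Hz per cm/s, frequency-speed gain
    h_theta_speed: float = 0.02  # Hz per cm/s
    maze_slow_scale: float = 0.0  # slow-component amplitude multiplier in maze

    # speed process (Ornstein-Uhlenbeck, reflected at 0)
    speed_mean_wheel: float = 60.0  # cm/s
    speed_mean_maze: float = 40.0  # cm/s
    speed_sd: float = 10.0  # cm/s
    speed_tau: float = 2.0  # s
    maze_stop_rate: float = 2.0  # mean number of stops per maze trial
    maze_stop_duration: float = 1.5  # s

    # background noise
    noise_exponent: float = 1.0  # 1/f^beta spectral slope
    noise_scale: float = 15.0  # µV RMS

    # spiking populations
    n_interneurons: int = 5
    n_pyramidal: int = 10
    base_rate_int: float = 15.0  # Hz
    base_rate_pyr: float = 3.0  # Hz
    kappa_slow_int: float = 2.0  # von Mises concentration, slow rhythm
    kappa_slow_pyr: float = 1.0
    kappa_theta_int: float = 1.5
    kappa_theta_pyr: float = 0.8
    mu_slow: float = 0.0  # preferred phase (rad)
    mu_theta: float = 0.0

    # post-muscimol transform
    muscimol_theta_scale: float = 0.0  # multiplier on a_theta0 (theta abolished)
    muscimol_speed_scale: float = 0.7
    muscimol_rate_scale_int: float = 0.6
    muscimol_kappa_scale: float = 0.5
    muscimol_freq_scale: float = 0.93  # both rhythms slightly slower post

    # choice labels
    p_correct_pre: float = 0.94
    p_correct_post: float = 0.60

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = (
            "fs_lfp fs_beh trial_duration gap_duration a_slow0 a_theta0 "
            "speed_mean_wheel speed_mean_maze speed_sd speed_tau maze_stop_rate "
            "maze_stop_duration noise_scale base_rate_int base_rate_pyr "
            "kappa_slow_int kappa_slow_pyr kappa_theta_int kappa_theta_pyr "
            "muscimol_theta_scale muscimol_speed_scale muscimol_rate_scale_int "
            "muscimol_kappa_scale muscimol_freq_scale maze_slow_scale"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.n_trials_per_context < 0 or self.n_interneurons < 0 or self.n_pyramidal < 0:
            raise InvalidArgumentError("counts must be >= 0")
        if not self.f_slow < self.f_theta:
            raise InvalidArgumentError("f_slow must be < f_theta")
        if not self.fs_lfp > 2.0 * (self.f_theta + 5.0):
            raise InvalidArgumentError("fs_lfp must exceed 2*(f_theta + 5 Hz)")
        for p in (self.p_correct_pre, self.p_correct_post):
            if not 0.0 <= p <= 1.0:
                raise InvalidArgumentError("correct-choice probabilities must be in [0, 1]")

    # ---- condition / cell-type helpers -----------------------------------

    def kappa(self, cell_type: str, band: str) -> float:
        key = {"interneuron": "int", "pyramidal": "pyr"}[cell_type]
        return getattr(self, f"kappa_{band}_{key}")

    def base_rate(self, cell_type: str) -> float:
        return {"interneuron": self.base_rate_int, "pyramidal": self.base_rate_pyr}[cell_type]

    def speed_mean(self, context: str) -> float:
        return {"maze": self.speed_mean_maze, "wheel": self.speed_mean_wheel}[context]

    def p_correct(self, condition: str) -> float:
        return {"pre": self.p_correct_pre, "post": self.p_correct_post}[condition]

    # ---- JSON schema ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynthConfig":
        obj = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


def check_condition(condition: str) -> str:
    if condition not in CONDITIONS:
        raise InvalidArgumentError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    return condition


def check_context(context: str) -> str:
    if context not in CONTEXTS:
        raise InvalidArgumentError(f"context must be one of {CONTEXTS}, got {context!r}")
    return context
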