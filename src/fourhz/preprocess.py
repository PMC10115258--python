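"""LFP cleaning and run-epoch selection.

Three filters, applied in the order the analysis expects: a 55–65 Hz
zero-phase notch against line noise, amplitude-based artifact rejection
(|x − mean| > 2·SD over the whole session, dilated by ±0.25 s to avoid
filter-edge contamination), and a running-speed gate keeping only samples
inside trial epochs where speed exceeds 10 cm/s. Each step produces an
``EpochMask`` whose flags compose commutatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import DegenerateInputError, InvalidArgumentError
from .synth import TrialEpoch

__all__ = ["EpochMask", "notch_filter", "reject_artifacts", "select_run_epochs"]

NOTCH_BAND = (55.0, 65.0)


@dataclass
class EpochMask:
    """Per-LFP-sample keep/exclude flags with provenance.

    ``kept`` is True where the sample is inside a trial epoch and flagged by
    neither the artifact detector nor the speed gate. Masks from different
    stages combine with ``&``: flags OR together, trial membership ANDs.
    """

    n: int
    artifact: np.ndarray = field(default=None)  # type: ignore[assignment]
    slow_speed: np.ndarray = field(default=None)  # type: ignore[assignment]
    in_trial: np.ndarray = field(default=None)  # type: ignore[assignment]
    exceedance: np.ndarray | None = None  # raw per-sample threshold crossings

    def __post_init__(self) -> None:
        if self.artifact is None:
            self.artifact = np.zeros(self.n, dtype=bool)
        if self.slow_speed is None:
            self.slow_speed = np.zeros(self.n, dtype=bool)
        if self.in_trial is None:
            self.in_trial = np.ones(self.n, dtype=bool)
        for arr in (self.artifact, self.slow_speed, self.in_trial):
            if len(arr) != self.n:
                raise InvalidArgumentError("mask flag length mismatch")

    @property
    def kept(self) -> np.ndarray:
        return self.in_trial & ~self.artifact & ~self.slow_speed

    def __and__(self, other: "EpochMask") -> "EpochMask":
        if self.n != other.n:
            raise InvalidArgumentError("cannot combine masks of different length")
        return EpochMask(
            n=self.n,
            artifact=self.artifact | other.artifact,
            slow_speed=self.slow_speed | other.slow_speed,
            in_trial=self.in_trial & other.in_trial,
        )

    def kept_intervals(self, fs: float) -> list[tuple[float, float]]:
        """Contiguous kept runs as (t_start, t_end) seconds."""
        k = self.kept
        if not k.any():
            return []
        edges = np.flatnonzero(np.diff(k.astype(np.int8)))
        bounds = np.concatenate(([0], edges + 1, [self.n]))
        out = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if k[a]:
                out.append((a / fs, b / fs))
        return out


def notch_filter(lfp: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 55–65 Hz band-stop (line-noise removal).

    Forward–backward Butterworth band-stop; pass-band gain below 30 Hz is
    within 1% of unity.
    """
    if fs <= 2 * NOTCH_BAND[1]:
        raise InvalidArgumentError(
            f"sampling rate {fs} Hz too low for a {NOTCH_BAND} Hz stop band"
        )
    sos = signal.butter(4, NOTCH_BAND, btype="bandstop", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(lfp, float))


def reject_artifacts(
    lfp: np.ndarray,
    fs: float,
    sd_mult: float = 2.0,
    dilation_s: float = 0.25,
    gross_mult: float | None = 4.0,
) -> EpochMask:
    """Flag artifact intervals by the 2·SD amplitude rule.

    Samples deviating more than ``sd_mult``·SD from the session mean (SD
    over the whole session) are threshold crossings; crossings are dilated
    by ±``dilation_s`` into candidate intervals so filter transients around
    an artifact are excluded with it. An oscillation-dominated or Gaussian
    signal crosses 2·SD at its crests/tails a few percent of the time
    without any artifact being present, so a candidate interval is kept as
    artifact only if it contains a gross excursion beyond
    ``gross_mult``·SD — a transient the stationary signal statistics do not
    produce. Pass ``gross_mult=None`` to flag every dilated crossing.
    The raw crossings are exposed as ``mask.exceedance``. Callers should
    notch-filter first.
    """
    x = np.asarray(lfp, float)
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("zero-variance LFP: artifact threshold undefined")
    z = np.abs(x - x.mean()) / sd
    exceed = z > sd_mult
    pad = int(round(dilation_s * fs))
    dilated = (
        ndimage.binary_dilation(exceed, structure=np.ones(2 * pad + 1, bool)) if pad else exceed
    )
    if gross_mult is None:
        flagged = dilated
    else:
        labels, n_lbl = ndimage.label(dilated)
        if n_lbl:
            gross_lbls = np.unique(labels[z >= gross_mult])
            gross_lbls = gross_lbls[gross_lbls > 0]
            flagged = np.isin(labels, gross_lbls)
        else:
            flagged = dilated
    return EpochMask(n=len(x), artifact=flagged, exceedance=exceed)


def select_run_epochs(
    speed: np.ndarray,
    fs_beh: float,
    trials: list[TrialEpoch],
    n_lfp: int,
    fs_lfp: float,
    threshold: float = 10.0,
) -> tuple[EpochMask, pd.DataFrame]:
    """Keep LFP samples inside trials where running speed > ``threshold`` cm/s.

    The gate is evaluated on the behavioral clock then up-sampled to the LFP
    clock with zero-order hold. Returns the mask and a per-trial summary of
    kept duration. An empty trial list yields an all-excluded mask.
    """
    speed = np.asarray(speed, float)
    fast_beh = speed > threshold
    idx = np.minimum((np.arange(n_lfp) * fs_beh / fs_lfp).astype(int), max(len(speed) - 1, 0))
    fast_lfp = fast_beh[idx] if len(speed) else np.zeros(n_lfp, bool)

    in_trial = np.zeros(n_lfp, dtype=bool)
    rows = []
    for i, tr in enumerate(trials):
        a = int(round(tr.t_start * fs_lfp))
        b = min(int(round(tr.t_end * fs_lfp)), n_lfp)
        in_trial[a:b] = True
        kept = fast_lfp[a:b].sum() / fs_lfp
        rows.append(
            {
                "trial_id": i,
                "context": tr.context,
                "condition": tr.condition,
                "choice": tr.choice,
                "duration_s": tr.duration,
                "kept_s": kept,
            }
        )
    summary = pd.DataFrame(
        rows, columns=["trial_id", "context", "condition", "choice", "duration_s", "kept_s"]
    )
    mask = EpochMask(n=n_lfp, slow_speed=~fast_lfp, in_trial=in_trial)
    return mask, summary
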