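"""Frequency-band definitions and per-band analysis parameters.

The two rhythms under study are the slow "4-Hz" oscillation that appears
during stationary (wheel) running and the classical locomotor theta rhythm.
Each band carries, besides its LFP filter edges, the parameters used by the
spike analyses: the spike-PSD band (spike rhythmicity peaks slightly above
the LFP band), the autocorrelogram lag window in which band peaks are read
out, and the band edge used by the power index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidArgumentError

ACG_MAX_LAG_MS = 500.0


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with its analysis parameters.

    Parameters
    ----------
    name : str
        Band label, e.g. ``"4hz"`` or ``"theta"``.
    lfp_band : tuple of float
        (lo, hi) LFP filter edges in Hz.
    spike_band : tuple of float
        (lo, hi) Hz band used for spike-PSD peak / power-index readout.
    acg_lag_window : tuple of float
        (lo, hi) ms positive-lag window for ACG peak features.
    index_edge : float
        Frequency (Hz) whose relative-PSD value is subtracted in the power
        index.
    """

    name: str
    lfp_band: tuple[float, float]
    spike_band: tuple[float, float]
    acg_lag_window: tuple[float, float]
    index_edge: float

    def __post_init__(self) -> None:
        for lo, hi in (self.lfp_band, self.spike_band, self.acg_lag_window):
            if not lo < hi:
                raise InvalidArgumentError(
                    f"band {self.name!r}: interval ({lo}, {hi}) must be increasing"
                )
        if self.acg_lag_window[1] > ACG_MAX_LAG_MS:
            raise InvalidArgumentError(
                f"band {self.name!r}: ACG lag window exceeds ±{ACG_MAX_LAG_MS} ms support"
            )


FOUR_HZ = BandSpec(
    name="4hz",
    lfp_band=(3.0, 5.0),
    spike_band=(4.0, 6.0),
    acg_lag_window=(200.0, 300.0),
    index_edge=6.0,
)

THETA = BandSpec(
    name="theta",
    lfp_band=(6.0, 10.0),
    spike_band=(8.0, 15.0),
    acg_lag_window=(100.0, 200.0),
    index_edge=15.0,
)

DEFAULT_BANDS: tuple[BandSpec, BandSpec] = (FOUR_HZ, THETA)


def bands_from_json(obj: list[dict]) -> list[BandSpec]:
    """Build a list of BandSpec from a JSON-decoded list of dicts."""
    out = []
    for d in obj:
        out.append(
            BandSpec(
                name=d["name"],
                lfp_band=tuple(d["lfp_band"]),
                spike_band=tuple(d["spike_band"]),
                acg_lag_window=tuple(d["acg_lag_window"]),
                index_edge=float(d["index_edge"]),
            )
        )
    return out
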