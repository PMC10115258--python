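"""HDF5 session container.

Layout (schema 1.0):

* ``/lfp/samples`` (float64, attrs ``fs`` Hz, ``units`` = "uV")
* ``/behavior/speed`` (float64, attrs ``fs`` Hz, ``units`` = "cm/s")
* ``/spikes/<id>/times`` (float64 s, attr ``cell_type``)
* ``/trials/{t_start,t_end,context,choice,condition}`` (parallel arrays)
* ``/meta`` attrs: ``schema_version``, ``condition``; optional
  ``/ground_truth`` group with the generator config (JSON attr) and
  realized per-sample component amplitudes/phases.

Numeric arrays round-trip bit-exactly. Unknown groups are preserved on
read (exposed via the returned extras dict) so future schema minors can
add data without breaking old readers: a minor-version mismatch warns, a
major mismatch raises ``SchemaError`` with a migration hint.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np

from .config import SynthConfig
from .errors import SchemaError
from .synth import GroundTruth, NeuronRecord, SessionRecording, TrialEpoch

__all__ = ["SCHEMA_VERSION", "write_session", "read_session", "DryadAdapter"]

SCHEMA_VERSION = "1.0"
_CORE_GROUPS = ("lfp", "behavior", "trials", "meta")

_str_dt = h5py.string_dtype(encoding="utf-8")


def write_session(session: SessionRecording, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        g = f.create_group("lfp")
        d = g.create_dataset("samples", data=np.asarray(session.lfp, np.float64))
        d.attrs["fs"] = float(session.fs_lfp)
        d.attrs["units"] = "uV"
        g = f.create_group("behavior")
        d = g.create_dataset("speed", data=np.asarray(session.speed, np.float64))
        d.attrs["fs"] = float(session.fs_beh)
        d.attrs["units"] = "cm/s"
        g = f.create_group("spikes")
        for nr in session.neurons:
            ng = g.create_group(nr.id)
            ng.create_dataset("times", data=np.asarray(nr.spike_times, np.float64))
            ng.attrs["cell_type"] = nr.cell_type
        g = f.create_group("trials")
        g.create_dataset("t_start", data=np.array([t.t_start for t in session.trials]))
        g.create_dataset("t_end", data=np.array([t.t_end for t in session.trials]))
        g.create_dataset("context", data=[t.context for t in session.trials], dtype=_str_dt)
        g.create_dataset("choice", data=[t.choice for t in session.trials], dtype=_str_dt)
        g.create_dataset("condition", data=[t.condition for t in session.trials], dtype=_str_dt)
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["condition"] = session.condition
        if session.ground_truth is not None:
            gt = session.ground_truth
            gg = f.create_group("ground_truth")
            gg.attrs["config_json"] = gt.config.to_json()
            for name in ("amp_slow", "amp_theta", "phase_slow", "phase_theta"):
                gg.create_dataset(name, data=np.asarray(getattr(gt, name), np.float64))
            if gt.slow_scale is not None:
                gg.create_dataset("slow_scale", data=np.asarray(gt.slow_scale, np.float64))
    return path


def _check_schema(f: h5py.File, path: Path) -> None:
    for grp in ("lfp", "behavior", "meta"):
        if grp not in f:
            raise SchemaError(f"{path}: missing required group /{grp}")
    version = f["meta"].attrs.get("schema_version")
    if version is None:
        raise SchemaError(f"{path}: no schema_version in /meta")
    major, _, minor = str(version).partition(".")
    want_major = SCHEMA_VERSION.partition(".")[0]
    if major != want_major:
        raise SchemaError(
            f"{path}: schema {version} incompatible with reader {SCHEMA_VERSION}; "
            f"re-export the session with a matching writer or migrate the container"
        )
    if str(version) != SCHEMA_VERSION:
        warnings.warn(
            f"{path}: schema {version} read by {SCHEMA_VERSION} reader; "
            "unknown groups are preserved",
            stacklevel=3,
        )


def read_session(path: str | Path) -> tuple[SessionRecording, dict]:
    """Read a session container; returns (session, extras).

    ``extras`` maps the names of any non-core top-level groups to the
    h5py-free copies of their datasets, so forward-compatible additions
    survive a read-write cycle.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        lfp_ds = f["lfp/samples"]
        lfp = lfp_ds[()]
        fs_lfp = float(lfp_ds.attrs["fs"])
        sp_ds = f["behavior/speed"]
        speed = sp_ds[()]
        fs_beh = float(sp_ds.attrs["fs"])
        neurons = []
        if "spikes" in f:
            for nid in sorted(f["spikes"]):
                ng = f["spikes"][nid]
                neurons.append(
                    NeuronRecord(nid, str(ng.attrs["cell_type"]), ng["times"][()])
                )
        trials = []
        if "trials" in f and "t_start" in f["trials"]:
            g = f["trials"]
            for i in range(len(g["t_start"])):
                trials.append(
                    TrialEpoch(
                        float(g["t_start"][i]),
                        float(g["t_end"][i]),
                        g["context"][i].decode(),
                        g["choice"][i].decode(),
                        g["condition"][i].decode(),
                    )
                )
        condition = str(f["meta"].attrs["condition"])
        truth = None
        if "ground_truth" in f:
            gg = f["ground_truth"]
            truth = GroundTruth(
                config=SynthConfig.from_json(str(gg.attrs["config_json"])),
                amp_slow=gg["amp_slow"][()],
                amp_theta=gg["amp_theta"][()],
                phase_slow=gg["phase_slow"][()],
                phase_theta=gg["phase_theta"][()],
                slow_scale=gg["slow_scale"][()] if "slow_scale" in gg else None,
            )
        extras = {}
        for name in f:
            if name not in _CORE_GROUPS + ("spikes", "ground_truth"):
                extras[name] = {k: f[name][k][()] for k in f[name]}
    session = SessionRecording(
        lfp=lfp,
        fs_lfp=fs_lfp,
        speed=speed,
        fs_beh=fs_beh,
        neurons=neurons,
        trials=trials,
        condition=condition,
        ground_truth=truth,
    )
    return session, extras


class DryadAdapter:
    """Stub interface mapping an external deposit into SessionRecordings.

    Loading the original public deposit is out of scope for this package;
    this adapter documents the contract a loader must satisfy so real data
    can be plugged into the analysis modules without touching them: it
    must yield ``SessionRecording`` objects with LFP in µV at a known rate,
    speed in cm/s, labeled spike trains, and labeled trial epochs.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)

    def sessions(self):  # pragma: no cover - stub
        raise NotImplementedError(
            "implement a mapping from the deposit's files to SessionRecording; "
            "see this class's docstring for the required fields"
        )
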