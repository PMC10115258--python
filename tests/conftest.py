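import numpy as np
import pytest

from fourhz import (
    EpochMask,
    SynthConfig,
    notch_filter,
    reject_artifacts,
    select_run_epochs,
    gen_session,
)

FS = 1250.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230425)


@pytest.fixture
def tiny_cfg():
    """A fast-to-simulate session configuration."""
    return SynthConfig(n_trials_per_context=2, n_interneurons=1, n_pyramidal=2)


def preprocessed(session):
    """Standard preprocessing chain; returns (filtered lfp, combined mask)."""
    lfpf = notch_filter(session.lfp, session.fs_lfp)
    mask = reject_artifacts(lfpf, session.fs_lfp) & select_run_epochs(
        session.speed, session.fs_beh, session.trials, len(session.lfp), session.fs_lfp
    )[0]
    return lfpf, mask


def kept_epochs(mask, fs, min_s=0.5):
    intervals = EpochMask(n=mask.n, in_trial=mask.kept).kept_intervals(fs)
    return [(a, b) for a, b in intervals if b - a > min_s]


@pytest.fixture(scope="session")
def wheel_session():
    """A moderately sized wheel-only pre session shared across tests."""
    cfg = SynthConfig(n_trials_per_context=10, n_interneurons=2, n_pyramidal=2)
    return gen_session(cfg, "pre", 424242, contexts=("wheel",))
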