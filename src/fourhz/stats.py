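"""Binned correlations, speed matching, and hypothesis-testing conventions.

Instantaneous band metrics are averaged in non-overlapping per-trial bins
(5 s by default, 1 s supported) and correlated with speed using Spearman's
rank coefficient. Group contrasts follow the normality-gated convention:
Shapiro–Wilk on both groups, then a t-test if both pass, otherwise the
Wilcoxon signed-rank (paired) or rank-sum (unpaired) test at α = 0.05,
without multiple-testing correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidArgumentError
from .preprocess import EpochMask
from .spectral import InstantaneousMetrics
from .synth import TrialEpoch

__all__ = [
    "CorrelationResult",
    "ComparisonResult",
    "bin_metrics",
    "spearman",
    "speed_matched_subsets",
    "compare",
]

ALPHA = 0.05
EXACT_PERMUTATION_N = 10
BIN_COMPLETENESS = 0.8


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    pair: str = ""
    stratum: str = ""
    method: str = "t-approximation"


@dataclass
class ComparisonResult:
    statistic: float
    p: float
    test: str  # paired-t | unpaired-t | signed-rank | rank-sum
    n_a: int
    n_b: int
    normal_a: bool
    normal_b: bool


def bin_metrics(
    metrics: dict[str, InstantaneousMetrics],
    speed: np.ndarray,
    fs_beh: float,
    mask: EpochMask,
    trials: list[TrialEpoch],
    bin_s: float = 5.0,
) -> pd.DataFrame:
    """Per-trial, non-overlapping bin means of speed and band metrics.

    Bins are anchored at each trial's start; a bin is dropped unless at
    least 80% of its LFP samples are kept by the mask. Bin means of
    amplitude and frequency are taken over kept samples only.
    """
    if bin_s not in (1.0, 5.0):
        # other widths work fine; the analyses use 1 or 5 s
        pass
    fs_lfp = next(iter(metrics.values())).fs if metrics else None
    if fs_lfp is None:
        raise InvalidArgumentError("metrics dict must not be empty")
    kept = mask.kept
    speed = np.asarray(speed, float)
    rows = []
    nbin_lfp = int(round(bin_s * fs_lfp))
    for ti, tr in enumerate(trials):
        start = int(round(tr.t_start * fs_lfp))
        stop = min(int(round(tr.t_end * fs_lfp)), mask.n)
        for b0 in range(start, stop - nbin_lfp + 1, nbin_lfp):
            b1 = b0 + nbin_lfp
            k = kept[b0:b1]
            if k.mean() < BIN_COMPLETENESS:
                continue
            s0, s1 = int(b0 / fs_lfp * fs_beh), int(b1 / fs_lfp * fs_beh)
            row = {
                "bin_start_s": b0 / fs_lfp,
                "trial_id": ti,
                "context": tr.context,
                "condition": tr.condition,
                "choice": tr.choice,
                "speed": float(speed[s0:s1].mean()) if s1 > s0 else float("nan"),
            }
            for name, m in metrics.items():
                row[f"amp_{name}"] = float(m.amplitude[b0:b1][k].mean())
                row[f"freq_{name}"] = float(m.frequency[b0:b1][k].mean())
            rows.append(row)
    return pd.DataFrame(rows)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 10), tie-safe."""
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    count = 0
    total = math.factorial(n)
    batch: list[tuple[int, ...]] = []
    thresh = abs(rho_obs) - 1e-12
    perms = itertools.permutations(range(n))
    while True:
        batch = list(itertools.islice(perms, 200_000))
        if not batch:
            break
        P = np.asarray(batch)
        rhos = (ry[P] * rx).mean(axis=1)
        count += int((np.abs(rhos) >= thresh).sum())
        del P, rhos
    return count / total


def spearman(x: np.ndarray, y: np.ndarray, pair: str = "", stratum: str = "") -> CorrelationResult:
    """Spearman rank correlation with mid-rank ties.

    p comes from the t approximation; for n ≤ 10 the exact permutation
    distribution is enumerated instead.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise InvalidArgumentError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need at least 3 finite pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateCorrelationError("zero-variance input: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_N:
        p = _exact_spearman_p(rx, ry, rho)
        method = "exact-permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2 * sps.t.sf(abs(t), df=n - 2))
        method = "t-approximation"
    return CorrelationResult(rho=rho, p=p, n=n, pair=pair, stratum=stratum, method=method)


class DegenerateCorrelationError(InvalidArgumentError):
    """Raised when either variable has zero variance."""


def speed_matched_subsets(
    trial_speeds: pd.DataFrame,
    lo: float = 55.0,
    hi: float = 63.0,
) -> tuple[pd.DataFrame, pd.DataFrame, ComparisonResult | None]:
    """Select wheel trials with mean speed in [lo, hi] cm/s per condition.

    ``trial_speeds`` needs columns trial_id, context, condition,
    mean_speed. Returns (pre subset, post subset) and a rank-sum check
    that the matched speed distributions no longer differ (None if either
    subset is empty).
    """
    df = trial_speeds[(trial_speeds["context"] == "wheel")]
    sub = df[(df["mean_speed"] >= lo) & (df["mean_speed"] <= hi)]
    pre = sub[sub["condition"] == "pre"].reset_index(drop=True)
    post = sub[sub["condition"] == "post"].reset_index(drop=True)
    check = None
    if len(pre) and len(post):
        stat = sps.mannwhitneyu(pre["mean_speed"], post["mean_speed"], alternative="two-sided")
        check = ComparisonResult(
            statistic=float(stat.statistic),
            p=float(stat.pvalue),
            test="rank-sum",
            n_a=len(pre),
            n_b=len(post),
            normal_a=False,
            normal_b=False,
        )
    return pre, post, check


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False  # Shapiro-Wilk undefined for constant samples
    return sps.shapiro(x).pvalue > ALPHA


def compare(a: np.ndarray, b: np.ndarray, paired: bool = False) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Shapiro–Wilk on each group; both normal → (paired) t-test, otherwise
    Wilcoxon signed-rank (paired) or rank-sum (unpaired). Identical paired
    groups return p = 1 (the signed-rank statistic degenerates when all
    differences are zero).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("need at least 3 observations per group")
    if paired and len(a) != len(b):
        raise InvalidArgumentError("paired comparison requires equal lengths")
    na, nb = _is_normal(a), _is_normal(b)
    if na and nb:
        if paired:
            res = sps.ttest_rel(a, b)
            test = "paired-t"
        else:
            res = sps.ttest_ind(a, b)
            test = "unpaired-t"
        stat, p = float(res.statistic), float(res.pvalue)
        if math.isnan(p):  # zero-variance difference
            stat, p = 0.0, 1.0
    elif paired:
        d = a - b
        if np.all(d == 0):
            stat, p = 0.0, 1.0
        else:
            res = sps.wilcoxon(a, b, zero_method="wilcox")
            stat, p = float(res.statistic), float(res.pvalue)
        test = "signed-rank"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        test = "rank-sum"
    return ComparisonResult(
        statistic=stat, p=p, test=test, n_a=len(a), n_b=len(b), normal_a=na, normal_b=nb
    )
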