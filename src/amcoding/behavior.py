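"""Behavioral psychometrics for the AM-detection licking task.

Animals report the UM->SAM transition by licking; AM trials yield hits and
lick latencies, catch trials (no transition) yield the false-alarm rate.
Hit and false-alarm rates are clipped to [0.5/N, 1 - 0.5/N] before any d'
conversion to avoid infinities.  Sensitivity per depth is computed from the
latency distributions by ROC analysis (shorter latency = stronger evidence,
no-response trials at the ceiling), converted to d', and the detection
threshold interpolated where d' crosses 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import amcode

__all__ = ["PsychometricResult", "compute_rates", "latency_roc_dprime", "rate_dprime"]


@dataclass
class PsychometricResult:
    """Per-(fmod x intensity x condition) psychometrics of one subject."""

    fmod: float
    intensity: float
    condition: str
    depths: np.ndarray
    depths_db: np.ndarray
    hit_rate: np.ndarray          # clipped
    fa_rate: float                # clipped
    median_latency: np.ndarray
    dprime: np.ndarray            # latency-ROC d' per depth
    threshold: amcode.ThresholdResult
    n_trials: np.ndarray
    n_catch: int

    @property
    def threshold_db(self) -> float:
        return self.threshold.threshold_db


def _clip_rate(k: int, n: int) -> float:
    """Observed proportion clipped to [0.5/N, 1 - 0.5/N]."""
    return float(np.clip(k / n, 0.5 / n, 1.0 - 0.5 / n))


def compute_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Clipped hit/false-alarm rates per stimulus cell.

    ``trials`` must carry columns fmod, depth, intensity, condition, catch,
    response (bool).  Returns a tidy table with one row per
    (condition x intensity x fmod x depth) cell plus one catch row per
    (condition x intensity); empty cells are absent rather than zero.
    """
    rows = []
    am = trials[~trials.catch]
    for (cond, inten, f, d), sub in am.groupby(["condition", "intensity", "fmod", "depth"]):
        n = len(sub)
        rows.append(
            dict(
                condition=cond, intensity=inten, fmod=f, depth=d,
                n_trials=n, rate=_clip_rate(int(sub.response.sum()), n), kind="hit",
            )
        )
    for (cond, inten), sub in trials[trials.catch].groupby(["condition", "intensity"]):
        n = len(sub)
        rows.append(
            dict(
                condition=cond, intensity=inten, fmod=np.nan, depth=0.0,
                n_trials=n, rate=_clip_rate(int(sub.response.sum()), n), kind="fa",
            )
        )
    return pd.DataFrame(rows)


def rate_dprime(hit_rate: float, fa_rate: float) -> float:
    """Yes/no sensitivity Phi^-1(HR) - Phi^-1(FA) from clipped rates."""
    from scipy.stats import norm

    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def latency_roc_dprime(
    trials: pd.DataFrame,
    fmod: float,
    intensity: float,
    condition: str = "baseline",
    convention: str = "sqrt2",
    ceiling: float = 2.0,
) -> PsychometricResult:
    """Latency-based ROC d' and threshold for one stimulus block.

    Per depth, the AM-trial latency distribution is compared with the
    catch-trial one; evidence is the negated latency with no-response trials
    assigned the common ceiling (worst rank, ties counted one half).  The
    threshold is interpolated at d' = 1 over depths in dB re full
    modulation.
    """
    sel = (trials.condition == condition) & (trials.intensity == intensity)
    catch = trials[sel & trials.catch]
    if catch.empty:
        raise ValueError("catch trials are required for the latency ROC")
    am = trials[sel & ~trials.catch & (trials.fmod == fmod)]

    def evidence(sub):
        lat = sub.latency.to_numpy(dtype=float)
        resp = sub.response.to_numpy(dtype=bool)
        lat = np.where(resp & np.isfinite(lat), lat, ceiling)
        return -lat

    null = evidence(catch)
    depths = np.array(sorted(am.depth.unique()))
    hit_rate, med_lat, dps, ns = [], [], [], []
    for d in depths:
        sub = am[am.depth == d]
        n = len(sub)
        sig = evidence(sub)
        a = amcode.roc_auc(sig, null)
        a = amcode._clip_auc(a, sig.size * null.size)
        dps.append(amcode.dprime_from_auc(a, convention=convention))
        hit_rate.append(_clip_rate(int(sub.response.sum()), n))
        lat_hits = sub.latency.to_numpy(dtype=float)
        lat_hits = lat_hits[np.isfinite(lat_hits)]
        med_lat.append(float(np.median(lat_hits)) if lat_hits.size else np.nan)
        ns.append(n)
    depths_db = amcode.depth_to_db(depths)
    thr = amcode._threshold_or_undefined(depths_db, np.array(dps))
    return PsychometricResult(
        fmod=fmod,
        intensity=intensity,
        condition=condition,
        depths=depths,
        depths_db=depths_db,
        hit_rate=np.array(hit_rate),
        fa_rate=_clip_rate(int(catch.response.sum()), len(catch)),
        median_latency=np.array(med_lat),
        dprime=np.array(dps),
        threshold=thr,
        n_trials=np.array(ns),
        n_catch=len(catch),
    )
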