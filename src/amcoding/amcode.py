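"""Temporal and rate coding of SAM noise: VS_PP, ROC -> d', and thresholds.

Temporal coding is quantified by the phase-projected vector strength
(VS_PP): the per-trial resultant length of spike phases, projected onto the
global mean phase by ``cos(theta_t - theta_c)``.  Unlike classic vector
strength, VS_PP penalizes trials that lock at the wrong phase and tolerates
low spike counts (zero-spike trials contribute 0 rather than being dropped).

Per-trial metric values at each nonzero modulation depth are compared with
the unmodulated (depth 0) distribution by ROC analysis; the area under the
curve is converted to a sensitivity index d' = |sqrt(2) * Phi^-1(AUC)|, and
the AM detection threshold is the interpolated depth (in dB re full
modulation) where d' crosses 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "SpikeTrain",
    "SensitivityCurve",
    "ThresholdResult",
    "vector_strength",
    "vs_pp",
    "roc_auc",
    "dprime_from_auc",
    "sensitivity_curve",
    "modulation_threshold",
    "depth_to_db",
]


@dataclass
class SpikeTrain:
    """Spike times of one unit on one trial, with stimulus metadata.

    Times are in seconds from trial onset; ``transition_time`` marks the
    UM -> AM switch.
    """

    spike_times: np.ndarray
    fmod: float
    depth: float
    intensity: float
    condition: str = "baseline"
    transition_time: float = 1.0
    duration: float = 2.0
    unit_id: str = "u0"
    trial_index: int = 0


@dataclass
class ThresholdResult:
    threshold_db: float          # NaN when undefined
    censored: bool = False       # True when the curve starts above 1 (floor)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.threshold_db)


@dataclass
class SensitivityCurve:
    """d' versus modulation depth for one unit x stimulus block."""

    depths: np.ndarray                 # nonzero depths, ascending
    depths_db: np.ndarray              # 20*log10(depth)
    metric_per_trial: dict             # depth (incl. 0) -> per-trial metric values
    dprime: np.ndarray                 # per nonzero depth
    auc: np.ndarray
    threshold: ThresholdResult = field(default_factory=lambda: ThresholdResult(np.nan))
    coding: str = "temporal"           # {"temporal", "rate"}
    fmod: float = np.nan
    intensity: float = np.nan
    condition: str = "baseline"

    @property
    def threshold_db(self) -> float:
        return self.threshold.threshold_db

    def to_frame(self, unit_id: str = "u0"):
        import pandas as pd

        return pd.DataFrame(
            {
                "unit": unit_id,
                "condition": self.condition,
                "fmod": self.fmod,
                "intensity": self.intensity,
                "coding": self.coding,
                "depth_db": self.depths_db,
                "dprime": self.dprime,
                "threshold_db": self.threshold.threshold_db,
            }
        )


def depth_to_db(m) -> np.ndarray:
    """Modulation depth -> dB re full modulation (20*log10 m)."""
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(np.asarray(m, dtype=float))


def vector_strength(phases: np.ndarray):
    """Classic vector strength and mean phase of a set of spike phases.

    vs = |sum exp(i*theta)| / n, mean_phase = arg(sum exp(i*theta)).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("vector_strength requires at least one phase")
    z = np.exp(1j * phases).sum()
    return float(np.abs(z)) / phases.size, float(np.angle(z))


def vs_pp(trials, fmod: float, window: tuple):
    """Phase-projected vector strength over an analysis window.

    Spike times inside ``window`` are mapped to modulation phases
    ``2*pi*fmod*t mod 2*pi``.  The global mean phase ``theta_c`` is taken
    from all spikes pooled across trials; each trial contributes
    ``VS_t * cos(theta_t - theta_c)``, with zero-spike trials contributing 0.

    Parameters
    ----------
    trials : sequence of SpikeTrain or of spike-time arrays.
    window : (t0, t1) seconds; by default callers use the last 500 ms of the
        AM segment to eliminate onset effects.

    Returns
    -------
    (per-trial VS_PP array, mean over trials)
    """
    t0, t1 = window
    spike_sets = []
    for tr in trials:
        st = tr.spike_times if hasattr(tr, "spike_times") else np.asarray(tr, dtype=float)
        st = np.asarray(st, dtype=float)
        spike_sets.append(st[(st >= t0) & (st < t1)])
    pooled = np.concatenate(spike_sets) if spike_sets else np.array([])
    if pooled.size == 0:
        return np.zeros(len(spike_sets)), 0.0
    _, theta_c = vector_strength(2.0 * np.pi * fmod * pooled % (2.0 * np.pi))
    out = np.zeros(len(spike_sets))
    for i, st in enumerate(spike_sets):
        if st.size == 0:
            continue
        vs_t, theta_t = vector_strength(2.0 * np.pi * fmod * st % (2.0 * np.pi))
        out[i] = vs_t * np.cos(theta_t - theta_c)
    return out, float(out.mean())


def roc_auc(signal_values, null_values) -> float:
    """Probability that a random signal value exceeds a random null value.

    Ties count one half (average-rank / Mann-Whitney formulation); equals the
    area under the empirical ROC curve.
    """
    s = np.asarray(signal_values, dtype=float)
    n = np.asarray(null_values, dtype=float)
    if s.size == 0 or n.size == 0:
        raise ValueError("roc_auc requires non-empty signal and null samples")
    ranks = rankdata(np.concatenate([s, n]))
    r_s = ranks[: s.size].sum()
    u = r_s - s.size * (s.size + 1) / 2.0
    return float(u / (s.size * n.size))


def dprime_from_auc(auc: float, convention: str = "sqrt2") -> float:
    """Sensitivity index from ROC area: d' = |sqrt(2) * Phi^-1(AUC)|.

    ``convention="2"`` uses 2*Phi^-1(AUC) instead.  Symmetric in
    auc <-> 1-auc; infinite at 0 or 1 (callers clip first).
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    k = np.sqrt(2.0) if convention == "sqrt2" else 2.0
    if convention not in ("sqrt2", "2"):
        raise ValueError(f"unknown d' convention {convention!r}")
    return float(np.abs(k * norm.ppf(auc)))


def _clip_auc(auc: float, n_pairs: int) -> float:
    lo = 0.5 / n_pairs
    return float(np.clip(auc, lo, 1.0 - lo))


def firing_rate(train, window: tuple) -> float:
    """Mean firing rate (spk/s) of one trial inside a window."""
    t0, t1 = window
    st = train.spike_times if hasattr(train, "spike_times") else np.asarray(train, dtype=float)
    st = np.asarray(st, dtype=float)
    return float(((st >= t0) & (st < t1)).sum() / (t1 - t0))


def sensitivity_curve(
    trains_by_depth: dict,
    coding: str,
    fmod: float,
    window: tuple,
    convention: str = "sqrt2",
    intensity: float = np.nan,
    condition: str = "baseline",
) -> SensitivityCurve:
    """d' versus modulation depth from trial-wise metrics.

    ``trains_by_depth`` maps modulation depth (including 0, the unmodulated
    null) to a list of SpikeTrain.  For ``coding="temporal"`` the per-trial
    metric is VS_PP; for ``"rate"`` it is the firing rate in ``window``.
    Each nonzero depth's metric distribution is compared with the depth-0
    distribution by ROC; the AUC (clipped away from 0/1 by half a pair) is
    converted to d' and the threshold interpolated at d' = 1.
    """
    if coding not in ("temporal", "rate"):
        raise ValueError(f"unknown coding {coding!r}")
    if 0.0 not in trains_by_depth:
        raise ValueError("depth-0 (unmodulated) trials are required as the ROC null")
    depths = np.array(sorted(d for d in trains_by_depth if d > 0))
    metric = {}
    for d, trains in trains_by_depth.items():
        if coding == "temporal":
            vals, _ = vs_pp(trains, fmod, window)
        else:
            vals = np.array([firing_rate(tr, window) for tr in trains])
        metric[float(d)] = vals
    null = metric[0.0]
    aucs, dps = [], []
    for d in depths:
        sig = metric[float(d)]
        a = roc_auc(sig, null)
        a = _clip_auc(a, sig.size * null.size)
        aucs.append(a)
        dps.append(dprime_from_auc(a, convention=convention))
    depths_db = depth_to_db(depths)
    thr = _threshold_or_undefined(depths_db, np.array(dps))
    return SensitivityCurve(
        depths=depths,
        depths_db=depths_db,
        metric_per_trial=metric,
        dprime=np.array(dps),
        auc=np.array(aucs),
        threshold=thr,
        coding=coding,
        fmod=fmod,
        intensity=intensity,
        condition=condition,
    )


def _threshold_or_undefined(depths_db, dprime) -> ThresholdResult:
    """modulation_threshold, but undefined (not an error) for < 2 depths."""
    if np.asarray(depths_db).size < 2:
        return ThresholdResult(np.nan)
    return modulation_threshold(depths_db, dprime)


def modulation_threshold(depths_db, dprime) -> ThresholdResult:
    """Interpolated modulation depth (dB) at which d' crosses 1.

    Linear interpolation of d' against depth in dB; returns the lowest-depth
    upward crossing.  If the curve starts at exactly 1 the first depth is the
    threshold; if it starts above 1 the first depth is returned flagged as
    censored (the true threshold lies below the tested range); if d' never
    reaches 1 the threshold is undefined (NaN).
    """
    x = np.asarray(depths_db, dtype=float)
    y = np.asarray(dprime, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two depths")
    if np.any(np.diff(x) <= 0):
        raise ValueError("depths_db must be strictly ascending")
    if y[0] >= 1.0:
        return ThresholdResult(float(x[0]), censored=bool(y[0] > 1.0))
    for i in range(x.size - 1):
        if y[i] < 1.0 <= y[i + 1]:
            frac = (1.0 - y[i]) / (y[i + 1] - y[i])
            return ThresholdResult(float(x[i] + frac * (x[i + 1] - x[i])))
    return ThresholdResult(np.nan)
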