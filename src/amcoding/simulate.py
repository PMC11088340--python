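"""Synthetic spike trains and behavioral sessions with known ground truth.

These generators emulate the statistical structure the analyses assume, so
every downstream stage can be exercised and validated by parameter recovery:

* phase-locked, rate-modulated responses to SAM noise (inhomogeneous
  Poisson with a depth-dependent gain and a phase-locking modulator),
* linear-nonlinear-Poisson (LNP) responses to DRC stimuli with an optional
  planted context gain field,
* behavioral go/no-go sessions with sigmoidal depth-dependent hit rates and
  an inverse depth-latency relation.

Condition multipliers on gain and locking strength emulate pharmacological
manipulations (e.g., a salicylate-like increase of AM sensitivity) without
any claim of biophysical realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amcode import SpikeTrain
from .stimuli import SAMParams, DRCStimulus, scale_intensity

__all__ = [
    "SAMUnitParams",
    "LNPUnitParams",
    "BehaviorModelParams",
    "simulate_sam_unit",
    "simulate_lnp_unit",
    "simulate_behavior_session",
    "simulate_population",
    "behavior_design",
]

logger = logging.getLogger(__name__)


@dataclass
class SAMUnitParams:
    """Generative parameters of one synthetic AM-responsive unit.

    The firing intensity during the AM segment is

        lambda(t) = r_base * g(m) * (1 + tanh(lock_strength*m)
                                       * sin(2*pi*f_mod*(t - t0 - latency) + pref_phase))

    and ``r_base`` before the transition.  The tanh keeps the modulator in
    [0, 1] so lambda stays non-negative at every depth.  ``gain`` may be a
    callable m -> g or a dict of per-depth gains.  ``condition_multipliers``
    maps a condition label to (gain multiplier, lock-strength multiplier).
    """

    r_base: float = 20.0             # spk/s
    gain: object = None              # None -> g(m) = 1 + gain_slope*m
    gain_slope: float = 0.8          # depth-dependence of the rate gain
    lock_strength: float = 2.0       # unitless >= 0
    pref_phase: float = 0.0          # rad
    latency: float = 0.005           # s
    condition_multipliers: dict = field(default_factory=dict)
    unit_id: str = "u0"

    def gain_at(self, m: float) -> float:
        if self.gain is None:
            return 1.0 + self.gain_slope * m
        if callable(self.gain):
            return float(self.gain(m))
        return float(self.gain.get(m, 1.0))

    def effective(self, condition: str):
        g_mult, l_mult = self.condition_multipliers.get(condition, (1.0, 1.0))
        return g_mult, l_mult


@dataclass
class LNPUnitParams:
    """Ground truth of a linear-nonlinear-Poisson DRC responder."""

    true_prf: np.ndarray             # (lags, freq bins)
    true_cgf: np.ndarray | None = None  # (tau bins, phi bins) or None
    c: float = 0.1                   # baseline, spk/bin
    scaling: str = "amp"
    nonlinearity: str = "rectify"    # {"rectify", "exp"}


@dataclass
class BehaviorModelParams:
    """Generative psychometric/chronometric model of one subject."""

    fa_rate: float = 0.1
    lapse: float = 0.05
    threshold_db: float = -12.0      # dB re full modulation
    slope: float = 0.5               # 1/dB (steep, as in rodent AM detection)
    latency_floor: float = 0.25      # s
    latency_scale: float = 0.25      # s
    latency_noise: float = 0.25      # lognormal sigma
    condition_thresholds: dict = field(default_factory=dict)  # condition -> threshold_db

    def threshold_for(self, condition: str) -> float:
        return float(self.condition_thresholds.get(condition, self.threshold_db))


def make_gabor_prf(
    n_lags: int,
    n_freq: int,
    peak_weight: float = 12.0,
    center_freq_bin: float | None = None,
    center_lag: float = 2.5,
    sigma_lag: float = 1.5,
    sigma_freq: float = 2.0,
    inhibition: float = 0.35,
) -> np.ndarray:
    """A plausible excitatory/delayed-inhibitory PRF (difference of
    Gaussians over lag x frequency), strong enough that DRC-driven LNP
    responses pass the signal-power inclusion rule at 10-20 repetitions."""
    if center_freq_bin is None:
        center_freq_bin = n_freq / 2.0
    lg, fq = np.meshgrid(np.arange(n_lags), np.arange(n_freq), indexing="ij")
    exc = np.exp(-((lg - center_lag) ** 2 / (2 * sigma_lag**2) + (fq - center_freq_bin) ** 2 / (2 * sigma_freq**2)))
    inh = np.exp(
        -((lg - center_lag - 3.0) ** 2 / (2 * sigma_lag**2) + (fq - center_freq_bin) ** 2 / (2 * (sigma_freq + 1.0) ** 2))
    )
    return peak_weight * (exc - inhibition * inh)


def make_suppressive_cgf(n_tau: int, n_phi: int, weight: float = -0.25) -> np.ndarray:
    """A context gain field with suppressive weights along the tau = 0 and
    phi = 0 axes (nearby tones at the same time or frequency reduce a
    tone's effect), the combination-sensitive pattern typical of cortical
    and collicular context models."""
    cgf = np.zeros((n_tau, 2 * n_phi + 1))
    cgf[0, :] = weight
    cgf[:, n_phi] = weight
    cgf[0, n_phi] = weight * 1.4
    return cgf


def _inhomogeneous_poisson(rate_fn, t0: float, t1: float, lam_max: float, rng) -> np.ndarray:
    """Exact thinning sampler for an inhomogeneous Poisson process."""
    if lam_max <= 0:
        return np.array([])
    n = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n))
    keep = rng.uniform(0.0, lam_max, size=n) < rate_fn(cand)
    return cand[keep]


def simulate_sam_unit(
    params: SAMUnitParams,
    stimuli,
    n_trials: int,
    seed: int,
    condition: str = "baseline",
) -> list:
    """Simulate SpikeTrains of one unit over a SAM stimulus grid.

    ``stimuli`` is a list of SAMParams (one entry per distinct condition of
    the grid); ``n_trials`` repetitions are drawn for each.  Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    g_mult, l_mult = params.effective(condition)
    trains = []
    for sp in stimuli:
        t0 = sp.um_duration
        t_end = sp.um_duration + sp.am_duration
        # the condition multiplier scales the depth-dependent part of the
        # gain (AM contrast), leaving the unmodulated drive unchanged
        g = 1.0 + (params.gain_at(sp.m) - 1.0) * g_mult
        lock = np.tanh(params.lock_strength * l_mult * sp.m)
        r_am = params.r_base * g

        def rate(t, sp=sp, g=g, lock=lock, r_am=r_am, t0=t0):
            t = np.asarray(t, dtype=float)
            base = np.full(t.shape, params.r_base)
            am = r_am * (
                1.0 + lock * np.sin(2.0 * np.pi * sp.fmod * (t - t0 - params.latency) + params.pref_phase)
            )
            out = np.where(t >= t0, am, base)
            if np.any(out < 0):
                logger.warning("negative rate clipped at 0")
            return np.clip(out, 0.0, None)

        lam_max = max(params.r_base, r_am * (1.0 + lock)) * 1.0000001
        for k in range(n_trials):
            st = _inhomogeneous_poisson(rate, 0.0, t_end, lam_max, rng)
            trains.append(
                SpikeTrain(
                    spike_times=st,
                    fmod=sp.fmod,
                    depth=sp.m,
                    intensity=sp.intensity,
                    condition=condition,
                    transition_time=t0,
                    duration=t_end,
                    unit_id=params.unit_id,
                    trial_index=k,
                )
            )
    return trains


def simulate_lnp_unit(params: LNPUnitParams, drc: DRCStimulus, n_reps: int, seed: int):
    """Poisson spike counts of an LNP unit driven by a DRC.

    The per-bin rate is the context-gain-model prediction on the scaled
    stimulus, rectified at zero, then Poisson-sampled independently per
    repetition.  Returns (counts: reps x time bins, rate: time bins).
    """
    from .strf import context_model_predict

    s = scale_intensity(drc.level_matrix, params.scaling)
    cgf = params.true_cgf
    rate = context_model_predict(s, params.c, params.true_prf, cgf)
    if params.nonlinearity == "rectify":
        rate = np.clip(rate, 0.0, None)
    elif params.nonlinearity == "exp":
        rate = np.exp(np.clip(rate, None, 10.0))
    else:
        raise ValueError(f"unknown nonlinearity {params.nonlinearity!r}")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate, size=(n_reps, rate.size))
    return counts, rate


def behavior_design(
    fmods=(16.0, 512.0),
    depths=(0.06, 0.125, 0.25, 0.5, 1.0),
    intensities=(45.0, 60.0),
    n_per_cell: int = 10,
    catch_fraction: float = 0.25,
    conditions=("baseline",),
) -> pd.DataFrame:
    """Trial grid of a behavioral session, including catch trials."""
    rows = []
    for cond in conditions:
        for f in fmods:
            for i in intensities:
                for m in depths:
                    rows += [dict(fmod=f, depth=m, intensity=i, condition=cond, catch=False)] * n_per_cell
        n_am = sum(1 for r in rows if r["condition"] == cond)
        n_catch = int(round(catch_fraction * n_am / max(1e-9, 1.0 - catch_fraction)))
        rows += [
            dict(fmod=np.nan, depth=0.0, intensity=i, condition=cond, catch=True)
            for i in list(intensities) * (n_catch // len(intensities) + 1)
        ][:n_catch]
    return pd.DataFrame(rows)


def simulate_behavior_session(params: BehaviorModelParams, design: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Simulate lick responses and latencies for a trial design.

    Hit probability on AM trials is
    ``fa + (1 - fa - lapse) * logistic((depth_db - threshold_db) * slope)``;
    latency on hits is ``floor + scale*exp(-(depth_db - threshold_db)*slope)``
    times lognormal noise.  Catch trials lick at the false-alarm rate with
    latencies from the floor distribution.  Returns the design with added
    ``response`` (bool) and ``latency`` (s from transition; NaN for
    no-response) columns.
    """
    if not bool(design["catch"].any()):
        raise ValueError("design must include catch trials")
    rng = np.random.default_rng(seed)
    out = design.copy().reset_index(drop=True)
    n = len(out)
    resp = np.zeros(n, dtype=bool)
    lat = np.full(n, np.nan)
    for i, row in out.iterrows():
        thr = params.threshold_for(row["condition"])
        if row["catch"]:
            p = params.fa_rate
            mean_lat = params.latency_floor + params.latency_scale
        else:
            from scipy.special import expit

            ddb = 20.0 * np.log10(row["depth"])
            x = (ddb - thr) * params.slope
            p = params.fa_rate + (1.0 - params.fa_rate - params.lapse) * expit(x)
            mean_lat = params.latency_floor + params.latency_scale * np.exp(-np.clip(x, -50.0, 50.0))
        if rng.random() < p:
            resp[i] = True
            lat[i] = mean_lat * rng.lognormal(0.0, params.latency_noise)
    out["response"] = resp
    out["latency"] = lat
    return out


def simulate_population(unit_params, stimuli, n_trials: int, seed: int, condition: str = "baseline"):
    """Simulate a population of SAM units on a common design.

    Returns a dict unit_id -> list of SpikeTrain; all units share the same
    stimulus list and trial count (a common design is required downstream
    for population decoding).
    """
    if len(unit_params) < 2:
        raise ValueError("a population needs at least 2 units")
    streams = np.random.SeedSequence(seed).spawn(len(unit_params))
    pop = {}
    for up, ss in zip(unit_params, streams):
        sub = int(ss.generate_state(1)[0] % (2**31))
        pop[up.unit_id] = simulate_sam_unit(up, stimuli, n_trials, sub, condition=condition)
    return pop
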