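"""Population AM decoding: the AM-encoding component and a threshold-crossing
latency model.

The population's trial-averaged PSTHs (bin 1/256 s ~ 3.9 ms) to fully
modulated and unmodulated stimuli are differenced to form a units x time
matrix; the first principal component over the unit dimension is the
"AM-encoding component".  Single-trial kernel spike densities (Gaussian
kernel, sigma = 2 ms) projected onto this component give a one-dimensional
population signal; the time at which it first crosses a detection level
after the UM->AM transition, plus a 100-200 ms non-decision time, is the
simulated response latency.  Simulated latency distributions are compared
with behavioral ones via the RMS difference of their CDFs, and converted to
d' and AM detection thresholds with the same latency-ROC used for behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import amcode
from .fra import compute_ksd

__all__ = [
    "PopulationActivity",
    "DecoderParams",
    "build_population_activity",
    "am_encoding_component",
    "project_trials",
    "simulate_response_latency",
    "fit_decoder_params",
    "decoder_sensitivity",
]

PSTH_BIN = 1.0 / 256.0  # s ("3.9 ms")
KSD_SIGMA = 0.002       # s


@dataclass
class PopulationActivity:
    """Units x time (x trials) firing arrays on a common time base."""

    unit_ids: list
    time: np.ndarray                       # bin centers, s
    psth_by_group: dict                    # (fmod, depth) -> units x time, spk/s
    trial_ksd: np.ndarray                  # units x trials x time, spk/s
    trial_info: list                       # per-trial dicts (fmod, depth, ...)
    bin: float = PSTH_BIN
    ksd_sigma: float = KSD_SIGMA
    transition_time: float = 1.0


@dataclass
class DecoderParams:
    component: np.ndarray                  # unit-space weights, unit norm
    detection_level: float
    non_decision_time: float = 0.150       # s, in [0.100, 0.200]

    def __post_init__(self) -> None:
        self.component = np.asarray(self.component, dtype=float)
        nrm = np.linalg.norm(self.component)
        if nrm > 0:
            self.component = self.component / nrm
        if not 0.100 <= self.non_decision_time <= 0.200:
            raise ValueError("non-decision time must lie in [0.100, 0.200] s")


def build_population_activity(pop: dict, bin_width: float = PSTH_BIN, ksd_sigma: float = KSD_SIGMA) -> PopulationActivity:
    """Convert a dict unit_id -> list of SpikeTrain into binned containers.

    All units must share the same trial design (same ordered stimulus
    labels); trial-averaged PSTHs are computed per (fmod, depth) group and
    single-trial KSDs on the common grid.
    """
    unit_ids = list(pop)
    first = pop[unit_ids[0]]
    info = [dict(fmod=tr.fmod, depth=tr.depth, intensity=tr.intensity, condition=tr.condition) for tr in first]
    for uid in unit_ids[1:]:
        other = [(tr.fmod, tr.depth, tr.intensity) for tr in pop[uid]]
        if other != [(tr.fmod, tr.depth, tr.intensity) for tr in first]:
            raise ValueError("inconsistent trial designs across units")
    duration = first[0].duration
    transition = first[0].transition_time
    grid = np.arange(bin_width / 2.0, duration, bin_width)
    n_units, n_trials = len(unit_ids), len(first)
    ksd = np.zeros((n_units, n_trials, grid.size))
    for ui, uid in enumerate(unit_ids):
        for ti, tr in enumerate(pop[uid]):
            ksd[ui, ti] = compute_ksd(tr.spike_times, ksd_sigma, grid)
    groups: dict = {}
    keys = [(tr.fmod, tr.depth) for tr in first]
    for key in sorted(set(keys)):
        mask = np.array([k == key for k in keys])
        # PSTH via boxcar binning would duplicate work; the mean KSD is an
        # equivalent smoothed PSTH on the same grid
        groups[key] = ksd[:, mask, :].mean(axis=1)
    return PopulationActivity(
        unit_ids=unit_ids,
        time=grid,
        psth_by_group=groups,
        trial_ksd=ksd,
        trial_info=info,
        bin=bin_width,
        ksd_sigma=ksd_sigma,
        transition_time=transition,
    )


def am_encoding_component(pop: PopulationActivity, full_depth: float = 1.0) -> np.ndarray:
    """First principal component of the full-depth minus unmodulated PSTH.

    The difference matrix (units x time) between the PSTH averaged over all
    full-depth stimuli and over all unmodulated stimuli is decomposed by
    PCA over the unit dimension; the leading component is returned with
    unit norm and its sign chosen so the mean projection of the difference
    is positive.  Raises if fewer than 2 units; a near-zero difference
    (e.g., unmodulated-only input) is flagged with a warning.
    """
    if len(pop.unit_ids) < 2:
        raise ValueError("population must contain at least 2 units")
    full = [v for (f, d), v in pop.psth_by_group.items() if d == full_depth]
    um = [v for (f, d), v in pop.psth_by_group.items() if d == 0.0]
    if not full or not um:
        raise ValueError("need both full-depth and unmodulated trials")
    diff = np.mean(full, axis=0) - np.mean(um, axis=0)   # units x time
    if np.linalg.norm(diff) < 1e-12:
        import warnings

        warnings.warn("difference matrix is ~0; AM-encoding component unreliable", stacklevel=2)
    u, sv, _ = np.linalg.svd(diff, full_matrices=False)
    comp = u[:, 0]
    if np.mean(comp @ diff) < 0:
        comp = -comp
    return comp


def project_trials(pop: PopulationActivity, component: np.ndarray) -> np.ndarray:
    """Project single-trial KSDs onto a unit-space component.

    Returns trials x time.  The component may come from a different
    condition's population (e.g., baseline weights applied to drug trials)
    but must match the unit set.
    """
    component = np.asarray(component, dtype=float)
    if component.size != len(pop.unit_ids):
        raise ValueError("component length does not match the unit set")
    return np.einsum("u,utb->tb", component, pop.trial_ksd)


def simulate_response_latency(
    projection: np.ndarray,
    time: np.ndarray,
    params: DecoderParams,
    transition_time: float,
) -> float:
    """First upward crossing of the detection level after the transition,
    plus the non-decision time; NaN when the level is never crossed."""
    after = time >= transition_time
    p = projection[after]
    t = time[after]
    above = p >= params.detection_level
    if not above.any():
        return np.nan
    i = int(np.argmax(above))
    return float(t[i] - transition_time + params.non_decision_time)


def _latency_cdf(latencies: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Empirical CDF on a time grid; no-response (NaN) trials never count."""
    lat = np.asarray(latencies, dtype=float)
    n = lat.size
    if n == 0:
        return np.zeros_like(grid)
    finite = lat[np.isfinite(lat)]
    return np.searchsorted(np.sort(finite), grid, side="right") / n


def fit_decoder_params(
    pop: PopulationActivity,
    component: np.ndarray,
    behavioral: "pd.DataFrame",
    detection_levels: np.ndarray | None = None,
    non_decision_times=(0.100, 0.125, 0.150, 0.175, 0.200),
    cdf_step: float = 0.010,
    cdf_max: float = 1.0,
):
    """Grid-search decoder parameters against behavioral latencies.

    For every (detection level, non-decision time) pair, simulated latencies
    are computed for all trials, grouped by (fmod, depth) as in the
    behavioral table, and compared group-by-group to the behavioral latency
    CDFs on a common 10-ms grid; the goodness is the RMS CDF difference
    averaged over groups.  Returns (best DecoderParams, goodness DataFrame).
    """
    import pandas as pd

    proj = project_trials(pop, component)
    if detection_levels is None:
        peak = np.median(
            [proj[i, pop.time >= pop.transition_time].max() for i in range(proj.shape[0])]
        )
        detection_levels = np.geomspace(0.1 * abs(peak) + 1e-12, 3.0 * abs(peak) + 1e-12, 12)
    grid = np.arange(0.0, cdf_max + cdf_step / 2, cdf_step)

    beh_groups = {}
    for (f, d), sub in behavioral[~behavioral.catch].groupby(["fmod", "depth"]):
        beh_groups[(f, d)] = _latency_cdf(sub.latency.to_numpy(), grid)
    if not beh_groups:
        raise ValueError("behavioral table has no AM trials")

    sim_keys = [(ti["fmod"], ti["depth"]) for ti in pop.trial_info]
    rows = []
    best = None
    for lvl in detection_levels:
        # crossing time is independent of non-decision time: compute once
        p0 = DecoderParams(component=component, detection_level=float(lvl), non_decision_time=0.100)
        cross = np.array(
            [
                simulate_response_latency(proj[i], pop.time, p0, pop.transition_time) - 0.100
                for i in range(proj.shape[0])
            ]
        )
        for ndt in non_decision_times:
            lats = cross + ndt
            rms_all = []
            for key, beh_cdf in beh_groups.items():
                mask = np.array([k == key for k in sim_keys])
                if not mask.any():
                    continue
                sim_cdf = _latency_cdf(lats[mask], grid)
                rms_all.append(np.sqrt(np.mean((sim_cdf - beh_cdf) ** 2)))
            if not rms_all:
                continue
            rms = float(np.mean(rms_all))
            rows.append(dict(detection_level=float(lvl), non_decision_time=float(ndt), rms=rms))
            if best is None or rms < best[0]:
                best = (rms, float(lvl), float(ndt))
    params = DecoderParams(component=component, detection_level=best[1], non_decision_time=best[2])
    return params, pd.DataFrame(rows)


def decoder_sensitivity(
    pop: PopulationActivity,
    params: DecoderParams,
    fmod: float,
    convention: str = "sqrt2",
) -> amcode.SensitivityCurve:
    """Latency-ROC sensitivity of the threshold-crossing decoder.

    Latencies at each nonzero depth are compared with the unmodulated
    (catch analogue) latencies; shorter latency ranks as stronger evidence
    and no-response trials share the worst (ceiling) rank.  AUC -> d' ->
    interpolated threshold as in the single-unit analysis.
    """
    proj = project_trials(pop, params.component)
    lats = np.array(
        [
            simulate_response_latency(proj[i], pop.time, params, pop.transition_time)
            for i in range(proj.shape[0])
        ]
    )
    ceiling = float(pop.time[-1] - pop.transition_time + params.non_decision_time)
    evidence = -np.where(np.isfinite(lats), lats, ceiling)
    keys = [(ti["fmod"], ti["depth"]) for ti in pop.trial_info]
    null = evidence[np.array([k[1] == 0.0 for k in keys])]
    if null.size == 0:
        raise ValueError("unmodulated (catch) simulations are required")
    depths = sorted({k[1] for k in keys if k[0] == fmod and k[1] > 0})
    aucs, dps = [], []
    for d in depths:
        sig = evidence[np.array([k == (fmod, d) for k in keys])]
        a = amcode.roc_auc(sig, null)
        a = amcode._clip_auc(a, sig.size * null.size)
        aucs.append(a)
        dps.append(amcode.dprime_from_auc(a, convention=convention))
    depths = np.array(depths)
    depths_db = amcode.depth_to_db(depths)
    thr = amcode._threshold_or_undefined(depths_db, np.array(dps))
    return amcode.SensitivityCurve(
        depths=depths,
        depths_db=depths_db,
        metric_per_trial={},
        dprime=np.array(dps),
        auc=np.array(aucs),
        threshold=thr,
        coding="decoder",
        fmod=fmod,
    )
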