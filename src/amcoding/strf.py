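"""Receptive-field estimation from dynamic random chord responses.

Two models of the per-bin firing rate ``r(i)`` as a function of the scaled
stimulus ``s(t, f)`` (time bins x frequency bins):

* **simple model** — a linear spectrotemporal receptive field (STRF),

      r(i) = c + sum_{j,k} w_tf[j, k] * s(i - j, k)

  with weights estimated as the posterior mean under a separable
  squared-exponential Gaussian prior over (lag, log-frequency) whose scale,
  length constants and the noise variance are optimized by marginal
  likelihood (evidence) ascent — automatic smoothness determination (ASD).

* **context model** — a multilinear extension in which each tone's effect is
  multiplicatively modulated by its local acoustic context,

      r(i) = c + sum_{j,k} w_tf[j,k] * s(i-j,k)
                 * (1 + sum_{m,n} w_tauphi[m,n] * s(i-j-m, k+n))

  where ``w_tf`` is the principal receptive field (PRF, absolute frequency x
  time lag) and ``w_tauphi`` the context gain field (CGF, relative time
  offset tau x relative frequency offset phi).  The bilinear model is fit by
  alternating exact least squares (ALS): PRF (and baseline) given CGF, then
  CGF given PRF, each under its smoothness regularizer (PRF: the ASD-derived
  prior; CGF: a fixed squared-exponential smoother of bandwidth 0.5 time bin
  and 1/6 octave).

Model quality is the cross-validated predictive power, normalized by the
predictable (signal) power estimated from trial-to-trial variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize

from .stimuli import INPUT_SCALES, scale_intensity

__all__ = [
    "PowerEstimates",
    "STRFModel",
    "PredictionScore",
    "signal_noise_power",
    "include_unit",
    "context_model_predict",
    "fit_strf_asd",
    "fit_context_model",
    "cv_predictive_power",
    "cgf_norm_null",
    "strf_metrics",
    "scaling_comparison",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# signal / noise power
# ---------------------------------------------------------------------------

@dataclass
class PowerEstimates:
    """Decomposition of response power into signal and noise components."""

    signal_power: float      # (spk/bin)^2
    noise_power: float
    mean_total_power: float  # mean over reps of per-rep power
    n_reps: int


def _power(v: np.ndarray) -> float:
    """Averaged squared deviation from the mean over time."""
    v = np.asarray(v, dtype=float)
    return float(np.mean((v - v.mean()) ** 2))


def signal_noise_power(psths: np.ndarray) -> PowerEstimates:
    """Unbiased signal-power estimator from repeated responses.

    With N repetitions of response vectors ``r(n) = mu + eta(n)``,

        signal power:  P_hat(mu) = (N*P(rbar) - <P(r(n))>) / (N - 1)
        noise power:   <P(r(n))> - P_hat(mu)

    so signal + noise equals the mean per-repetition power exactly.
    """
    psths = np.asarray(psths, dtype=float)
    if psths.ndim != 2 or psths.shape[0] < 2:
        raise ValueError("need a (reps x time bins) array with at least 2 reps")
    n = psths.shape[0]
    p_mean = _power(psths.mean(axis=0))
    p_each = float(np.mean([_power(r) for r in psths]))
    signal = (n * p_mean - p_each) / (n - 1)
    return PowerEstimates(
        signal_power=signal,
        noise_power=p_each - signal,
        mean_total_power=p_each,
        n_reps=n,
    )


def include_unit(pe: PowerEstimates) -> bool:
    """Inclusion rule: signal power at least twice the noise power."""
    return bool(pe.signal_power >= 2.0 * pe.noise_power)


# ---------------------------------------------------------------------------
# model containers and forward prediction
# ---------------------------------------------------------------------------

@dataclass
class STRFModel:
    """Fitted simple or context model."""

    c: float
    prf: np.ndarray                      # (n_lags, n_freq)
    cgf: np.ndarray | None = None        # (n_tau, 2*n_phi+1), None for simple
    scaling: str = "amp"
    asd_hyperparams: dict = field(default_factory=dict)
    lag_bin_ms: float = 5.0
    freq_step_oct: float = 1.0 / 12.0
    converged: bool = True
    history: dict = field(default_factory=dict)

    @property
    def kind(self) -> str:
        return "context" if self.cgf is not None else "simple"

    def predict(self, s: np.ndarray) -> np.ndarray:
        return context_model_predict(s, self.c, self.prf, self.cgf)


@dataclass
class PredictionScore:
    predictive_power_norm: float
    model: str
    scaling: str
    cv_folds: int
    cv_reps: int


def _shift2(s: np.ndarray, m: int, n: int) -> np.ndarray:
    """Return a with a[t, k] = s[t - m, k + n], zero outside the array."""
    T, K = s.shape
    out = np.zeros_like(s)
    t0, t1 = max(m, 0), min(T, T + m)
    src_t0, src_t1 = max(-m, 0), min(T, T - m)
    k0, k1 = max(-n, 0), min(K, K - n)
    src_k0, src_k1 = max(n, 0), min(K, K + n)
    out[t0:t1, k0:k1] = s[src_t0:src_t1, src_k0:src_k1]
    return out


def _lag_views(s: np.ndarray, n_lags: int):
    """List of arrays v[l][t, k] = s[t - l, k] (views into one padded copy)."""
    T, K = s.shape
    pad = np.vstack([np.zeros((n_lags - 1, K)), s])
    return [pad[n_lags - 1 - l : n_lags - 1 - l + T] for l in range(n_lags)]


def apply_prf(s: np.ndarray, prf: np.ndarray) -> np.ndarray:
    """Causal PRF filter output: out(i) = sum_{l,k} prf[l,k] * s(i-l, k)."""
    n_lags = prf.shape[0]
    out = np.zeros(s.shape[0])
    for l, v in enumerate(_lag_views(s, n_lags)):
        out += v @ prf[l]
    return out


def context_field(s: np.ndarray, cgf: np.ndarray) -> np.ndarray:
    """ctx(t, k) = sum_{m,n} cgf[m, n+N] * s(t - m, k + n)."""
    n_tau, n_phi_total = cgf.shape
    N = (n_phi_total - 1) // 2
    ctx = np.zeros_like(s)
    for m in range(n_tau):
        for n in range(-N, N + 1):
            w = cgf[m, n + N]
            if w != 0.0:
                ctx += w * _shift2(s, m, n)
    return ctx


def context_model_predict(s: np.ndarray, c: float, prf: np.ndarray, cgf: np.ndarray | None) -> np.ndarray:
    """Firing-rate prediction of the context (or simple, cgf=None) model."""
    s = np.asarray(s, dtype=float)
    if cgf is None:
        return c + apply_prf(s, prf)
    s_eff = s * (1.0 + context_field(s, cgf))
    return c + apply_prf(s_eff, prf)


# ---------------------------------------------------------------------------
# Gram-matrix machinery (memory-light lagged design algebra)
# ---------------------------------------------------------------------------

def _gram_and_xty(s: np.ndarray, y: np.ndarray, n_lags: int, idx=None):
    """Gram matrix X^T X, X^T y and column sums of the lagged design.

    ``idx`` restricts the sums to a subset of time bins (cross-validation
    folds) without materializing the full design matrix.
    """
    T, K = s.shape
    views = _lag_views(s, n_lags)
    if idx is not None:
        views = [v[idx] for v in views]
        y = y[idx]
    p = n_lags * K
    G = np.empty((p, p))
    b = np.empty(p)
    colsum = np.empty(p)
    for l in range(n_lags):
        b[l * K : (l + 1) * K] = views[l].T @ y
        colsum[l * K : (l + 1) * K] = views[l].sum(axis=0)
        for l2 in range(l, n_lags):
            blk = views[l].T @ views[l2]
            G[l * K : (l + 1) * K, l2 * K : (l2 + 1) * K] = blk
            if l2 != l:
                G[l2 * K : (l2 + 1) * K, l * K : (l + 1) * K] = blk.T
    return G, b, colsum, float(y @ y), float(y.sum()), y.shape[0]


def _se_kernel(n: int, length: float, jitter: float = 1e-6) -> np.ndarray:
    idx = np.arange(n)
    K = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * length**2))
    return K + jitter * np.eye(n)


def _kron_transform(G: np.ndarray, Ut: np.ndarray, Uf: np.ndarray) -> np.ndarray:
    """(Ut (x) Uf)^T G (Ut (x) Uf) for G of shape (L*K, L*K)."""
    L, K = Ut.shape[0], Uf.shape[0]
    B = G.reshape(L, K, L, K)
    # contract each axis with the eigenvector matrices (BLAS-backed)
    B = np.tensordot(B, Ut, axes=(0, 0))   # (K, L, K, L')
    B = np.tensordot(B, Uf, axes=(0, 0))   # (L, K, L', K')
    B = np.tensordot(B, Ut, axes=(0, 0))   # (K, L', K', L'')... axis order rotates
    B = np.tensordot(B, Uf, axes=(0, 0))   # (L', K', L'', K'')
    return B.reshape(L * K, L * K)


class _ASDPrior:
    """Separable squared-exponential prior over (lag, frequency)."""

    def __init__(self, n_lags: int, n_freq: int):
        self.n_lags = n_lags
        self.n_freq = n_freq

    def eig(self, log_rho: float, log_lt: float, log_lf: float):
        Kt = _se_kernel(self.n_lags, np.exp(log_lt))
        Kf = _se_kernel(self.n_freq, np.exp(log_lf))
        dt, Ut = eigh(Kt)
        df, Uf = eigh(Kf)
        d = np.exp(log_rho) * np.kron(dt, df)
        return np.clip(d, 1e-12, None), Ut, Uf


def _evidence_and_mean(theta, prior: _ASDPrior, Gc, bc, yty_c, n, want_mean=False):
    """Negative log marginal likelihood (and posterior mean) of the linear
    Gaussian model with centered design/response."""
    log_rho, log_lt, log_lf, log_sig2 = theta
    sig2 = np.exp(log_sig2)
    d, Ut, Uf = prior.eig(log_rho, log_lt, log_lf)
    B = _kron_transform(Gc, Ut, Uf)
    b_e = (Ut.T @ bc.reshape(prior.n_lags, prior.n_freq) @ Uf).ravel()
    sd = np.sqrt(d)
    M = (sd[:, None] * B * sd[None, :]) / sig2
    M[np.diag_indices_from(M)] += 1.0
    try:
        cf = cho_factor(M, lower=True)
    except np.linalg.LinAlgError:
        return (np.inf, None) if want_mean else np.inf
    logdet_m = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    v = sd * b_e
    alpha = cho_solve(cf, v)
    quad = yty_c / sig2 - float(v @ alpha) / sig2**2
    nll = 0.5 * (n * np.log(2.0 * np.pi) + n * np.log(sig2) + logdet_m + quad)
    if not want_mean:
        return nll
    w_e = sd * alpha / sig2
    w = (Ut @ w_e.reshape(prior.n_lags, prior.n_freq) @ Uf.T).ravel()
    return nll, w


def _center(G, b, colsum, yty, ysum, n):
    mu = colsum / n
    ybar = ysum / n
    Gc = G - n * np.outer(mu, mu)
    bc = b - n * mu * ybar
    yty_c = yty - n * ybar**2
    return Gc, bc, yty_c, mu, ybar


def _solve_posterior(prior, hyper, Gc, bc):
    """Posterior-mean weights at fixed hyperparameters (centered algebra)."""
    d, Ut, Uf = prior.eig(hyper["log_rho"], hyper["log_lt"], hyper["log_lf"])
    sig2 = np.exp(hyper["log_sig2"])
    B = _kron_transform(Gc, Ut, Uf)
    b_e = (Ut.T @ bc.reshape(prior.n_lags, prior.n_freq) @ Uf).ravel()
    sd = np.sqrt(d)
    M = (sd[:, None] * B * sd[None, :]) / sig2
    M[np.diag_indices_from(M)] += 1.0
    cf = cho_factor(M, lower=True)
    w_e = sd * cho_solve(cf, sd * b_e) / sig2
    return (Ut @ w_e.reshape(prior.n_lags, prior.n_freq) @ Uf.T).ravel()


def fit_strf_asd(
    stimulus,
    response: np.ndarray,
    scaling: str = "amp",
    n_lags: int = 21,
    maxfun: int = 80,
    hyperparams: dict | None = None,
) -> STRFModel:
    """Fit the simple (linear STRF) model with evidence-optimized smoothness.

    Parameters
    ----------
    stimulus : DRCStimulus or pre-scaled (time x freq) array.  A DRCStimulus
        is converted with ``scale_intensity(level_matrix, scaling)``.
    response : spike counts per time bin (trial-averaged PSTH), aligned to
        the stimulus time bins.
    n_lags : PRF lag window in bins (default 21 = 0-100 ms at 5 ms).
    maxfun : cap on evidence-function evaluations per restart.
    hyperparams : optional fixed hyperparameters (skips optimization).
    """
    s = _as_scaled(stimulus, scaling)
    y = np.asarray(response, dtype=float)
    if y.shape[0] != s.shape[0]:
        raise ValueError("response length must match stimulus time bins")
    G, b, colsum, yty, ysum, n = _gram_and_xty(s, y, n_lags)
    Gc, bc, yty_c, mu, ybar = _center(G, b, colsum, yty, ysum, n)
    prior = _ASDPrior(n_lags, s.shape[1])

    if hyperparams is None:
        yvar = max(yty_c / n, 1e-12)
        bounds = [(-15.0, 10.0), (np.log(0.25), np.log(30.0)), (np.log(0.25), np.log(40.0)), (np.log(yvar) - 10.0, np.log(yvar) + 4.0)]
        inits = [
            np.array([np.log(yvar), np.log(1.5), np.log(3.0), np.log(0.5 * yvar)]),
            np.array([np.log(yvar) - 3.0, np.log(3.0), np.log(6.0), np.log(0.1 * yvar)]),
        ]
        best = None
        converged = True
        for x0 in inits:
            res = minimize(
                _evidence_and_mean,
                x0,
                args=(prior, Gc, bc, yty_c, n),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxfun": maxfun, "ftol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success) or np.isfinite(best.fun)
        theta = best.x
        hyperparams = dict(zip(("log_rho", "log_lt", "log_lf", "log_sig2"), map(float, theta)))
        if not best.success:
            logger.debug("evidence ascent stopped at the evaluation cap; using best iterate")
    else:
        converged = True

    w = _solve_posterior(prior, hyperparams, Gc, bc)
    c = ybar - float(mu @ w)
    return STRFModel(
        c=c,
        prf=w.reshape(n_lags, s.shape[1]),
        cgf=None,
        scaling=scaling if not isinstance(stimulus, np.ndarray) else scaling,
        asd_hyperparams=hyperparams,
        converged=converged,
    )


def _as_scaled(stimulus, scaling: str) -> np.ndarray:
    if isinstance(stimulus, np.ndarray):
        return np.asarray(stimulus, dtype=float)
    return scale_intensity(stimulus.level_matrix, scaling)


# ---------------------------------------------------------------------------
# context model (ALS)
# ---------------------------------------------------------------------------

def _cgf_regularizer(n_tau: int, n_phi: int, lt: float = 0.5, lf: float = 2.0) -> np.ndarray:
    """Inverse of the fixed CGF smoothing prior (SE kernels: 0.5 time bin,
    1/6 octave = 2 frequency bins)."""
    Kc = np.kron(_se_kernel(n_tau, lt, jitter=1e-5), _se_kernel(2 * n_phi + 1, lf, jitter=1e-5))
    return np.linalg.inv(Kc)


def _cgf_design(s: np.ndarray, prf: np.ndarray, n_tau: int, n_phi: int) -> np.ndarray:
    """Design matrix of the CGF block given the PRF.

    Column (m, n) at time i is sum_{l,k} prf[l,k]*s(i-l,k)*s(i-l-m,k+n),
    i.e. the PRF filter applied to the elementwise product of the stimulus
    with its (m, n)-shifted copy.
    """
    cols = []
    for m in range(n_tau):
        for nn in range(-n_phi, n_phi + 1):
            cols.append(apply_prf(s * _shift2(s, m, nn), prf))
    return np.stack(cols, axis=1)


def fit_context_model(
    stimulus,
    response: np.ndarray,
    scaling: str = "amp",
    init: STRFModel | None = None,
    n_tau: int = 9,
    n_phi: int = 12,
    max_iter: int = 50,
    tol: float = 1e-5,
    cgf_prior_var: float = 1.0,
    n_lags: int | None = None,
    train_idx=None,
    cgf_init: np.ndarray | None = None,
) -> STRFModel:
    """Fit the context-gain model by alternating least squares.

    Initializes the PRF from the simple ASD fit (``init``) and the CGF at
    zero, then alternates exact solves: PRF and baseline given CGF (under
    the ASD-derived prior at fixed hyperparameters), CGF given PRF (under
    the fixed 0.5-bin x 1/6-octave squared-exponential smoother).  Stops
    when the relative change of the penalized training objective falls
    below ``tol`` or after ``max_iter`` alternations.  Frequency bins
    outside the stimulus band contribute zero to the context sum.
    """
    s = _as_scaled(stimulus, scaling)
    y = np.asarray(response, dtype=float)
    if init is None:
        init = fit_strf_asd(s, y, scaling=scaling, n_lags=n_lags or 21)
    n_lags = init.prf.shape[0]
    prior = _ASDPrior(n_lags, s.shape[1])
    hyper = init.asd_hyperparams
    sig2 = np.exp(hyper["log_sig2"])
    d, Ut, Uf = prior.eig(hyper["log_rho"], hyper["log_lt"], hyper["log_lf"])
    # PRF penalty: sig2 * w^T C^-1 w in the prior eigenbasis
    inv_d = 1.0 / d
    Rc = _cgf_regularizer(n_tau, n_phi)

    idx = np.arange(y.size) if train_idx is None else np.asarray(train_idx)
    y_fit = y[idx]

    prf = init.prf.copy()
    c = init.c
    cgf = np.zeros((n_tau, 2 * n_phi + 1)) if cgf_init is None else np.asarray(cgf_init, dtype=float).copy()
    obj_hist, mse_hist = [], []
    prev_obj = np.inf
    converged = False

    def penalized_obj(pred):
        resid = y_fit - pred[idx]
        w_e = (Ut.T @ prf @ Uf).ravel()
        pen_prf = sig2 * float(w_e @ (inv_d * w_e))
        pen_cgf = sig2 / cgf_prior_var * float(cgf.ravel() @ Rc @ cgf.ravel())
        return float(resid @ resid), float(resid @ resid) + pen_prf + pen_cgf

    for it in range(max_iter):
        # --- PRF (and c) step, CGF fixed ---
        s_eff = s * (1.0 + context_field(s, cgf)) if np.any(cgf) else s
        G, b, colsum, yty, ysum, n = _gram_and_xty(s_eff, y, n_lags, idx=None if train_idx is None else idx)
        Gc, bc, yty_c, mu, ybar = _center(G, b, colsum, yty, ysum, n)
        w = _solve_posterior(prior, hyper, Gc, bc)
        prf = w.reshape(n_lags, s.shape[1])
        c = ybar - float(mu @ w)

        # --- CGF step, PRF fixed ---
        Z = _cgf_design(s, prf, n_tau, n_phi)
        base = c + apply_prf(s, prf)
        Zf, rf = Z[idx], y_fit - base[idx]
        A = Zf.T @ Zf + (sig2 / cgf_prior_var) * Rc
        u = np.linalg.solve(A, Zf.T @ rf)
        cgf = u.reshape(n_tau, 2 * n_phi + 1)

        pred = context_model_predict(s, c, prf, cgf)
        mse, obj = penalized_obj(pred)
        obj_hist.append(obj)
        mse_hist.append(mse)
        if not np.isfinite(prev_obj) or prev_obj - obj > 1e-9 + tol * abs(prev_obj):
            prev_obj = obj
            continue
        if obj > prev_obj * (1.0 + 1e-9):
            logger.warning("ALS objective increased; returning best iterate")
        converged = True
        break
    else:
        if tol > 0:
            logger.warning("ALS hit the iteration cap without convergence")

    return STRFModel(
        c=c,
        prf=prf,
        cgf=cgf,
        scaling=scaling,
        asd_hyperparams=hyper,
        converged=converged,
        history={"objective": np.array(obj_hist), "mse": np.array(mse_hist)},
    )


def cgf_norm_null(
    stimulus,
    response: np.ndarray,
    model: STRFModel,
    n_shifts: int = 100,
    seed: int = 0,
    cgf_prior_var: float = 1.0,
) -> np.ndarray:
    """Permutation null for the CGF norm.

    Refits the CGF block (PRF, baseline and design held fixed) against
    circularly time-shifted responses; returns the distribution of fitted
    CGF L2 norms.  The observed ``||cgf||`` of a unit without genuine
    context structure should fall below the null's 95th percentile.
    """
    s = _as_scaled(stimulus, model.scaling)
    y = np.asarray(response, dtype=float)
    n_tau, n_phi_total = model.cgf.shape
    n_phi = (n_phi_total - 1) // 2
    Z = _cgf_design(s, model.prf, n_tau, n_phi)
    base = model.c + apply_prf(s, model.prf)
    sig2 = np.exp(model.asd_hyperparams["log_sig2"])
    A = Z.T @ Z + (sig2 / cgf_prior_var) * _cgf_regularizer(n_tau, n_phi)
    cf = cho_factor(A)
    rng = np.random.default_rng(seed)
    T = y.size
    norms = np.empty(n_shifts)
    for i in range(n_shifts):
        shift = int(rng.integers(T // 10, T - T // 10))
        y_sh = np.roll(y, shift)
        u = cho_solve(cf, Z.T @ (y_sh - base))
        norms[i] = np.linalg.norm(u)
    return norms


# ---------------------------------------------------------------------------
# cross-validated predictive power
# ---------------------------------------------------------------------------

def _normalized_pp(r_obs: np.ndarray, rho: np.ndarray, signal_power: float) -> float:
    """(P(r) - P(r - rho)) / P_hat(mu) on one set of bins."""
    return (_power(r_obs) - _power(r_obs - rho)) / signal_power


def cv_predictive_power(
    model: str,
    stimulus,
    psths: np.ndarray,
    scaling: str = "amp",
    folds: int = 10,
    reps: int = 20,
    seed: int = 0,
    n_lags: int = 21,
    n_tau: int = 9,
    n_phi: int = 12,
    als_iter: int = 3,
    maxfun: int = 80,
    base_fit: STRFModel | None = None,
) -> PredictionScore:
    """Cross-validated normalized predictive power of a model.

    For each repetition, time bins are randomly partitioned into ``folds``
    disjoint validation sets; the model is fit on the remaining bins and its
    predictive power on the held-out bins, normalized by the predictable
    signal power, is averaged over folds and repetitions.  ASD
    hyperparameters are optimized once on the full data and held fixed
    across folds; the context model is warm-started from the full-data fit
    and refined with ``als_iter`` alternations per fold.
    """
    if model not in ("simple", "context"):
        raise ValueError(f"unknown model {model!r}")
    s = _as_scaled(stimulus, scaling)
    psths = np.asarray(psths, dtype=float)
    pe = signal_noise_power(psths)
    y = psths.mean(axis=0)
    T = y.size

    if base_fit is None:
        base_fit = fit_strf_asd(s, y, scaling=scaling, n_lags=n_lags, maxfun=maxfun)
    n_lags = base_fit.prf.shape[0]
    prior = _ASDPrior(n_lags, s.shape[1])
    hyper = base_fit.asd_hyperparams
    full_context = None
    if model == "context":
        full_context = fit_context_model(
            s, y, scaling=scaling, init=base_fit, n_tau=n_tau, n_phi=n_phi, max_iter=15
        )

    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(reps):
        perm = rng.permutation(T)
        fold_sets = np.array_split(perm, folds)
        for val_idx in fold_sets:
            if val_idx.size == 0:
                raise ValueError("empty cross-validation fold")
            val_mask = np.zeros(T, dtype=bool)
            val_mask[val_idx] = True
            train_idx = np.nonzero(~val_mask)[0]
            if model == "simple":
                Gt, bt, cst, ytyt, ysumt, nt = _gram_and_xty(s, y, n_lags, idx=train_idx)
                Gc, bc, yty_c, mu, ybar = _center(Gt, bt, cst, ytyt, ysumt, nt)
                w = _solve_posterior(prior, hyper, Gc, bc)
                c = ybar - float(mu @ w)
                pred = c + apply_prf(s, w.reshape(n_lags, s.shape[1]))
            else:
                # warm-start each fold from the full fit's CGF shape; only
                # training bins enter the fold's least-squares solves
                m_fold = fit_context_model(
                    s, y, scaling=scaling, init=base_fit, n_tau=n_tau, n_phi=n_phi,
                    max_iter=als_iter, train_idx=train_idx, tol=0.0,
                    cgf_init=full_context.cgf,
                )
                pred = m_fold.predict(s)
            scores.append(_normalized_pp(y[val_idx], pred[val_idx], pe.signal_power))
    return PredictionScore(
        predictive_power_norm=float(np.mean(scores)),
        model=model,
        scaling=scaling,
        cv_folds=folds,
        cv_reps=reps,
    )


# ---------------------------------------------------------------------------
# descriptive metrics and scaling comparison
# ---------------------------------------------------------------------------

def strf_metrics(model_a: STRFModel, model_b: STRFModel | None = None, freqs: np.ndarray | None = None) -> dict:
    """Best frequency, peak weight, PRF correlation, and BF-aligned PRF.

    BF is the frequency bin of the maximum positive PRF weight (over all
    lags); the BF-aligned PRF shifts the frequency axis so BF sits at the
    center column, for population averaging.
    """
    prf = model_a.prf
    out: dict = {}
    if np.all(prf <= 0):
        out["bf_bin"] = None
        logger.warning("all-zero/negative PRF: BF undefined")
    else:
        lag_i, bf_bin = np.unravel_index(np.argmax(prf), prf.shape)
        out["bf_bin"] = int(bf_bin)
        out["bf_hz"] = float(freqs[bf_bin]) if freqs is not None else None
        out["peak_lag_bin"] = int(lag_i)
    out["max_weight"] = float(prf.max())
    if out["bf_bin"] is not None:
        K = prf.shape[1]
        aligned = np.zeros((prf.shape[0], 2 * K - 1))
        shift = K - 1 - out["bf_bin"]
        aligned[:, shift : shift + K] = prf
        out["bf_aligned_prf"] = aligned
    if model_b is not None:
        a, b = model_a.prf.ravel(), model_b.prf.ravel()
        out["prf_correlation"] = float(np.corrcoef(a, b)[0, 1])
        if out["bf_bin"] is not None and np.any(model_b.prf > 0):
            bf_b = int(np.unravel_index(np.argmax(model_b.prf), model_b.prf.shape)[1])
            out["delta_bf_oct"] = (bf_b - out["bf_bin"]) * model_a.freq_step_oct
    return out


def scaling_comparison(
    stimulus,
    psths: np.ndarray,
    scales=INPUT_SCALES,
    models=("simple",),
    folds: int = 10,
    reps: int = 1,
    seed: int = 0,
    **fit_kwargs,
):
    """Cross-validated predictive power per input scale (and model).

    Returns (table: DataFrame with one row per scale x model, best_scale:
    dict model -> argmax scale).
    """
    import pandas as pd

    rows = []
    for scale in scales:
        for model in models:
            score = cv_predictive_power(
                model, stimulus, psths, scaling=scale, folds=folds, reps=reps, seed=seed, **fit_kwargs
            )
            rows.append(
                dict(scale=scale, model=model, predictive_power_norm=score.predictive_power_norm)
            )
    table = pd.DataFrame(rows)
    best = {
        m: table[table.model == m].set_index("scale").predictive_power_norm.idxmax()
        for m in models
    }
    return table, best
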