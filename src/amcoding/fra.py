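"""Pure-tone tuning analysis: kernel spike density, significance-bounded
frequency response areas, CF/MT extraction, and the threshold-shift parabola.

A frequency response area (FRA) is the matrix of evoked firing rates over a
tone frequency x level grid.  Significant tuning is delimited with a
permutation test on evoked-minus-spontaneous rates with family-wise error
control (a surrogate for autocorrelation-based tuning-area methods whose
internals are not standardized), after which the characteristic frequency
(CF) is the frequency of the significant cell at the lowest significant
level, and the minimum threshold (MT) is that level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, label

__all__ = ["FRAResult", "compute_ksd", "extract_cf_mt", "fit_mt_parabola"]


@dataclass
class FRAResult:
    """Tuning matrix with significance mask and extracted CF/MT."""

    response_matrix: np.ndarray    # levels x frequencies, evoked rate (spk/s)
    significance_mask: np.ndarray  # boolean, same shape
    cf: float                      # Hz, NaN if no significant cell
    mt: float                      # dB SPL, NaN if no significant cell
    frequencies: np.ndarray        # Hz
    levels: np.ndarray             # dB SPL
    condition: str = "baseline"

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.cf))

    def to_frame(self):
        import pandas as pd

        li, fi = np.meshgrid(np.arange(self.levels.size), np.arange(self.frequencies.size), indexing="ij")
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies[fi.ravel()],
                "level_db": self.levels[li.ravel()],
                "rate": self.response_matrix.ravel(),
                "significant": self.significance_mask.ravel(),
            }
        )


def compute_ksd(spike_times, kernel_sigma: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian kernel spike density, in spikes/s, on a regular time grid.

    The density integrates (over the grid's support) to the spike count.
    An empty spike list returns the zero function.

    Parameters
    ----------
    spike_times : spike times, s.
    kernel_sigma : kernel standard deviation, s.
    grid : regular time grid (bin centers), s; spacing should be well below
        ``kernel_sigma`` for the peak values to be accurate.
    """
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    grid = np.asarray(grid, dtype=float)
    st = np.asarray(spike_times, dtype=float)
    dt = grid[1] - grid[0]
    if st.size == 0:
        return np.zeros_like(grid)
    edges = np.concatenate([grid - dt / 2.0, [grid[-1] + dt / 2.0]])
    counts, _ = np.histogram(st, bins=edges)
    rate = counts / dt
    return gaussian_filter1d(rate, sigma=kernel_sigma / dt, mode="constant", truncate=8.0)


def _evoked_spont_rates(spike_trains, grid, evoked_window=(0.0, 0.100), spont_window=(0.250, 0.300)):
    """Per-trial evoked and spontaneous rates for each FRA cell.

    ``spike_trains[level_index][freq_index]`` is a list of per-repetition
    spike-time arrays relative to tone onset (tone plays 0-100 ms; the
    spontaneous window defaults to the final 50 ms of the 200-ms ITI).
    """
    n_l = len(spike_trains)
    n_f = len(spike_trains[0])
    n_rep = len(spike_trains[0][0])
    evoked = np.zeros((n_l, n_f, n_rep))
    spont = np.zeros((n_l, n_f, n_rep))
    for li in range(n_l):
        for fi in range(n_f):
            for ri, st in enumerate(spike_trains[li][fi]):
                st = np.asarray(st, dtype=float)
                evoked[li, fi, ri] = ((st >= evoked_window[0]) & (st < evoked_window[1])).sum() / (
                    evoked_window[1] - evoked_window[0]
                )
                spont[li, fi, ri] = ((st >= spont_window[0]) & (st < spont_window[1])).sum() / (
                    spont_window[1] - spont_window[0]
                )
    return evoked, spont


def extract_cf_mt(
    responses,
    grid,
    alpha: float = 0.05,
    n_permutations: int = 500,
    seed: int = 0,
    condition: str = "baseline",
) -> FRAResult:
    """Significance-bounded tuning area with CF and MT.

    Parameters
    ----------
    responses : either a tuple ``(evoked, spont)`` of (levels x freqs x reps)
        rate arrays, or nested per-cell spike-time lists (see
        ``_evoked_spont_rates``).
    grid : FRAGrid (provides frequencies and levels).
    alpha : family-wise false-positive level of the tuning mask.

    The per-cell statistic is the mean over repetitions of the paired
    evoked-minus-spontaneous rate difference.  The null distribution of the
    *maximum* statistic over all cells is built by random sign flips of the
    per-repetition differences (exact under exchangeability of the two
    windows), which controls the family-wise error rate at ``alpha``.  The
    mask is then restricted to the contiguous (4-connected) cluster that
    contains the peak cell.  CF is the frequency of the significant cell at
    the lowest significant level (ties broken by the larger response); MT is
    that level.  A unit with no significant cell returns NaN CF/MT.
    """
    if isinstance(responses, tuple) and len(responses) == 2 and hasattr(responses[0], "ndim"):
        evoked, spont = (np.asarray(a, dtype=float) for a in responses)
    else:
        evoked, spont = _evoked_spont_rates(responses, grid)
    if evoked.shape[2] < 2:
        raise ValueError("need at least 2 repetitions per cell")
    n_l, n_f, n_rep = evoked.shape
    diffs = evoked - spont                      # levels x freqs x reps
    stat = diffs.mean(axis=2)                   # observed per-cell statistic

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_rep))
    # max-T null: flip signs of per-rep differences, take max cell statistic
    flipped = np.einsum("lfr,pr->plf", diffs, signs) / n_rep
    max_null = flipped.reshape(n_permutations, -1).max(axis=1)
    crit = np.quantile(max_null, 1.0 - alpha)
    mask = stat > crit

    if mask.any():
        # keep the contiguous cluster containing the peak significant cell
        labels, _ = label(mask)
        peak_flat = np.argmax(np.where(mask, stat, -np.inf))
        peak = np.unravel_index(peak_flat, stat.shape)
        mask = labels == labels[peak]

    freqs = np.asarray(grid.frequencies, dtype=float)
    levels = np.asarray(grid.levels, dtype=float)
    if mask.any():
        mt_idx = int(np.nonzero(mask.any(axis=1))[0].min())
        row = np.where(mask[mt_idx], stat[mt_idx], -np.inf)
        cf_idx = int(np.argmax(row))
        cf, mt = float(freqs[cf_idx]), float(levels[mt_idx])
    else:
        cf = mt = np.nan
    return FRAResult(
        response_matrix=evoked.mean(axis=2),
        significance_mask=mask,
        cf=cf,
        mt=mt,
        frequencies=freqs,
        levels=levels,
        condition=condition,
    )


def fit_mt_parabola(delta_mt, cf_khz):
    """Least-squares parabola of threshold shift against log CF.

    Fits ``dMT = a*(log10 CF)^2 + b*log10 CF + c`` with CF in kHz by ordinary
    least squares.  Returns ``(a, b, c)`` and the fitted values.
    """
    y = np.asarray(delta_mt, dtype=float)
    x = np.log10(np.asarray(cf_khz, dtype=float))
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct CFs")
    design = np.column_stack([x**2, x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design")
    return tuple(float(c) for c in coef), design @ coef
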