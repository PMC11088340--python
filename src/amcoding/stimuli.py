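"""Stimulus synthesis: SAM noise, dynamic random chords, and pure-tone grids.

Three stimulus classes drive the analyses in this package:

* **SAM noise** — band-limited pink noise whose envelope switches from flat
  (unmodulated, UM) to sinusoidal (``1 + m*sin(2*pi*f_mod*t + phi)``).  The UM
  segment is spectrally matched to the modulated noise by randomizing the
  sideband phases, and the two segments are joined with an energy-preserving
  20-ms sine/cosine cross-fade so that the transition carries no spectral or
  loudness cue other than the modulation itself.
* **Dynamic random chords (DRC)** — dense superpositions of brief tone pips
  with independently randomized onsets, frequencies, levels and durations,
  used for spectrotemporal receptive-field estimation.
* **FRA grids** — pure-tone frequency x level grids for tuning-curve mapping.

All generators are deterministic given an integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SAMParams",
    "SAMTrial",
    "DRCGrid",
    "ToneEvent",
    "DRCStimulus",
    "FRAGrid",
    "INPUT_SCALES",
    "am_phase_offset",
    "pink_noise",
    "make_matched_um",
    "crossfade_pair",
    "synthesize_sam_trial",
    "generate_drc",
    "scale_intensity",
    "generate_fra_schedule",
    "write_wav",
]

#: Modulation frequencies (Hz), depths, and intensities (dB SPL) of the
#: standard SAM recording grid.
SAM_FMODS = (16.0, 64.0, 128.0, 512.0)
SAM_DEPTHS = (0.0, 0.06, 0.125, 0.25, 0.5, 1.0)
SAM_INTENSITIES = (45.0, 60.0)

INPUT_SCALES = ("pow", "amp", "dB0", "dB20", "dB40", "binary")


@dataclass(frozen=True)
class SAMParams:
    """Parameters of one SAM-noise trial.

    The trial consists of ``um_duration`` seconds of unmodulated noise
    followed by ``am_duration`` seconds of modulated noise, cross-faded over
    ``crossfade_ms`` at the transition.
    """

    fmod: float = 16.0           # modulation frequency, Hz
    m: float = 1.0               # modulation depth in [0, 1]
    intensity: float = 60.0      # dB SPL (metadata; waveforms are unit-RMS carrier)
    um_duration: float = 1.0     # s
    am_duration: float = 1.0     # s
    sample_rate: float = 97656.25  # Hz
    band_low: float = 2000.0     # carrier band, Hz
    band_high: float = 48000.0
    crossfade_ms: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"modulation depth must be in [0, 1], got {self.m}")
        if not (0 < self.band_low < self.band_high < self.sample_rate / 2):
            raise ValueError("require 0 < band_low < band_high < sample_rate/2")
        if self.um_duration <= self.crossfade_ms / 1000.0:
            raise ValueError("UM segment must outlast the cross-fade window")


@dataclass
class SAMTrial:
    """A synthesized SAM trial: waveform, envelope, and transition time."""

    waveform: np.ndarray     # pressure samples, arbitrary units
    envelope: np.ndarray     # unitless modulator, same length
    transition_time: float   # s, start of the cross-fade into AM
    params: SAMParams


@dataclass(frozen=True)
class DRCGrid:
    """Time/frequency/level grid of a dynamic random chord stimulus."""

    time_bin: float = 5.0          # ms
    freq_low: float = 2000.0       # Hz
    freq_high: float = 64000.0     # Hz
    freq_step: float = 1.0 / 12.0  # octaves
    level_min: float = 25.0        # dB SPL
    level_max: float = 70.0
    level_step: float = 5.0
    duration_min: float = 20.0     # ms, includes one on- and one off-ramp bin
    duration_max: float = 200.0
    duration_step: float = 5.0
    duration_lambda: float = 30.0  # ms, exponential decay constant
    density: float = 2.0           # mean concurrent tones per octave
    total_duration: float = 60.0   # s

    @property
    def n_freq(self) -> int:
        octaves = np.log2(self.freq_high / self.freq_low)
        return int(round(octaves / self.freq_step))

    @property
    def frequencies(self) -> np.ndarray:
        """Center frequencies (Hz) of the ``n_freq`` bins."""
        return self.freq_low * 2.0 ** (self.freq_step * np.arange(self.n_freq))

    @property
    def levels(self) -> np.ndarray:
        n = int(round((self.level_max - self.level_min) / self.level_step)) + 1
        return self.level_min + self.level_step * np.arange(n)

    @property
    def n_time(self) -> int:
        return int(round(self.total_duration * 1000.0 / self.time_bin))

    @property
    def duration_support_bins(self) -> np.ndarray:
        """Allowed tone durations, in time bins."""
        d = np.arange(self.duration_min, self.duration_max + 1e-9, self.duration_step)
        return np.round(d / self.time_bin).astype(int)

    def duration_pmf(self) -> np.ndarray:
        """Truncated, discretized exponential over the duration support."""
        d_ms = self.duration_support_bins * self.time_bin
        w = np.exp(-d_ms / self.duration_lambda)
        return w / w.sum()


@dataclass(frozen=True)
class ToneEvent:
    onset_bin: int
    freq_bin: int
    level: float          # dB SPL
    duration_bins: int


@dataclass
class DRCStimulus:
    """A DRC instance: tone list plus the painted level matrix.

    ``level_matrix`` has shape (time bins, freq bins); silent bins hold NaN
    ("no tone"), occupied bins hold the tone level in dB SPL.
    """

    grid: DRCGrid
    tones: list
    level_matrix: np.ndarray
    seed: int

    def tone_table(self):
        """Flat table of tone events (pandas DataFrame)."""
        import pandas as pd

        freqs = self.grid.frequencies
        return pd.DataFrame(
            {
                "onset_bin": [t.onset_bin for t in self.tones],
                "freq_bin": [t.freq_bin for t in self.tones],
                "freq_hz": [freqs[t.freq_bin] for t in self.tones],
                "level_db": [t.level for t in self.tones],
                "duration_bins": [t.duration_bins for t in self.tones],
            }
        )


@dataclass(frozen=True)
class FRAGrid:
    """Pure-tone frequency-response-area grid.

    2-64 kHz in 1/4-octave steps (21 frequencies) x 0-60 dB SPL in 5-dB steps
    (13 levels), 100-ms tones at 200-ms intertrial interval, 20 repetitions in
    pseudorandom order.
    """

    freq_low: float = 2000.0
    freq_high: float = 64000.0
    freq_step: float = 0.25       # octaves
    level_min: float = 0.0
    level_max: float = 60.0
    level_step: float = 5.0
    tone_duration: float = 0.100  # s
    iti: float = 0.200            # s
    repetitions: int = 20

    @property
    def frequencies(self) -> np.ndarray:
        n = int(round(np.log2(self.freq_high / self.freq_low) / self.freq_step)) + 1
        return self.freq_low * 2.0 ** (self.freq_step * np.arange(n))

    @property
    def levels(self) -> np.ndarray:
        n = int(round((self.level_max - self.level_min) / self.level_step)) + 1
        return self.level_min + self.level_step * np.arange(n)


# ---------------------------------------------------------------------------
# SAM noise
# ---------------------------------------------------------------------------

def am_phase_offset(m: float, mode: str = "printed") -> float:
    """Starting phase of the sinusoidal modulator.

    The modulation begins at the phase where the instantaneous value of the
    modulated envelope matches the average power of the preceding unmodulated
    noise, avoiding a level step at the transition.

    Parameters
    ----------
    m : modulation depth in [0, 1].
    mode : ``"printed"`` uses ``arcsin(sqrt(1 + m^2/2) - 1)``; ``"power"``
        uses ``arcsin((sqrt(1 + m^2/2) - 1)/m)``, the variant that makes the
        squared envelope at the transition equal the mean AM envelope power
        ``1 + m^2/2`` exactly.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"modulation depth must be in [0, 1], got {m}")
    if m == 0.0:
        return 0.0
    root = np.sqrt(1.0 + 0.5 * m * m) - 1.0
    if mode == "printed":
        return float(np.arcsin(root))
    if mode == "power":
        return float(np.arcsin(root / m))
    raise ValueError(f"unknown phase-offset mode {mode!r}")


def pink_noise(
    n_samples: int,
    sample_rate: float,
    band: tuple = (2000.0, 48000.0),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Band-limited pink (1/f power) noise with unit RMS.

    Constructed in the frequency domain: magnitude proportional to
    ``1/sqrt(f)`` inside ``band``, zero outside, uniformly random phases.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    mag = np.zeros_like(freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    mag[in_band] = 1.0 / np.sqrt(freqs[in_band])
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.shape)
    spec = mag * np.exp(1j * phases)
    spec[0] = 0.0
    if n_samples % 2 == 0:
        spec[-1] = np.abs(spec[-1])  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n_samples)
    rms = np.sqrt(np.mean(x * x))
    return x / rms


def make_matched_um(sam_waveform: np.ndarray, seed: int) -> np.ndarray:
    """Spectrally matched unmodulated noise via sideband phase randomization.

    Returns a real waveform with the identical discrete magnitude spectrum
    (hence identical power and spectral envelope) as the input, but with
    uniformly randomized phases, which destroys the periodic envelope of a
    SAM input while preserving every long-term spectral property.
    """
    x = np.asarray(sam_waveform, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform must be finite")
    n = x.size
    spec = np.fft.rfft(x)
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.shape)
    new = np.abs(spec) * np.exp(1j * phases)
    new[0] = np.abs(spec[0]) * np.sign(spec.real[0]) if spec.real[0] != 0 else 0.0
    if n % 2 == 0:
        new[-1] = np.abs(spec[-1])
    return np.fft.irfft(new, n=n)


def crossfade_pair(a: np.ndarray, b: np.ndarray, window_ms: float, sample_rate: float) -> np.ndarray:
    """Energy-preserving cross-fade from ``a`` into ``b``.

    Over the fade window the first signal is weighted by cos(theta) and the
    second by sin(theta) with theta ramping 0 -> pi/2, so the summed squared
    weights are identically 1 and the combined instantaneous power of two
    uncorrelated noises stays constant.  The output has length
    ``len(a) + len(b) - window``: the window consumes the tail of ``a`` and
    the head of ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    nwin = int(round(window_ms * 1e-3 * sample_rate))
    if nwin > a.size or nwin > b.size:
        raise ValueError("cross-fade window longer than a segment")
    theta = (np.arange(nwin) + 0.5) / nwin * (np.pi / 2.0)
    out = np.empty(a.size + b.size - nwin)
    out[: a.size - nwin] = a[: a.size - nwin]
    out[a.size - nwin : a.size] = a[a.size - nwin :] * np.cos(theta) + b[:nwin] * np.sin(theta)
    out[a.size :] = b[nwin:]
    return out


def synthesize_sam_trial(params: SAMParams, phase_mode: str = "printed") -> SAMTrial:
    """Synthesize one UM->SAM trial.

    The AM segment is band-limited pink noise multiplied by
    ``1 + m*sin(2*pi*f_mod*t + phi)`` with ``phi`` from
    :func:`am_phase_offset`.  The UM segment is produced by sideband phase
    randomization of a second instance of the modulated noise, so its power
    and spectral envelope match the AM segment.  The segments are joined with
    a sine/cosine cross-fade starting at the transition.
    """
    p = params
    fs = p.sample_rate
    n_um = int(round(p.um_duration * fs))
    n_am = int(round(p.am_duration * fs))
    nwin = int(round(p.crossfade_ms * 1e-3 * fs))
    if p.m > 0 and p.am_duration < 1.0 / p.fmod:
        import warnings

        warnings.warn("AM segment shorter than one modulation period", stacklevel=2)

    seeds = np.random.SeedSequence(p.seed).spawn(3)
    carrier = pink_noise(n_am, fs, (p.band_low, p.band_high), rng=np.random.default_rng(seeds[0]))
    phi = am_phase_offset(p.m, mode=phase_mode)
    t_am = np.arange(n_am) / fs
    env_am = 1.0 + p.m * np.sin(2.0 * np.pi * p.fmod * t_am + phi)
    am = carrier * env_am

    # matched UM: phase-randomize an independent SAM instance of UM length
    um_src_carrier = pink_noise(n_um, fs, (p.band_low, p.band_high), rng=np.random.default_rng(seeds[1]))
    t_um = np.arange(n_um) / fs
    um_src = um_src_carrier * (1.0 + p.m * np.sin(2.0 * np.pi * p.fmod * t_um + phi))
    um = make_matched_um(um_src, seed=int(seeds[2].generate_state(1)[0] % (2**31)))

    # cross-fade window sits at the start of the AM segment: extend UM by nwin
    # so the total length stays (um_duration + am_duration) * fs
    um_ext = np.concatenate([um, um[:nwin]]) if nwin else um
    waveform = crossfade_pair(um_ext, am, p.crossfade_ms, fs)
    assert waveform.size == n_um + n_am

    t = np.arange(n_um + n_am) / fs
    envelope = np.ones(n_um + n_am)
    envelope[n_um:] = 1.0 + p.m * np.sin(2.0 * np.pi * p.fmod * (t[n_um:] - p.um_duration) + phi)
    return SAMTrial(waveform=waveform, envelope=envelope, transition_time=p.um_duration, params=p)


def sam_condition_grid(
    fmods=SAM_FMODS, depths=SAM_DEPTHS, intensities=SAM_INTENSITIES, **kwargs
) -> list:
    """All distinct SAMParams of the standard stimulus grid (4 x 6 x 2 = 48)."""
    out = []
    for f in fmods:
        for m in depths:
            for i in intensities:
                out.append(SAMParams(fmod=f, m=m, intensity=i, **kwargs))
    return out


# ---------------------------------------------------------------------------
# Dynamic random chords
# ---------------------------------------------------------------------------

def _onset_probability(grid: DRCGrid) -> float:
    """Per-(time, freq)-bin tone onset probability.

    "Density" is the time-averaged count of concurrently active tones per
    octave.  With ``rho = density / bins_per_octave`` the target occupancy of
    a single frequency bin, and tones forbidden from starting in an occupied
    bin, the onset probability in a free bin solves
    ``rho = p*E[dur] / (p*E[dur] + 1)``-type renewal balance:
    ``p = rho / ((1 - rho) * E[dur])``.
    """
    bins_per_octave = int(round(1.0 / grid.freq_step))
    rho = grid.density / bins_per_octave
    if rho >= 1.0:
        raise ValueError("requested density implies >=1 concurrent tone per frequency bin")
    mean_dur = float(np.sum(grid.duration_support_bins * grid.duration_pmf()))
    # renewal balance: busy fraction = E[dur] / (E[idle] + E[dur]) with
    # E[idle] = (1-p)/p geometric waiting before an onset
    r = rho / ((1.0 - rho) * mean_dur)
    return r / (1.0 + r)


def generate_drc(grid: DRCGrid, seed: int) -> DRCStimulus:
    """Generate a dynamic random chord stimulus.

    Tone onsets are drawn independently per (time bin x frequency bin) with a
    probability calibrated so the mean number of simultaneously active tones
    per octave equals ``grid.density``; durations follow a truncated,
    discretized exponential (decay ``duration_lambda``); levels are uniform
    on the level grid.  A bin already occupied by an active tone cannot start
    a new one, so the level matrix is single-valued.
    """
    rng = np.random.default_rng(seed)
    n_t, n_f = grid.n_time, grid.n_freq
    level_matrix = np.full((n_t, n_f), np.nan)
    tones: list = []
    if grid.density == 0:
        return DRCStimulus(grid=grid, tones=tones, level_matrix=level_matrix, seed=seed)

    p = _onset_probability(grid)
    support = grid.duration_support_bins
    pmf = grid.duration_pmf()
    levels = grid.levels
    # occupied-until bookkeeping per frequency bin
    busy_until = np.zeros(n_f, dtype=int)  # first free bin index per freq
    onset_draws = rng.random((n_t, n_f))
    dur_draws = rng.integers(0, 2**31, size=(n_t, n_f))
    for ti in range(n_t):
        free = busy_until <= ti
        start = free & (onset_draws[ti] < p)
        for fi in np.nonzero(start)[0]:
            sub = np.random.default_rng(int(dur_draws[ti, fi]))
            dur = int(support[sub.choice(support.size, p=pmf)])
            lvl = float(levels[sub.integers(0, levels.size)])
            dur_eff = min(dur, n_t - ti)
            level_matrix[ti : ti + dur_eff, fi] = lvl
            busy_until[fi] = ti + dur
            tones.append(ToneEvent(onset_bin=ti, freq_bin=int(fi), level=lvl, duration_bins=dur))
    return DRCStimulus(grid=grid, tones=tones, level_matrix=level_matrix, seed=seed)


def scale_intensity(level, scale: str):
    """Map tone level in dB SPL to model input strength.

    Every scale maps 70 dB SPL -> 1 and silence (NaN) -> 0.

    * ``pow``:    10^((x-70)/10)   (sound power re maximum)
    * ``amp``:    10^((x-70)/20)   (sound amplitude re maximum)
    * ``dB0/20/40``: (x-ref)/(70-ref) for x > ref, else 0 — linear in
      decibels above the reference, normalized so 70 dB SPL maps to 1
    * ``binary``: 1 wherever a tone is present
    """
    x = np.asarray(level, dtype=float)
    silent = np.isnan(x)
    if scale == "pow":
        s = 10.0 ** ((x - 70.0) / 10.0)
    elif scale == "amp":
        s = 10.0 ** ((x - 70.0) / 20.0)
    elif scale in ("dB0", "dB20", "dB40"):
        ref = float(scale[2:])
        s = np.where(x > ref, (x - ref) / (70.0 - ref), 0.0)
    elif scale == "binary":
        s = np.ones_like(x)
    else:
        raise ValueError(f"unknown input scale {scale!r}")
    s = np.where(silent, 0.0, s)
    if np.ndim(level) == 0:
        return float(s)
    return s


# ---------------------------------------------------------------------------
# FRA schedule
# ---------------------------------------------------------------------------

def generate_fra_schedule(grid: FRAGrid, seed: int):
    """Pseudorandom trial order for an FRA set.

    Returns a DataFrame with one row per tone presentation: onset time (s),
    frequency (Hz), and level (dB SPL).  Each (frequency, level) cell appears
    exactly ``grid.repetitions`` times.
    """
    import pandas as pd

    freqs = grid.frequencies
    levels = grid.levels
    fi, li = np.meshgrid(np.arange(freqs.size), np.arange(levels.size), indexing="ij")
    cells = np.stack([fi.ravel(), li.ravel()], axis=1)
    rng = np.random.default_rng(seed)
    order = []
    for _ in range(grid.repetitions):
        perm = rng.permutation(cells.shape[0])
        order.append(cells[perm])
    order = np.concatenate(order, axis=0)
    period = grid.tone_duration + grid.iti
    onsets = np.arange(order.shape[0]) * period
    return pd.DataFrame(
        {
            "onset_s": onsets,
            "freq_hz": freqs[order[:, 0]],
            "level_db": levels[order[:, 1]],
            "freq_index": order[:, 0],
            "level_index": order[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_wav(path, waveform: np.ndarray, sample_rate: float, metadata: dict | None = None):
    """Write a float32 WAV plus a JSON metadata sidecar (``<path>.json``)."""
    from scipy.io import wavfile

    wavfile.write(path, int(round(sample_rate)), np.asarray(waveform, dtype=np.float32))
    if metadata is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(_jsonable(metadata), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj
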