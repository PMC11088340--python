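"""Stimulus synthesis: SAM envelope conventions, matched UM, cross-fade,
DRC statistics, input scalings, FRA schedules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from amcoding import stimuli as st


class TestPhaseOffset:
    def test_no_modulation_returns_zero(self):
        assert st.am_phase_offset(0.0) == 0.0

    @pytest.mark.parametrize(
        "m, mode, expected",
        [
            # closed forms evaluated independently: arcsin(sqrt(1+m^2/2)-1)
            # and arcsin((sqrt(1+m^2/2)-1)/m)
            (1.0, "printed", np.arcsin(np.sqrt(1.5) - 1.0)),
            (0.5, "printed", np.arcsin(np.sqrt(1.125) - 1.0)),
            (0.5, "power", np.arcsin((np.sqrt(1.125) - 1.0) / 0.5)),
        ],
    )
    def test_closed_forms(self, m, mode, expected):
        assert st.am_phase_offset(m, mode=mode) == pytest.approx(expected, abs=1e-12)

    def test_power_mode_matches_mean_envelope_power(self):
        # only the power-continuity variant makes the squared envelope at the
        # transition equal the mean AM envelope power 1 + m^2/2
        m = 0.5
        phi = st.am_phase_offset(m, mode="power")
        assert (1 + m * np.sin(phi)) ** 2 == pytest.approx(1 + m**2 / 2, abs=1e-12)
        phi_p = st.am_phase_offset(m, mode="printed")
        assert (1 + m * np.sin(phi_p)) ** 2 != pytest.approx(1 + m**2 / 2, abs=1e-3)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            st.am_phase_offset(1.5)


class TestSAMTrial:
    def test_waveform_length_and_envelope(self):
        p = st.SAMParams(fmod=16.0, m=1.0, um_duration=0.5, am_duration=0.5, seed=1)
        tr = st.synthesize_sam_trial(p)
        assert tr.waveform.size == int(round(1.0 * p.sample_rate))
        n0 = int(round(0.5 * p.sample_rate))
        assert np.all(tr.envelope[:n0] == 1.0)
        phi = st.am_phase_offset(1.0)
        # sample grid quantizes the transition instant to ~1/fs
        assert tr.envelope[n0] == pytest.approx(1 + np.sin(phi), abs=1e-3)

    def test_am_power_ratio_vs_carrier(self):
        # E[(1 + m sin)^2] = 1 + m^2/2 relative to the unit-power carrier
        for m, expected in [(0.0, 1.0), (0.5, 1.125), (1.0, 1.5)]:
            p = st.SAMParams(fmod=16.0, m=m, seed=4)
            tr = st.synthesize_sam_trial(p)
            n0 = int(round(p.um_duration * p.sample_rate))
            nwin = int(round(p.crossfade_ms * 1e-3 * p.sample_rate))
            am = tr.waveform[n0 + nwin :]
            assert np.mean(am**2) == pytest.approx(expected, rel=0.05)

    def test_m1_16hz_has_16_cycles(self):
        p = st.SAMParams(fmod=16.0, m=1.0, am_duration=1.0, seed=2)
        tr = st.synthesize_sam_trial(p)
        n0 = int(round(p.um_duration * p.sample_rate))
        env = tr.envelope[n0:]
        # count upward crossings of the mean envelope level
        crossings = np.sum((env[:-1] < 1.0) & (env[1:] >= 1.0))
        assert crossings == 16

    def test_condition_grid_has_48_conditions(self):
        assert len(st.sam_condition_grid()) == 48


class TestMatchedUM:
    def test_magnitude_spectrum_identity(self):
        p = st.SAMParams(fmod=16.0, m=1.0, um_duration=0.2, am_duration=0.2, seed=9)
        tr = st.synthesize_sam_trial(p)
        um = st.make_matched_um(tr.waveform, seed=5)
        a = np.abs(np.fft.rfft(tr.waveform))
        b = np.abs(np.fft.rfft(um))
        nz = a > a.max() * 1e-12
        assert np.max(np.abs(a[nz] - b[nz]) / a[nz]) < 1e-9
        assert np.sum(tr.waveform**2) == pytest.approx(np.sum(um**2), rel=1e-12)

    def test_envelope_periodicity_removed(self):
        from scipy.signal import hilbert

        p = st.SAMParams(fmod=16.0, m=1.0, um_duration=1.0, am_duration=1.0, seed=12)
        tr = st.synthesize_sam_trial(p)
        n0 = int(round(p.um_duration * p.sample_rate))
        am = tr.waveform[n0:]
        um = st.make_matched_um(am, seed=6)

        def env_power_at_fmod(x):
            env = np.abs(hilbert(x))
            spec = np.abs(np.fft.rfft(env - env.mean()))
            freqs = np.fft.rfftfreq(x.size, 1 / p.sample_rate)
            return spec[np.argmin(np.abs(freqs - p.fmod))]

        assert env_power_at_fmod(am) > 10 * env_power_at_fmod(um)


class TestCrossfade:
    def test_squared_weight_sum_is_one(self):
        fs = 97656.25
        a = np.ones(4000)
        out = st.crossfade_pair(a, a.copy(), 20.0, fs)
        nwin = int(round(0.020 * fs))
        assert nwin == 1953
        theta = (np.arange(nwin) + 0.5) / nwin * np.pi / 2
        w = np.cos(theta) ** 2 + np.sin(theta) ** 2
        assert np.allclose(w, 1.0)
        # identical inputs: output equals input outside the window and shows
        # the (cos+sin) >= 1 bump inside
        assert out.size == 2 * 4000 - nwin
        assert np.all(out[4000 - nwin : 4000] >= 1.0 - 1e-12)

    def test_window_longer_than_segment_raises(self):
        with pytest.raises(ValueError):
            st.crossfade_pair(np.ones(10), np.ones(10), 20.0, 97656.25)

    def test_mean_power_preserved_for_independent_noise(self):
        fs = 10000.0
        nwin = int(round(0.020 * fs))
        rng = np.random.default_rng(0)
        powers = []
        for _ in range(1000):
            a = rng.normal(size=500)
            b = rng.normal(size=500)
            out = st.crossfade_pair(a, b, 20.0, fs)
            powers.append(np.mean(out[500 - nwin : 500] ** 2))
        powers = np.asarray(powers)
        se = powers.std(ddof=1) / np.sqrt(powers.size)
        assert abs(powers.mean() - 1.0) < 3 * se


class TestDRC:
    def test_durations_and_levels_on_grid(self, small_drc):
        g = small_drc.grid
        durs = np.array([t.duration_bins for t in small_drc.tones]) * g.time_bin
        levels = np.array([t.level for t in small_drc.tones])
        assert durs.min() >= 20.0 and durs.max() <= 200.0
        assert set(np.unique(levels)) <= set(g.levels)

    def test_grid_shape(self):
        g = st.DRCGrid()
        assert g.n_freq == 60
        assert g.levels.size == 10
        assert np.array_equal(g.duration_support_bins, np.arange(4, 41))

    def test_density_two_per_octave(self):
        octaves = 5.0
        conc = []
        for seed in (1, 2, 3):
            drc = st.generate_drc(st.DRCGrid(total_duration=30), seed)
            conc.append(np.isfinite(drc.level_matrix).sum(axis=1).mean() / octaves)
        assert np.mean(conc) == pytest.approx(2.0, abs=0.05)

    def test_determinism_and_seed_sensitivity(self):
        g = st.DRCGrid(total_duration=5)
        a = st.generate_drc(g, 11)
        b = st.generate_drc(g, 11)
        c = st.generate_drc(g, 12)
        assert a.tones == b.tones
        assert np.array_equal(a.level_matrix, b.level_matrix, equal_nan=True)
        assert a.tones != c.tones

    def test_zero_density_is_silent(self):
        drc = st.generate_drc(st.DRCGrid(total_duration=5, density=0.0), 1)
        assert drc.tones == []
        assert np.all(np.isnan(drc.level_matrix))

    def test_no_overlap_within_frequency_bin(self, small_drc):
        n_t = small_drc.grid.n_time
        painted = np.zeros_like(small_drc.level_matrix, dtype=int)
        for t in small_drc.tones:
            painted[t.onset_bin : min(t.onset_bin + t.duration_bins, n_t), t.freq_bin] += 1
        assert painted.max() == 1


class TestInputScaling:
    @pytest.mark.parametrize("scale", st.INPUT_SCALES)
    def test_endpoints(self, scale):
        assert st.scale_intensity(70.0, scale) == pytest.approx(1.0)
        assert st.scale_intensity(np.nan, scale) == 0.0

    @pytest.mark.parametrize(
        "level, scale, expected",
        [(50.0, "amp", 0.1), (50.0, "pow", 0.01), (30.0, "dB40", 0.0), (30.0, "dB20", 0.2), (45.0, "dB20", 0.5)],
    )
    def test_printed_values(self, level, scale, expected):
        assert st.scale_intensity(level, scale) == pytest.approx(expected)

    @given(hst.sampled_from(st.INPUT_SCALES))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_level(self, scale):
        levels = np.arange(25.0, 70.1, 5.0)
        vals = st.scale_intensity(levels, scale)
        assert np.all(np.diff(vals) >= 0)

    def test_unknown_scale_raises(self):
        with pytest.raises(ValueError):
            st.scale_intensity(50.0, "loudness")


class TestExport:
    def test_wav_and_metadata_sidecar_roundtrip(self, tmp_path):
        from scipy.io import wavfile

        p = st.SAMParams(fmod=16.0, m=0.5, um_duration=0.1, am_duration=0.1, seed=2)
        tr = st.synthesize_sam_trial(p)
        path = tmp_path / "trial.wav"
        st.write_wav(path, tr.waveform, p.sample_rate, metadata={"params": p})
        rate, data = wavfile.read(path)
        assert rate == int(round(p.sample_rate))
        assert np.allclose(data, tr.waveform.astype(np.float32))
        import json

        meta = json.loads((tmp_path / "trial.wav.json").read_text())
        assert meta["params"]["fmod"] == 16.0

    def test_drc_tone_table_columns(self, small_drc):
        table = small_drc.tone_table()
        assert list(table.columns) == ["onset_bin", "freq_bin", "freq_hz", "level_db", "duration_bins"]
        assert len(table) == len(small_drc.tones)
        assert (table.freq_hz >= 2000).all() and (table.freq_hz < 64000).all()


class TestFRASchedule:
    def test_cell_counts_and_determinism(self):
        g = st.FRAGrid()
        assert g.frequencies.size == 21
        assert g.levels.size == 13
        sched = st.generate_fra_schedule(g, seed=0)
        assert len(sched) == 21 * 13 * 20
        counts = sched.groupby(["freq_hz", "level_db"]).size()
        assert (counts == 20).all()
        again = st.generate_fra_schedule(g, seed=0)
        assert sched.equals(again)
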