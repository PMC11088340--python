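import numpy as np
import pytest

from amcoding import simulate as sim
from amcoding import stimuli as st


@pytest.fixture(scope="session")
def small_drc():
    """A 15-s DRC on the standard grid (fast enough for fitting tests)."""
    grid = st.DRCGrid(total_duration=15)
    return st.generate_drc(grid, seed=7)


@pytest.fixture(scope="session")
def planted_lnp(small_drc):
    """An LNP unit with a planted PRF (no context), 10 repetitions."""
    prf = sim.make_gabor_prf(8, small_drc.grid.n_freq, center_freq_bin=30)
    params = sim.LNPUnitParams(true_prf=prf, true_cgf=None, c=0.2, scaling="amp")
    counts, rate = sim.simulate_lnp_unit(params, small_drc, n_reps=10, seed=3)
    return params, counts, rate


@pytest.fixture(scope="session")
def sam_grid_16hz():
    """SAM parameter list at 16 Hz over the standard depth grid."""
    return [st.SAMParams(fmod=16.0, m=m, intensity=60.0) for m in st.SAM_DEPTHS]


@pytest.fixture(scope="session")
def locked_unit_trains(sam_grid_16hz):
    """Trains of a strongly phase-locked unit, grouped by depth."""
    up = sim.SAMUnitParams(r_base=30.0, lock_strength=1.5, unit_id="locked")
    trains = sim.simulate_sam_unit(up, sam_grid_16hz, n_trials=25, seed=11)
    by_depth = {}
    for tr in trains:
        by_depth.setdefault(tr.depth, []).append(tr)
    return by_depth
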