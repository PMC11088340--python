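"""Population threshold-crossing decoder on a simulated population.

Builds a 8-unit population, extracts the AM-encoding component, simulates
latencies from detection-level crossings of the projected activity, and
derives d' and an AM-detection threshold from the latency ROC.
"""

import numpy as np

from amcoding import popdecode as pdq, simulate as sim, stimuli as st

stims = [st.SAMParams(fmod=16.0, m=m, intensity=60.0) for m in st.SAM_DEPTHS]
units = [
    sim.SAMUnitParams(r_base=20.0 + 4 * i, lock_strength=1.0 + 0.2 * i, unit_id=f"u{i}")
    for i in range(8)
]
pop = sim.simulate_population(units, stims, n_trials=25, seed=7)
act = pdq.build_population_activity(pop)

component = pdq.am_encoding_component(act)
print("AM-encoding component weights:", np.round(component, 3))

proj = pdq.project_trials(act, component)
peak = np.median(proj[:, act.time >= act.transition_time].max(axis=1))
params = pdq.DecoderParams(component=component, detection_level=0.5 * peak,
                           non_decision_time=0.150)
curve = pdq.decoder_sensitivity(act, params, fmod=16.0)
for db, d in zip(curve.depths_db, curve.dprime):
    print(f"  {db:6.1f} dB: decoder d' = {d:.2f}")
print(f"decoder AM-detection threshold: {curve.threshold_db:.2f} dB re full modulation")
# The component concentrates on the units that carry AM information; the
# threshold tells the shallowest modulation the population signal detects.
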