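"""Behavioral psychometrics from a simulated licking session.

Simulates a 300-trial session with a planted -12 dB threshold, computes
clipped hit/false-alarm rates and the latency-ROC d' per depth, and
recovers the detection threshold.
"""

from amcoding import behavior as beh, simulate as sim

design = sim.behavior_design(fmods=(16.0,), intensities=(60.0,), n_per_cell=48,
                             catch_fraction=0.2)
params = sim.BehaviorModelParams(threshold_db=-12.0, fa_rate=0.1)
trials = sim.simulate_behavior_session(params, design, seed=5)

rates = beh.compute_rates(trials)
print(rates.to_string(index=False))

res = beh.latency_roc_dprime(trials, fmod=16.0, intensity=60.0)
for db, d, hr in zip(res.depths_db, res.dprime, res.hit_rate):
    print(f"  {db:6.1f} dB: hit rate {hr:.2f}, latency-ROC d' = {d:.2f}")
print(f"false-alarm rate (clipped): {res.fa_rate:.3f}")
print(f"recovered threshold: {res.threshold_db:.2f} dB (planted -12.00)")
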