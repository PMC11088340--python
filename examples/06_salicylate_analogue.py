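"""End-to-end two-condition run: the drug analogue lowers AM thresholds.

Runs the bundled pipeline configuration — one simulated population and one
behavioral session under baseline and a high-gain ("salicylate") condition
— and prints the mean AM-detection thresholds per analysis stage.
"""

import numpy as np

from amcoding import session

res = session.run_pipeline(session.default_salicylate_config(seed=1))


def censor(x):
    # undefined thresholds count as 0 dB (full modulation) in comparisons
    return np.where(np.isfinite(x), x, 0.0)


am = res["amcode"].assign(thr=lambda d: censor(d.threshold_db))
print("single-unit thresholds (dB re full modulation, mean over units):")
print(am.groupby(["condition", "coding"]).thr.mean().round(2).to_string())

dec = res["popdecode"].assign(thr=lambda d: censor(d.threshold_db))
print("\npopulation-decoder thresholds:")
print(dec.groupby(["condition", "fmod"]).thr.mean().round(2).to_string())

print("\nbehavioral thresholds:")
print(res["behavior"].groupby(["condition", "fmod"]).threshold_db.mean().round(2).to_string())

# Lower (more negative) thresholds in the salicylate condition across all
# four readouts reproduce the qualitative effect the pipeline is built to
# measure: increased AM contrast and phase locking improve detection.
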