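"""One run of the face-discrimination staircase for a simulated observer.

Builds a synthetic observer with a known discrimination threshold (in
d-units: Euclidean distance between 127-point landmark vectors), runs the
50-trial Bayesian adaptive staircase, and prints how the running
posterior-mean threshold estimate homes in on the truth.
"""

import numpy as np

from tabvis import ObserverModel, QuestConfig, run_face_session

TRUE_THRESHOLD = 3.40  # d-units; healthy adults typically score 3-4

config = QuestConfig()
observer = ObserverModel(face_true_threshold=TRUE_THRESHOLD, face_run_jitter_sd=0.0)
result = run_face_session(observer, n_trials=50, seed=11, config=config)

print(f"true threshold: {TRUE_THRESHOLD:.2f} d   (posterior grain {config.grain:.3f} d)")
print("trial  level_d  correct  estimate_d")
for t in (1, 2, 5, 10, 20, 50):
    level, correct = result.trials[t - 1]
    print(f"{t:5d}  {level:7.3f}  {int(correct):7d}  {result.threshold_by_trial[t - 1]:9.3f}")
err20 = result.threshold_by_trial[19] - TRUE_THRESHOLD
err50 = result.final_threshold - TRUE_THRESHOLD
print(f"\nestimate after 20 trials: {result.threshold_by_trial[19]:.3f} d (error {err20:+.3f})")
print(f"estimate after 50 trials: {result.final_threshold:.3f} d (error {err50:+.3f})")
print("The staircase presents each trial at the current posterior mean, so")
print("levels converge toward the observer's threshold; smaller final error")
print("means better measurement, and higher thresholds mean poorer vision.")
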