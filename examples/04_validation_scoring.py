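"""Score growth predictions against observed community shifts.

Loads the shipped supplement x genus fold-change matrix (community dFBA at
round 3; a synthetic stand-in whose >= 2-fold calls match the published
prediction matrix) and the transcribed observation table of significant
abundance increases from supplemented soil, then crosses them into a
confusion summary.
"""

from biostim import classify_predictions, score
from biostim.datasets import published_fold_changes, soil_observations

calls = classify_predictions(published_fold_changes())
print("positive predictions (>= 2-fold growth support):")
print(calls.astype(int).to_string(), "\n")

summary = score(calls, soil_observations())
print(f"TP={summary.tp}  TN={summary.tn}  FP={summary.fp}  FN={summary.fn}")
print(f"accuracy  = (TP+TN)/total = {summary.accuracy:.2f}")
print(f"precision = TP/(TP+FP)   = {summary.precision:.2f}")

# Two of three positive calls are confirmed by the soil data (the
# disaccharides supporting the primary degrader genus); the single false
# positive is the trehalose call for Pseudomonas.
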