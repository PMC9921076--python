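"""Confidence scoring and the per-bucket calibration curve.

A bounded score x in [0, 1] gives a free confidence 2|x - 0.5|, rescaled to
[0.5, 1] so it shares an axis with accuracy.  Bucketing predictions by the
scaled confidence (width 0.05 -> lowest bucket midpoint 0.525) and scoring
each bucket shows whether high-confidence predictions really perform better
— and the per-bucket negative share explains why a handful of misranked
negatives can crater a bucket's ROC AUC without touching its accuracy.
"""

import numpy as np

import rxnyield as ry
from rxnyield.calibration import curve_to_frame

rng = np.random.default_rng(0)
scores = rng.uniform(0, 1, 5000)
truths = (rng.uniform(0, 1, 5000) < scores).astype(int)  # calibrated scores
preds = [ry.PredictionResult.from_score(float(s)) for s in scores]

print(f"score 0.9 -> confidence {ry.confidence(0.9):.2f}, "
      f"scaled {ry.scaled_confidence(0.9):.2f}")
print(f"score 0.1 -> confidence {ry.confidence(0.1):.2f}, "
      f"scaled {ry.scaled_confidence(0.1):.2f} (confidently negative)")

bins = ry.calibration_curve(preds, truths.tolist())
print(curve_to_frame(bins).to_string(index=False,
                                     float_format=lambda v: f"{v:.3f}"))
# For calibrated scores the accuracy column tracks the bucket midpoint: the
# first bucket sits near 0.525 and the last near 0.975 — the identity line.
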