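"""The metric suite on a constructed prediction/truth pair.

Builds a 100-pixel example with known confusion counts (tp=8, fp=2, fn=5,
tn=85), derives every metric, and cross-checks the Dice = F1 identity and
the Mann-Whitney AUC.
"""

import numpy as np

import ultraseg as us

truth = np.zeros(100, dtype=int)
truth[:13] = 1                      # 13 true lesion pixels
pred = np.zeros(100, dtype=int)
pred[:8] = 1                        # 8 of them found ...
pred[13:15] = 1                     # ... plus 2 false alarms

c = us.confusion(pred, truth)
print(f"confusion: tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn}")
r = us.basic_metrics(c)
print(f"ACC={r.acc:.4f} SEN={r.sen:.4f} SPE={r.spe:.4f} "
      f"PRE={r.pre:.4f} F1={r.f1:.4f}")
print(f"Dice={us.dice(pred, truth):.4f}  (identical to F1 on binary masks)")

rng = np.random.default_rng(0)
probs = np.clip(truth * 0.6 + rng.normal(0.3, 0.2, size=100), 0, 1)
print(f"ROC-AUC={us.roc_auc(probs, truth):.4f}  "
      f"(probability a lesion pixel outranks a background pixel)")
print(f"BCE={us.bce_loss(truth, probs):.4f}  "
      f"(mean per-pixel cross-entropy of the soft scores)")
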