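"""Walk the evaluation statistics through a 2x2 example.

Tallies the confusion matrix of a four-pixel prediction by hand and
shows the mIOU, precision/recall, F-score and Dice+CE values the
package computes from it.
"""

import numpy as np

import mbffnet as mb

truth = np.array([[1, 1], [0, 0]])
pred = np.array([[1, 0], [0, 0]])

c = mb.confusion(pred, truth, k=1)
print("confusion matrix p[true, pred]:")
print(c.p)
print(f"polyp class: TP={c.tp(1)} FP={c.fp(1)} FN={c.fn(1)}")

prec, rec = mb.precision_recall(c, positive_class=1)
print(f"mIOU      = {mb.miou(c):.4f}   (mean of 2/3 background and 1/2 polyp IoU)")
print(f"precision = {prec:.4f}, recall = {rec:.4f}")
print(f"F-score   = {mb.f_score(prec, rec):.4f}")

probs = np.where(pred == 1, 0.9, 0.1)
print(f"Dice+CE against soft prediction: {mb.dice_ce_loss(truth, probs):.4f}")
print("\nA perfect prediction gives mIOU = F = 1 and ~0 loss; every")
print("statistic derives from the exact integer pixel tally above.")
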