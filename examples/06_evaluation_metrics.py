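"""The evaluator on a constructed mini-benchmark with planted errors:
a missed object, a misclassified object, and a ghost detection.
"""

import numpy as np

from larvadet import BoxSet, confusion_matrix, summarize

gts = {
    "scene0": BoxSet(np.array([[10, 10, 70, 60], [100, 90, 180, 170.0]]),
                     np.array([1, 2])),
    "scene1": BoxSet(np.array([[30, 40, 95, 95.0]]), np.array([1])),
}
dets = {
    # scene0: class-1 found well; class-2 found but labelled class 1
    "scene0": BoxSet(np.array([[12, 11, 69, 59], [101, 92, 178, 169.0]]),
                     np.array([1, 1]), np.array([0.95, 0.80])),
    # scene1: the object is missed; a ghost box appears elsewhere
    "scene1": BoxSet(np.array([[150, 150, 200, 200.0]]),
                     np.array([2]), np.array([0.70])),
}

report = summarize(dets, gts, ["larva1", "larva2"])
print(report.table())
print()
cm = confusion_matrix(dets, gts, n_classes=2)
print("confusion matrix (rows: truth + background, cols: prediction + "
      "background, %):")
print(np.array2string(cm, precision=1, suppress_small=True))
print("(row 1: one larva1 found, one missed into the background column; "
      "row 2: the larva2 was claimed by a larva1-labelled box, an "
      "off-diagonal confusion; row 3: the ghost detection charges the "
      "background row)")
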