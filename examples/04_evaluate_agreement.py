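"""Agreement statistics between two annotation sets.

Compares a "manual" annotation set (the synthetic ground truth) with a
perturbed copy standing in for an automatic system: point-to-point errors
(PE, per-landmark PEL, per-image PEI), successful detection rates (SDR) at
the usual precision ranges, and classification agreement (SCR / confusion)
for one clinical parameter.
"""

import numpy as np

from cephaloc import (LandmarkSet, SyntheticSpec, classify, compute_parameters,
                      error_matrix, sample_case, scr_confusion, sdr, summarise)

spec = SyntheticSpec(n=15, seed=3)
manual = [sample_case(spec, i).truth for i in range(15)]
rng = np.random.default_rng(0)
auto = [LandmarkSet(points=m.points + rng.normal(0, 2.5, m.points.shape),
                    spacing=m.spacing) for m in manual]

errs = error_matrix(manual, auto)            # (n images, 19 landmarks), mm
s = summarise(errs)
print(f"PE  = {s.pe:.2f} +/- {s.pe_se:.2f} mm  (overall mean point error)")
print(f"PEL range over landmarks: {s.pel.min():.2f} - {s.pel.max():.2f} mm")
print(f"95th percentile PEI: {np.percentile(s.pei, 95):.2f} mm "
      "(per-image mean error)")

table = sdr(errs)
print("\nSDR (percentage of images with a landmark within z mm):")
print(table.loc[["L1", "L10", "average"]].round(1))

m_cls = [classify(compute_parameters(lm))["ANB"] for lm in manual]
a_cls = [classify(compute_parameters(lm))["ANB"] for lm in auto]
res = scr_confusion(m_cls, a_cls)
print(f"\nANB classification accuracy: {res['accuracy']:.0f}% "
      "(diagonal of the confusion matrix gives the per-class SCR)")
print(res["counts"])
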