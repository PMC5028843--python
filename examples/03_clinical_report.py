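"""Compute the eight clinical skeletal parameters and their classes.

From 19 landmark positions the package derives ANB/SNB/SNA (jaw-relation
angles at the nasion), ODI and APDI (sums of inter-line angles), FHI
(posterior/anterior face-height ratio), FMA (Frankfurt mandibular angle)
and MW (modified Wits appraisal, signed mm), and assigns each to a
skeletal-malformation class (C1 = normal range).
"""

from cephaloc import LandmarkSet, classify, compute_parameters, make_template

# the synthetic template is built to be a "normal" subject
lm = LandmarkSet(points=make_template() * 2.4, spacing=0.4)  # px at 0.4 mm/px
values = compute_parameters(lm)
classes = classify(values)

units = {"FHI": "", "MW": " mm"}
for name in values:
    unit = units.get(name, "\N{DEGREE SIGN}")
    print(f"{name:5s} = {values[name]:7.2f}{unit}   class {classes[name]}")
print("\nC1 means the value lies in the normal range; C2/C3 (and C4/C5 for "
      "MW) flag malformations on either side of it.")
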