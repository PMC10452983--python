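"""Classify one patient's lesions and derive the growth pattern.

A patient with three target lesions measured at baseline and at the
12-week restaging scan. Each lesion is classified from its percent
change in longest diameter (responding <= -30%, progressing >= +20%,
stable in between); the patient's growth pattern comes from the best
and worst lesion class, and RECIST 1.1 from the diameter sums.
"""

import lbr12 as L

# (baseline mm, restaging mm): -30%, 0%, +20%
lesions = [(50.0, 35.0), (40.0, 40.0), (30.0, 36.0)]

classes = [L.classify_lesion(l0, l12) for l0, l12 in lesions]
pattern = L.classify_patient(classes)
s0 = sum(l0 for l0, _ in lesions)
s12 = sum(l12 for _, l12 in lesions)
recist = L.classify_recist(s0, s12)

for (l0, l12), cls in zip(lesions, classes):
    print(f"  {l0:5.1f} mm -> {l12:5.1f} mm  ({(l12 - l0) / l0:+6.1%})  {cls.name}")
print(f"growth pattern: {pattern.value}")
print(f"prevalence subclass: {L.prevalence_subclass(classes).value}")
print(f"RECIST 1.1 from sums {s0:.0f} -> {s12:.0f} mm: {recist.value}")
# One responding and one progressing lesion make this the most
# heterogeneous pattern (RL/PL) even though the sum moves only -7.5%,
# which RECIST calls stable disease.
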