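"""The four evaluation metrics on a worked example.

Two 2x2 squares offset by one column overlap in 2 of their 4 voxels:
DSC = 2*2/(4+4) = 0.5 and JI = 2/6.  ASD and HD are computed in mm from
the surface voxels (6-connectivity boundary) under anisotropic spacing.
"""

import numpy as np

from slicechain import asd, dsc, hd, jaccard, paired_t

a = np.zeros((1, 4, 4), dtype=bool)
b = np.zeros((1, 4, 4), dtype=bool)
a[0, 1:3, 0:2] = True
b[0, 1:3, 1:3] = True

spacing = (2.5, 0.98, 0.98)
print(f"DSC = {dsc(a, b):.4f}   (expected 0.5)")
print(f"JI  = {jaccard(a, b):.4f}   (expected 2/6 = 0.3333)")
print(f"ASD = {asd(a, b, spacing):.4f} mm")
print(f"HD  = {hd(a, b, spacing):.4f} mm")

# paired comparison across cases: per-case metric differences
t, p = paired_t([0.04, 0.05, 0.03, 0.06, 0.02])
print(f"paired t-test on per-case DSC differences: t = {t:.3f}, p = {p:.4f}")
print("(a small p indicates a systematic difference between the two methods)")
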