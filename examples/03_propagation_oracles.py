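"""The sequential-iterative inference loop with oracle models.

An identity oracle (returns the current contour unchanged) is a fixed
point of the loop: the seed disk is carried verbatim to every slice.
A shrinking oracle erodes the contour one pixel per step, so the
area-stop rule (fewer than 10 voxels, twice in a row) eventually halts
the propagation.
"""

import numpy as np
from scipy import ndimage

from slicechain import CTVolume, PropagationConfig, propagate

yy, xx = np.mgrid[0:64, 0:64]
seed = (yy - 32) ** 2 + (xx - 32) ** 2 <= 8**2
vol = CTVolume(np.zeros((24, 64, 64), dtype=np.float32), (2.5, 0.98, 0.98))


class IdentityOracle:
    def predict(self, inp):
        return inp.current_mask.astype(np.float64)


class ShrinkingOracle:
    def predict(self, inp):
        return ndimage.binary_erosion(inp.current_mask > 0.5).astype(np.float64)


res = propagate(IdentityOracle(), vol, seed, seed_index=0, cfg=PropagationConfig())
print(f"identity oracle: visited {len(res.visited)} slices, stop = {res.stop_reason}")
print(f"  every slice equals the seed: {all((res.mask.voxels[j] == seed).all() for j in res.visited)}")

res = propagate(ShrinkingOracle(), vol, seed, seed_index=0,
                cfg=PropagationConfig(stop_min_voxels=10, stop_patience=2))
print(f"shrinking oracle: visited {len(res.visited)} slices, stop = {res.stop_reason}")
print(f"  per-slice areas: {[res.voxel_counts[j] for j in res.visited]}")
print("  (the loop halts after two consecutive slices fall below 10 voxels)")
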