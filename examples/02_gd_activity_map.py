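"""Compute a generalized-differences activity map for one stack.

Simulates a single-position stack containing one live nematode in a static
speckle background and compares GD values inside and outside the animal:
static speckle accumulates only read-noise differences while the
decorrelating body sums large frame-to-frame changes.
"""

import numpy as np

from bspim import GridGeometry, AcquisitionConfig, generalized_differences, make_scene, simulate_scan

geometry = GridGeometry(grid_shape=(128, 128, 1), voxel_size_xy=39.0625)
scene = make_scene(1, geometry=geometry, seed=7, z_margin_um=0.0)
scan = simulate_scan(scene, AcquisitionConfig(n_positions=1))

gd = generalized_differences(scan.stacks[0])
nem = scene.nematodes[0]
r = int(round(nem.centroid_um[1] / geometry.voxel_size_xy))
c = int(round(nem.centroid_um[0] / geometry.voxel_size_xy))

print(f"GD at the nematode centroid : {gd.values[r, c]:9.0f}")
print(f"GD median over the image    : {np.median(gd.values):9.0f}")
print(f"activity contrast           : {gd.values[r, c] / np.median(gd.values):9.1f}x")
# The body's summed absolute differences exceed the static background's
# noise floor by two orders of magnitude - that contrast is what makes
# label-free detection possible.
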