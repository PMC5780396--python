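"""Simulate a ground-truth cuvette scan and write it to disk.

Builds a 1 cm^2 cuvette scene holding five live nematodes, scans it with a
1 mm light sheet stepped by 125 um (64 frames at 10 fps per position), and
writes the per-position TIFF stacks plus manifest and truth table.
"""

from bspim import make_scene, simulate_scan, write_scan
from bspim.evaluate import CUVETTE_GEOMETRY, EXPERIMENT_ACQ

scene = make_scene(5, geometry=CUVETTE_GEOMETRY, seed=42)
scan = simulate_scan(scene, EXPERIMENT_ACQ)
write_scan(scan, "scratch/example_scan")

print(f"wrote {scan.n_positions} positions of {scan.acquisition.frames_per_position} frames each")
for i, nem in enumerate(scene.nematodes):
    x, y, z = nem.centroid_um
    print(f"  nematode {i}: ({x:6.0f}, {y:6.0f}, {z:6.0f}) um, "
          f"{nem.length_um:4.0f} um long, {'live' if nem.alive else 'dead'}")
# Each line is the exact ground-truth position and state of one animal;
# the scan directory is what the detection pipeline consumes.
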