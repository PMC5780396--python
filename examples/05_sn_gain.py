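"""Contrast gain of GD activity mapping over brightfield speckle.

Simulates scenes of one nematode in increasingly cluttered static media,
reads the same transect through the animal from a raw frame and from the
GD map, and reports the signal-to-noise ratio of each arm plus the fold
improvement.
"""

from bspim import run_sn_experiment, sn_fold_change

pairs, details = run_sn_experiment(n_scenes=6, seed=1)
print(details[["scene", "clutter_sd", "sn_brightfield", "sn_gd", "fold"]]
      .to_string(index=False, float_format=lambda v: f"{v:8.2f}"))

summary = sn_fold_change(pairs)
print(f"\nfold improvement: mean = {summary.mean:.1f} (SE = {summary.se:.1f}), "
      f"max = {summary.max:.1f} over {summary.n_pairs} scenes")
# Brightfield S/N is limited by static speckle clutter (contrast ~ 1);
# the GD map suppresses everything temporally constant, so its S/N is one
# to two orders of magnitude higher on the same transect.
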