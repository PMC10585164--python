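"""Run the CT preparation chain on a synthetic raw slice.

A raw scanner-integer slice is converted to Hounsfield units with the
header rescale, windowed at WW 160 / WL 80 (the soft-tissue brain
window), contrast-equalized with CLAHE and min-max normalized; a paired
augmentation then applies one random affine to image and mask together.
"""

import numpy as np

from lobeseg import preprocess as P

rng = np.random.default_rng(0)
raw = rng.integers(900, 1400, (64, 64)).astype(float)  # scanner integers
ct = P.CTSlice(raw, "raw", spacing=(0.8, 0.8), rescale=(1.0, -1024.0))

hu = P.to_hu(ct)
print(f"HU range         [{hu.pixels.min():.0f}, {hu.pixels.max():.0f}]")
win = P.window(hu)  # WW 160 / WL 80 -> clip to [0, 160] -> [0, 1]
print(f"windowed range   [{win.pixels.min():.3f}, {win.pixels.max():.3f}]")
eq = P.adaptive_equalize(win)
out = P.normalize01(eq)
print(f"final stage      {out.stage}, range [{out.pixels.min():.3f}, {out.pixels.max():.3f}]")

mask = np.zeros((64, 64), dtype=np.uint8)
mask[20:30, 25:35] = 1
spec = P.AugmentSpec(seed=3)
pairs = P.augment_pair(out.pixels, mask, spec, n=3)
print(f"augmented copies {len(pairs)}; mask stays crisp:",
      all(set(np.unique(m)) <= {0, 1} for _, m in pairs))
print("foreground px per copy:", [int(m.sum()) for _, m in pairs],
      "(area changes only through zoom, never interpolation blur)")
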