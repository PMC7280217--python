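"""Map stimulus greys to arena luminance and compute double-cone signals.

The calibration anchors come from the experiment: the darkest printed
grey measured 13 cd/m^2 in the arena and the lightest 216 cd/m^2.  The
effective (in-arena) Michelson contrast of a full-range pattern is
therefore (216-13)/(216+13) ~= 0.886, not 1.0 — printing and arena
lighting compress the physical contrast available to the birds.

The double-cone luminance integrates reflectance x illuminant x
sensitivity over 350-800 nm; the packaged curves are synthetic
stand-ins with plausible shapes (see their docstrings).
"""

import numpy as np

from apostim import (
    CalibrationCurve,
    double_cone_luminance,
    grey_to_luminance,
    load_arena_illuminant,
    load_double_cone_sensitivity,
)

curve = CalibrationCurve()  # linear, anchored at 13 and 216 cd/m^2
for grey in (0.0, 0.425, 0.5, 0.575, 1.0):
    print(f"grey {grey:5.3f} -> {grey_to_luminance(grey, curve):6.1f} cd/m^2")

lum_lo, lum_hi = grey_to_luminance(0.0, curve), grey_to_luminance(1.0, curve)
print(f"\neffective arena Michelson of a full-range pattern: "
      f"{(lum_hi - lum_lo) / (lum_hi + lum_lo):.3f}")

sens = load_double_cone_sensitivity()
wl, illum = load_arena_illuminant()
flat_grey = 0.5 * np.ones_like(sens.wavelengths)
white = np.ones_like(sens.wavelengths)
q_grey = double_cone_luminance(flat_grey, (wl, illum), sens)
q_white = double_cone_luminance(white, (wl, illum), sens)
print(f"double-cone catch, mid-grey vs white surface: "
      f"{q_grey:.1f} vs {q_white:.1f} (ratio {q_grey / q_white:.2f})")
print("The ratio is exactly 0.50: the luminance signal is linear in reflectance.")
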