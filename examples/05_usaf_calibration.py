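"""USAF 1951 resolution arithmetic and pixel-scale estimation.

Element E of group G on a USAF target has spatial frequency
2^(G+(E-1)/6) line pairs/mm; the reciprocal (in um) is the
centre-to-centre line distance.  Measuring the bar period in pixels on
a captured profile then yields the pixel scale of the optics.
"""

import numpy as np

from trackscope.calibration import (
    LineProfile,
    UsafIndex,
    brightness_percent,
    estimate_pixel_scale,
    usaf_lp_per_mm,
    usaf_resolution_um,
)

for group, element, objective in [(4, 6, "4x"), (6, 6, "10x")]:
    idx = UsafIndex(group, element)
    print(
        f"Group {group} Element {element} ({objective} objective): "
        f"{usaf_lp_per_mm(idx):.2f} LP/mm, {usaf_resolution_um(idx):.2f} um line spacing"
    )

# synthetic profile across G4E6 bars imaged at a 20 px period
period_px = 20
profile = LineProfile.from_array(([220.0] * 10 + [40.0] * 10) * 4)
scale = estimate_pixel_scale(profile, UsafIndex(4, 6))
print(f"\nbar period {period_px} px -> pixel scale {scale:.3f} um/px "
      f"(true: {usaf_resolution_um(UsafIndex(4, 6)) / period_px:.3f})")

frame = np.full((480, 640), 150, dtype=np.uint8)
print(f"illumination check: mean brightness {brightness_percent(frame):.2f}% of full scale")
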