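"""Measure a wound physically and characterize its color and texture.

Renders a scene with the 1.3 cm calibration marker at a known pixel scale,
recovers the cm/px ratio from the detected marker, converts the wound box
to centimeters, and reports the seven-color composition and surface
roughness of the wound crop.
"""

from woundkit.characterize import (
    color_composition,
    detect_marker,
    pixel_to_metric,
    roughness,
    wound_size,
)
from woundkit.detect import crop_wound
from woundkit.synthdata import SceneSpec, generate_scene

spec = SceneSpec(seed=7, f_red=0.35, f_yellow=0.45, f_dark=0.05)
img, gt = generate_scene(spec)

obs = detect_marker(img)
ratio = pixel_to_metric(obs)
print(f"marker: {obs.side_length_px:.1f} px side -> {ratio*10:.3f} mm/px "
      f"(generator truth {spec.cm_per_px*10:.3f} mm/px)")

m = wound_size(gt.wound_box, ratio)
w, h = m.rounded()
print(f"wound size: {w} x {h} cm (truth {gt.wound_width_cm:.2f} x {gt.wound_height_cm:.2f} cm)")
# agreement within 0.1 cm: the marker calibrates pixels to centimeters

crop = crop_wound(img, gt.wound_box, pad_fraction=0.1)
comp = color_composition(crop, seed=0)
print("color composition (top 4):")
for entry in comp.entries[:4]:
    print(f"  {entry.hex}  {entry.percent:5.1f}%")
# with f_yellow=0.45 the yellow slough tone dominates the wound interior,
# consistent with the infected label

rough = roughness(crop)
print(f"roughness: Ra={rough.ra:.2f}, Rq={rough.rq:.2f} (L* units)")
# Rq summarizes height variation of the smoothed lightness surface;
# a perfectly uniform crop would give 0
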