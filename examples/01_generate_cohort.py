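"""Generate a labeled synthetic facial cohort with known ground truth.

Each fixture is an elliptical skin region whose pixels mix the subject's
own basic skin tone with a class-specific morbid chromaticity, plus a lip
region, moles and hair strands as nuisances.  Ground truth (skin mask,
mouth box, planted chromaticity, severity fraction) rides along, so every
downstream stage can be scored against it.
"""

import numpy as np

import complexion as cx

fixtures = cx.generate_cohort(
    {"normal": 3, "cyan": 3, "red": 3, "yellow": 3, "white": 3, "black": 3}, seed=1
)
print(f"generated {len(fixtures)} faces, {fixtures[0].image.shape} each")

for label in cx.CLASS_LABELS:
    fix = next(f for f in fixtures if f.label == label)
    lab = cx.extract_skin_pixels(fix.image, fix.skin_mask)
    a, b = lab[:, 1].mean(), lab[:, 2].mean()
    print(
        f"  {label:7s} mean L*={lab[:, 0].mean():5.1f}  mean (a*,b*)=({a:5.1f},{b:5.1f})"
        f"  skin px={fix.skin_mask.sum()}"
    )

# The mean (a*, b*) sits between the class color and the subject's basic
# tone (weighted by the severity fraction); white/black share the normal
# chromaticity and differ only in L*.
planted = np.array(cx.CLASS_AB["red"])
print(f"\nplanted red chromaticity: ({planted[0]:.0f}, {planted[1]:.0f});"
      " severity fraction defaults to 0.65 of skin pixels")
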