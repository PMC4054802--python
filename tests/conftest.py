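"""Shared fixtures: small synthetic cohorts run once per session.

The heavier pipeline products (cleaned pixel sets, bases) are computed once
and reused across test modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import complexion as cx

REDUCED_C_GRID = [2.0**e for e in range(-8, 16, 4)]
REDUCED_GAMMA_GRID = [2.0**e for e in range(-8, 9, 4)]


@pytest.fixture(scope="session")
def default_cohort():
    """Four subjects per class, default effect sizes, full skin pipeline."""
    fixtures = cx.generate_cohort({l: 4 for l in cx.CLASS_LABELS}, seed=5)
    pix, masks = [], []
    for f in fixtures:
        lab, mask = cx.skin_pipeline(f.image, f.mouth_box)
        pix.append(lab)
        masks.append(mask)
    labels = [f.label for f in fixtures]
    return {"fixtures": fixtures, "pixels": pix, "masks": masks, "labels": labels}


@pytest.fixture(scope="session")
def default_bases(default_cohort):
    cohort = {
        lab: [
            p
            for p, l in zip(default_cohort["pixels"], default_cohort["labels"])
            if l == lab
        ]
        for lab in cx.BASE_CLASS_LABELS
    }
    return cx.build_all_bases(cohort, seed=0)


@pytest.fixture(scope="session")
def gradient_cohort():
    """Degree-gradient cohort (known color/gloss rankings), ground-truth masks."""
    fixtures = cx.generate_cohort(
        {l: 10 for l in cx.CLASS_LABELS}, degree_gradient=True, seed=17
    )
    pix = [
        cx.denoise_extremes(cx.extract_skin_pixels(f.image, f.skin_mask))
        for f in fixtures
    ]
    return {"fixtures": fixtures, "pixels": pix, "labels": [f.label for f in fixtures]}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
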