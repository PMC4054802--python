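"""Synthetic facial fixtures with known ground truth.

Clinical facial-color photographs cannot be redistributed, so every stage of
the pipeline is exercised on generated faces instead.  A fixture is an
elliptical "skin" region on a dark background whose pixels are drawn in
CIELAB as a two-component mixture:

* a *class color* component at ``planted_ab`` — the morbid chromaticity
  shared (up to a small per-subject jitter) by all subjects of a class, and
* a *basic skin* component at ``basic_ab`` — the subject's own skin tone,
  which varies between subjects.

``minor_fraction`` is the weight of the class-color component; below 0.5 the
morbid color is the minor pixel cluster, which is exactly the regime the
two-level clustering of base construction exists to handle.  Luminance is
Gaussian around ``luminance_mean`` (white/black classes reuse the normal
chromaticity and differ only here).  Dark moles, hair strands and a lip
region of skin-overlapping chromaticity are planted as realistic nuisances.

All randomness flows from ``FaceSpec.seed``; a fixture is byte-identical on
repeated generation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .colorspace import lab_to_rgb

__all__ = [
    "CLASS_LABELS",
    "BASE_CLASS_LABELS",
    "CLASS_AB",
    "BASIC_AB",
    "CLASS_LUMINANCE",
    "PAPER_COHORT",
    "FaceSpec",
    "FaceFixture",
    "generate_face",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

#: Canonical six-class order used everywhere downstream.
CLASS_LABELS = ("normal", "cyan", "red", "yellow", "white", "black")

#: The four classes that get a chromaticity base.
BASE_CLASS_LABELS = ("normal", "cyan", "red", "yellow")

#: Planted (a, b) chromaticity centers.  Mutually separated by >= 10 units in
#: the ab-plane; white/black reuse the normal chromaticity (their gamut
#: overlaps the others — only luminance separates them).
CLASS_AB = {
    "normal": (14.0, 16.0),
    "cyan": (0.0, 4.0),
    "red": (26.0, 16.0),
    "yellow": (12.0, 32.0),
    "white": (14.0, 16.0),
    "black": (14.0, 16.0),
}

#: Population-level basic skin tone around which per-subject tones scatter.
BASIC_AB = (14.0, 16.0)

#: Default mean L* per class.  White and black sit at the tails.
CLASS_LUMINANCE = {
    "normal": 60.0,
    "cyan": 58.0,
    "red": 56.0,
    "yellow": 62.0,
    "white": 65.0,
    "black": 42.0,
}

#: Class counts of the study cohort emulated by :func:`generate_cohort`.
PAPER_COHORT = {
    "normal": 24,
    "cyan": 15,
    "red": 18,
    "yellow": 24,
    "white": 21,
    "black": 20,
}

#: Per-subject chroma draws are clamped to these (a, b) boxes so that every
#: subject's pixel distribution stays inside the RGB gamut at its class
#: luminance.  The white (pale) class is bright, so its box is tight — pale
#: faces are desaturated by definition.
_SAFE_AB_BOX = {
    "white": ((8.0, 16.0), (10.0, 18.0)),
    None: ((2.0, 24.0), (4.0, 26.0)),
}

_LIP_LAB = (46.0, 34.0, 16.0)  # overlaps the red/skin chromaticity gamut
_ARTIFACT_LAB = (10.0, 3.0, 4.0)  # near-black moles / hair
_BACKGROUND_RGB = (18.0, 22.0, 30.0)  # dark bluish backdrop, distinct LO locus


@dataclass
class FaceSpec:
    """Full parameterization of one synthetic face."""

    class_label: str
    planted_ab: tuple[float, float] | None = None
    basic_ab: tuple[float, float] = BASIC_AB
    ab_spread: float = 4.0
    luminance_mean: float | None = None
    luminance_sd: float = 6.0
    minor_fraction: float = 0.65
    artifact_counts: tuple[int, int] = (3, 2)  # (moles, hair strands)
    image_size: tuple[int, int] = (96, 96)
    seed: int = 0
    tint_region: str | None = None  # None or "cheeks"

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.planted_ab is None:
            self.planted_ab = CLASS_AB[self.class_label]
        if self.luminance_mean is None:
            self.luminance_mean = CLASS_LUMINANCE[self.class_label]
        if not 0.0 < self.minor_fraction <= 1.0:
            raise ValueError("minor_fraction must lie in (0, 1]")
        if not 0.0 <= self.luminance_mean <= 100.0:
            raise ValueError("luminance_mean must lie in [0, 100]")


@dataclass
class FaceFixture:
    """A generated face plus its ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    skin_mask: np.ndarray  # (H, W) bool; excludes background and mouth box
    mouth_box: tuple[int, int, int, int]  # (row0, col0, row1, col1)
    spec: FaceSpec

    @property
    def label(self) -> str:
        return self.spec.class_label

    @property
    def true_color_degree(self) -> float:
        """Ground-truth ordering statistic for color degree (class-color
        pixel fraction)."""
        return self.spec.minor_fraction

    @property
    def true_gloss_degree(self) -> float:
        """Ground-truth ordering statistic for gloss degree (mean L*)."""
        return self.spec.luminance_mean


def _face_geometry(h: int, w: int):
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = 0.5 * h, 0.5 * w
    ellipse = ((yy - cy) / (0.46 * h)) ** 2 + ((xx - cx) / (0.40 * w)) ** 2 <= 1.0
    mouth_box = (
        int(round(0.70 * h)),
        int(round(0.38 * w)),
        int(round(0.84 * h)),
        int(round(0.62 * w)),
    )
    cheeks = np.zeros((h, w), dtype=bool)
    cheeks[int(0.42 * h):int(0.62 * h), int(0.14 * w):int(0.34 * w)] = True
    cheeks[int(0.42 * h):int(0.62 * h), int(0.66 * w):int(0.86 * w)] = True
    return ellipse, mouth_box, cheeks & ellipse


def generate_face(spec: FaceSpec) -> FaceFixture:
    """Render one fixture from its spec.

    Skin pixels are sampled in Lab and mapped to 8-bit RGB through the
    analytic Lab->RGB inverse; an error is raised if more than 1% of skin
    samples fall outside the RGB gamut.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    ellipse, mouth_box, cheeks = _face_geometry(h, w)
    n = int(ellipse.sum())

    # Component assignment: class color vs basic skin.
    if spec.tint_region == "cheeks":
        is_planted = cheeks[ellipse]
        rng.random(n)  # keep the random stream aligned with the default path
    elif spec.tint_region is None:
        is_planted = rng.random(n) < spec.minor_fraction
    else:
        raise ValueError(f"unknown tint_region {spec.tint_region!r}")

    centers = np.where(
        is_planted[:, None],
        np.asarray(spec.planted_ab, dtype=float),
        np.asarray(spec.basic_ab, dtype=float),
    )
    ab = centers + rng.normal(0.0, spec.ab_spread, size=(n, 2))
    L = np.clip(rng.normal(spec.luminance_mean, spec.luminance_sd, size=n), 5.0, 98.0)
    lab = np.column_stack([L, ab])
    skin_rgb, n_clipped = lab_to_rgb(lab)
    if n_clipped > 0.01 * n:
        raise ValueError(
            f"planted Lab distribution leaves the RGB gamut: {n_clipped}/{n} "
            f"skin samples clipped (mean L={L.mean():.1f}, "
            f"mean a={ab[:, 0].mean():.1f}, mean b={ab[:, 1].mean():.1f})"
        )

    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(_BACKGROUND_RGB) / 255.0
    img += rng.normal(0.0, 5.0 / 255.0, size=img.shape)
    img[ellipse] = skin_rgb

    # Lip region: an ellipse inside the mouth box, chromaticity overlapping skin.
    r0, c0, r1, c1 = mouth_box
    yy, xx = np.mgrid[0:h, 0:w]
    lip = (
        ((yy - 0.5 * (r0 + r1)) / (0.45 * (r1 - r0))) ** 2
        + ((xx - 0.5 * (c0 + c1)) / (0.45 * (c1 - c0))) ** 2
        <= 1.0
    )
    lip &= ellipse
    lip_lab = np.asarray(_LIP_LAB) + rng.normal(0.0, 2.0, size=(int(lip.sum()), 3))
    img[lip] = lab_to_rgb(lip_lab)[0]

    # Artifacts: dark moles (small disks) and hair strands (thin lines near
    # the top of the face).  They stay inside the skin mask; luminance
    # denoising is what removes them downstream.
    n_moles, n_hair = spec.artifact_counts
    artifact = np.zeros((h, w), dtype=bool)
    for _ in range(n_moles):
        ry = rng.integers(int(0.25 * h), int(0.65 * h))
        rx = rng.integers(int(0.25 * w), int(0.75 * w))
        rad = int(rng.integers(1, 3))
        artifact |= (yy - ry) ** 2 + (xx - rx) ** 2 <= rad**2
    for _ in range(n_hair):
        x_start = rng.integers(int(0.3 * w), int(0.7 * w))
        slope = rng.uniform(-0.5, 0.5)
        for t in range(int(0.12 * h)):
            ry = int(0.09 * h) + t
            rx = int(x_start + slope * t)
            if 0 <= ry < h and 0 <= rx < w:
                artifact[ry, rx] = True
    artifact &= ellipse
    if artifact.any():
        art_lab = np.asarray(_ARTIFACT_LAB) + rng.normal(
            0.0, 1.0, size=(int(artifact.sum()), 3)
        )
        img[artifact] = lab_to_rgb(art_lab)[0]

    image8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)

    mask = ellipse.copy()
    mask[r0:r1, c0:c1] = False  # ground truth excludes the mouth box
    return FaceFixture(image=image8, skin_mask=mask, mouth_box=mouth_box, spec=spec)


def generate_cohort(
    class_counts: dict[str, int],
    degree_gradient: bool = False,
    seed: int = 0,
    *,
    basic_sd: float = 3.0,
    subject_ab_jitter: float = 1.0,
    minor_fraction: float | None = None,
    degree_range: tuple[float, float] = (0.35, 0.9),
    luminance_halfwidth: float = 4.0,
    **spec_overrides,
) -> list[FaceFixture]:
    """Generate a labeled cohort with per-subject variation.

    Each subject draws its basic skin tone from N(BASIC_AB, basic_sd) and a
    small jitter on the class color, emulating inter-subject variation.
    With ``degree_gradient`` the class-color fraction sweeps ``degree_range``
    and the luminance mean sweeps +-``luminance_halfwidth`` linearly across
    the subjects of each class, so the true color/gloss rankings are known
    by construction.  ``minor_fraction`` overrides the default fraction for
    every subject (ignored under ``degree_gradient``).
    """
    if not class_counts:
        raise ValueError("empty cohort request")
    for label, count in class_counts.items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        if count < 1:
            raise ValueError(f"need at least one subject per requested class ({label})")

    master = np.random.SeedSequence(seed)
    fixtures: list[FaceFixture] = []
    for label in CLASS_LABELS:
        if label not in class_counts:
            continue
        n = class_counts[label]
        class_ss = master.spawn(1)[0]
        rng = np.random.default_rng(class_ss)
        subject_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in class_ss.spawn(n)]
        (a_lo, a_hi), (b_lo, b_hi) = _SAFE_AB_BOX.get(label, _SAFE_AB_BOX[None])
        box_lo, box_hi = np.array([a_lo, b_lo]), np.array([a_hi, b_hi])
        for i in range(n):
            basic = tuple(
                np.clip(np.asarray(BASIC_AB) + rng.normal(0.0, basic_sd, 2), box_lo, box_hi)
            )
            planted = tuple(
                np.clip(
                    np.asarray(CLASS_AB[label]) + rng.normal(0.0, subject_ab_jitter, 2),
                    np.minimum(box_lo, CLASS_AB[label]),
                    np.maximum(box_hi, CLASS_AB[label]),
                )
            )
            mf = 0.65 if minor_fraction is None else minor_fraction
            lum = CLASS_LUMINANCE[label]
            if degree_gradient and n > 1:
                frac = i / (n - 1)
                mf = degree_range[0] + frac * (degree_range[1] - degree_range[0])
                lum = lum - luminance_halfwidth + 2 * luminance_halfwidth * frac
            spec = FaceSpec(
                class_label=label,
                planted_ab=planted,
                basic_ab=basic,
                minor_fraction=mf,
                luminance_mean=lum,
                seed=subject_seeds[i],
                **spec_overrides,
            )
            fixtures.append(generate_face(spec))
    return fixtures


# ---------------------------------------------------------------------------
# On-disk fixture format: PNG image + single-channel PNG mask + JSON sidecar
# per subject, and a manifest CSV for the cohort.
# ---------------------------------------------------------------------------

def write_cohort(fixtures: list[FaceFixture], outdir) -> Path:
    """Write fixtures as PNGs with JSON sidecars plus a manifest CSV.

    Returns the manifest path.
    """
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, fix in enumerate(fixtures):
        stem = f"{i:04d}_{fix.label}"
        img_path = outdir / f"{stem}.png"
        Image.fromarray(fix.image).save(img_path)
        Image.fromarray((fix.skin_mask * 255).astype(np.uint8)).save(
            outdir / f"{stem}_mask.png"
        )
        sidecar = {
            "label": fix.label,
            "mouth_box": list(fix.mouth_box),
            "seed": fix.spec.seed,
            "true_color_degree": fix.true_color_degree,
            "true_gloss_degree": fix.true_gloss_degree,
            "spec": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(fix.spec).items()
            },
        }
        (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
        rows.append(f"{img_path.name},{fix.label}")
    manifest = outdir / "manifest.csv"
    manifest.write_text("path,label\n" + "\n".join(rows) + "\n")
    return manifest


def load_cohort(manifest_path) -> list[FaceFixture]:
    """Load a cohort previously written by :func:`write_cohort`."""
    from PIL import Image

    manifest_path = Path(manifest_path)
    outdir = manifest_path.parent
    fixtures = []
    lines = manifest_path.read_text().strip().splitlines()[1:]
    for line in lines:
        name, _label = line.split(",", 1)
        stem = name[: -len(".png")]
        sidecar = json.loads((outdir / f"{stem}.json").read_text())
        spec_dict = sidecar["spec"]
        spec = FaceSpec(
            **{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in spec_dict.items()
            }
        )
        image = np.asarray(Image.open(outdir / name).convert("RGB"))
        mask = np.asarray(Image.open(outdir / f"{stem}_mask.png")) > 127
        fixtures.append(
            FaceFixture(
                image=image,
                skin_mask=mask,
                mouth_box=tuple(sidecar["mouth_box"]),
                spec=spec,
            )
        )
    return fixtures
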