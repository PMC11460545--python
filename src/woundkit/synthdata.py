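"""Deterministic generator of synthetic wound photographs with ground truth.

Each scene emulates the macro structure of a clinical wound photograph: a
chromatically distinct drape background (surgical teal-green, whose a* and
Cr both sit well below skin), a large elliptical skin region with
low-frequency luminance mottling, an elliptical wound whose per-pixel color
is drawn from a mixture of red (granulating/inflamed), yellow (slough),
dark (eschar/necrotic) and pink (epithelial) tissue tones, an optional
square fiducial marker rendered at a known pixel scale, and additive
Gaussian sensor noise.

The wound's color mixture encodes the labels: a scene is flagged infected
when its yellow fraction exceeds 0.25 and ischemic when its dark fraction
exceeds 0.25.  These thresholds are generator constants that make the
labels recoverable from color statistics by construction; they are not
claims about real wound biology.  Everything is driven by a single seed,
so scenes, datasets and manifests are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .detect import BoundingBox
from .errors import InvalidInputError
from .fiducial import default_dictionary, render_marker

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "SKIN_TONES",
    "INFECTED_YELLOW_THRESHOLD",
    "ISCHEMIC_DARK_THRESHOLD",
    "generate_scene",
    "random_scene_spec",
    "iter_scenes",
    "generate_dataset",
]

# light-to-dark sRGB skin tone bases
SKIN_TONES = (
    (232, 190, 172),
    (212, 158, 128),
    (198, 134, 106),
    (160, 102, 76),
    (116, 74, 52),
    (88, 56, 42),
)

# tissue tones sampled inside the wound ellipse
_WOUND_COLORS = {
    "red": (168, 38, 36),
    "yellow": (203, 172, 74),
    "dark": (46, 33, 28),
    "pink": (226, 132, 140),
}

# background distractor tone: dark shadowed objects on the drape that
# clinical photos pick up; chromatically non-skin (a* and Cr both below the
# skin/background thresholds) so the chroma mask excludes them, while a
# detector without mask gating still fires on them
_DISTRACTOR_COLOR = (34, 62, 56)

INFECTED_YELLOW_THRESHOLD = 0.25
ISCHEMIC_DARK_THRESHOLD = 0.25


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene; the seed fixes everything."""

    height: int = 288
    width: int = 288
    skin_tone: tuple[int, int, int] = (198, 134, 106)
    mottling_amp: float = 6.0  # sd of the low-frequency luminance field, 8-bit units
    background_color: tuple[int, int, int] = (52, 110, 96)  # teal-green drape
    skin_axes_frac: tuple[float, float] = (0.36, 0.32)  # semi-axes / image size
    wound: bool = True
    wound_center: tuple[float, float] | None = None  # (x, y); None = image center
    wound_axes: tuple[float, float] = (24.0, 18.0)  # semi-axes, px
    wound_rotation_deg: float = 0.0
    f_red: float = 0.55
    f_yellow: float = 0.10
    f_dark: float = 0.10  # remainder is pink granulation
    color_jitter: float = 8.0
    noise_sigma: float = 4.0
    marker: bool = True
    marker_side_px: int = 50
    marker_position: tuple[int, int] | None = None  # top-left (x, y); None = corner
    marker_id: int = 0
    cm_per_px: float = 0.026
    distractors: int = 0  # dark non-skin blobs on the background
    seed: int = 0

    def __post_init__(self):
        fracs = (self.f_red, self.f_yellow, self.f_dark)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0 + 1e-9:
            raise InvalidInputError("mixture fractions must lie in [0, 1] and sum to at most 1")
        if self.height < 64 or self.width < 64:
            raise InvalidInputError("scene must be at least 64x64")
        if self.cm_per_px <= 0:
            raise InvalidInputError("cm_per_px must be positive")

    @property
    def infected(self) -> bool:
        return self.wound and self.f_yellow > INFECTED_YELLOW_THRESHOLD

    @property
    def ischemic(self) -> bool:
        return self.wound and self.f_dark > ISCHEMIC_DARK_THRESHOLD


@dataclass
class GroundTruth:
    skin_mask: np.ndarray
    wound_mask: np.ndarray | None
    wound_box: BoundingBox | None
    infected: bool
    ischemic: bool
    cm_per_px: float
    marker_side_px: int | None
    wound_width_cm: float | None
    wound_height_cm: float | None


def _ellipse_mask(h, w, cx, cy, ax, ay, rot_deg=0.0):
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    if rot_deg:
        t = np.deg2rad(rot_deg)
        dx, dy = dx * np.cos(t) + dy * np.sin(t), -dx * np.sin(t) + dy * np.cos(t)
    return (dx / ax) ** 2 + (dy / ay) ** 2 <= 1.0


def _fill_categorical(rng, n, spec):
    """Per-pixel tissue category indices drawn from the color mixture."""
    cut = np.cumsum([spec.f_red, spec.f_yellow, spec.f_dark])
    r = rng.random(n)
    return np.searchsorted(cut, r)  # 0=red 1=yellow 2=dark 3=pink


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene and its ground truth.

    Raises :class:`InvalidInputError` when the wound ellipse is not fully
    inside the skin region (infeasible geometry).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_color

    # skin blob with low-frequency mottling
    skin = _ellipse_mask(h, w, w / 2, h / 2,
                         spec.skin_axes_frac[0] * w, spec.skin_axes_frac[1] * h)
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=12.0)
    sd = field.std()
    if sd > 0:
        field = field / sd * spec.mottling_amp
    for c in range(3):
        img[:, :, c][skin] = spec.skin_tone[c] + field[skin]

    # wound ellipse drawn from the tissue-color mixture
    wound_mask = None
    wound_box = None
    if spec.wound:
        cx, cy = spec.wound_center if spec.wound_center is not None else (w / 2, h / 2)
        wound_mask = _ellipse_mask(h, w, cx, cy, spec.wound_axes[0], spec.wound_axes[1],
                                   spec.wound_rotation_deg)
        if not wound_mask.any():
            raise InvalidInputError("wound ellipse is empty")
        if (wound_mask & ~skin).any():
            raise InvalidInputError("wound ellipse extends beyond the skin region")
        cats = _fill_categorical(rng, int(wound_mask.sum()), spec)
        palette = np.array([_WOUND_COLORS[k] for k in ("red", "yellow", "dark", "pink")],
                           dtype=np.float64)
        colors = palette[cats] + rng.normal(0.0, spec.color_jitter, (len(cats), 3))
        img[wound_mask] = colors
        ys, xs = np.nonzero(wound_mask)
        wound_box = BoundingBox(float(xs.min()), float(ys.min()),
                                float(xs.max() + 1), float(ys.max() + 1))

    # background distractor blobs (dark neutral objects, off-skin)
    for _ in range(spec.distractors):
        for _attempt in range(50):
            bx = rng.uniform(10, w - 10)
            by = rng.uniform(10, h - 10)
            bax = rng.uniform(7, 14)
            bay = rng.uniform(7, 14)
            blob = _ellipse_mask(h, w, bx, by, bax, bay)
            if not (blob & skin).any():
                jit = rng.normal(0.0, spec.color_jitter, (int(blob.sum()), 3))
                img[blob] = np.array(_DISTRACTOR_COLOR, dtype=np.float64) + jit
                break

    # fiducial marker with a white quiet zone, rendered on top
    marker_side = None
    if spec.marker:
        side = spec.marker_side_px
        pad = max(4, side // 10)
        x0, y0 = spec.marker_position if spec.marker_position is not None else (pad, pad)
        if x0 - pad < 0 or y0 - pad < 0 or x0 + side + pad > w or y0 + side + pad > h:
            raise InvalidInputError("marker does not fit inside the scene")
        img[y0 - pad:y0 + side + pad, x0 - pad:x0 + side + pad] = 255.0
        cells = render_marker(spec.marker_id, side, default_dictionary())
        img[y0:y0 + side, x0:x0 + side] = cells[:, :, None].astype(np.float64)
        marker_side = side

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    gt = GroundTruth(
        skin_mask=skin,
        wound_mask=wound_mask,
        wound_box=wound_box,
        infected=spec.infected,
        ischemic=spec.ischemic,
        cm_per_px=spec.cm_per_px,
        marker_side_px=marker_side,
        wound_width_cm=wound_box.width * spec.cm_per_px if wound_box else None,
        wound_height_cm=wound_box.height * spec.cm_per_px if wound_box else None,
    )
    return img, gt


def random_scene_spec(
    rng: np.random.Generator,
    infected: bool = False,
    ischemic: bool = False,
    marker: bool = True,
    distractors: int = 0,
    size: int = 288,
    wound: bool = True,
) -> SceneSpec:
    """Draw a randomized scene specification with the requested labels.

    Mixture fractions are sampled on the correct side of the label
    thresholds with a margin, so flags are unambiguous.
    """
    if infected and ischemic:  # keep room for both dominant tissues
        f_yellow = rng.uniform(0.30, 0.45)
        f_dark = rng.uniform(0.30, 0.45)
    else:
        f_yellow = rng.uniform(0.35, 0.60) if infected else rng.uniform(0.0, 0.12)
        f_dark = rng.uniform(0.35, 0.60) if ischemic else rng.uniform(0.0, 0.12)
    remaining = 1.0 - f_yellow - f_dark
    if remaining >= 0.25:
        f_red = rng.uniform(0.25, min(0.60, remaining))
    else:
        f_red = remaining * rng.uniform(0.5, 0.9)
    scale = size / 288.0  # wound geometry scales with the frame
    cx = size / 2 + rng.uniform(-18, 18) * scale
    cy = size / 2 + rng.uniform(-18, 18) * scale
    return SceneSpec(
        height=size,
        width=size,
        skin_tone=SKIN_TONES[rng.integers(len(SKIN_TONES))],
        wound=wound,
        wound_center=(cx, cy) if wound else None,
        wound_axes=(rng.uniform(16, 30) * scale, rng.uniform(12, 24) * scale),
        wound_rotation_deg=float(rng.uniform(0, 180)),
        f_red=float(min(f_red, 1.0 - f_yellow - f_dark)),
        f_yellow=float(f_yellow),
        f_dark=float(f_dark),
        marker=marker,
        distractors=distractors,
        seed=int(rng.integers(2 ** 31)),
    )


def _label_plan(n, infected_frac, ischemic_frac, rng):
    """Exact flag counts (round(n * frac) each), assigned independently."""
    n_inf = round(n * infected_frac)
    n_isch = round(n * ischemic_frac)
    if n_inf > n or n_isch > n:
        raise InvalidInputError("label fractions exceed the dataset size")
    inf = np.zeros(n, dtype=bool)
    inf[rng.choice(n, n_inf, replace=False)] = True
    isch = np.zeros(n, dtype=bool)
    isch[rng.choice(n, n_isch, replace=False)] = True
    return list(zip(inf.tolist(), isch.tolist()))


def iter_scenes(
    n: int,
    infected_frac: float = 0.3,
    ischemic_frac: float = 0.1,
    seed: int = 0,
    marker: bool = True,
    distractors: int = 0,
    size: int = 288,
):
    """Yield ``(index, image, ground_truth, spec)`` for n randomized scenes
    with exact label counts (round(n * frac) scenes per flag)."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    flags = _label_plan(n, infected_frac, ischemic_frac, rng)
    for i, (inf, isch) in enumerate(flags):
        spec = random_scene_spec(rng, infected=inf, ischemic=isch, marker=marker,
                                 distractors=distractors, size=size)
        img, gt = generate_scene(spec)
        yield i, img, gt, spec


def generate_dataset(
    n: int,
    infected_frac: float = 0.3,
    ischemic_frac: float = 0.1,
    seed: int = 0,
    out_dir=None,
    marker: bool = True,
    distractors: int = 0,
    size: int = 288,
) -> dict:
    """Generate a labeled scene collection; optionally write it to disk.

    With ``out_dir`` set, writes ``scene_####.png`` images, ``gt.json``
    (COCO-style wound boxes), ``labels.csv`` and ``manifest.yaml``; two runs
    with the same arguments produce byte-identical files.  Returns the
    manifest dictionary either way.
    """
    records = []
    writers = None
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        writers = out_dir
    per_image_boxes = {}
    sizes = {}
    for i, img, gt, spec in iter_scenes(n, infected_frac, ischemic_frac, seed,
                                        marker, distractors, size):
        name = f"scene_{i:04d}.png"
        rec = {
            "file": name,
            "seed": spec.seed,
            "infected": bool(gt.infected),
            "ischemic": bool(gt.ischemic),
            "f_red": round(spec.f_red, 6),
            "f_yellow": round(spec.f_yellow, 6),
            "f_dark": round(spec.f_dark, 6),
            "cm_per_px": spec.cm_per_px,
            "wound_box": ([gt.wound_box.x_min, gt.wound_box.y_min,
                           gt.wound_box.x_max, gt.wound_box.y_max]
                          if gt.wound_box else None),
        }
        records.append(rec)
        if writers is not None:
            from .detect import Detection
            from .image import write_image

            write_image(writers / name, img)
            per_image_boxes[name] = [Detection(gt.wound_box)] if gt.wound_box else []
            sizes[name] = (spec.width, spec.height)
    manifest = {
        "n": n,
        "seed": seed,
        "infected_frac": infected_frac,
        "ischemic_frac": ischemic_frac,
        "size": size,
        "marker": marker,
        "distractors": distractors,
        "scenes": records,
    }
    if writers is not None:
        import json

        import pandas as pd
        import yaml

        from .annotations import save_coco_json

        save_coco_json(writers / "gt.json", per_image_boxes, sizes)
        pd.DataFrame(
            [{"file": r["file"], "infected": int(r["infected"]), "ischemic": int(r["ischemic"])}
             for r in records]
        ).to_csv(writers / "labels.csv", index=False)
        (writers / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest
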