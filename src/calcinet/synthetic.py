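"""Synthetic mammogram-like phantom cohort.

Images are a smooth low-frequency breast-shaped background plus a cluster of
bright calcification-like structures around a lesion center.  The low-risk
family (grades I/II, differing only in blob density) renders small round
blobs; the high-risk family (grade III and upstaged patients) renders
denser, elongated, branching linear segments.  Per-structure intensities are
drawn from the same distribution for every class, so the class signal is
morphological (shape and density), never raw intensity.

Grade counts follow largest-remainder quota allocation, upstage flags
nearest-integer rounding, so cohort composition is exact and reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .config import ClassMorphology, SyntheticCohortConfig
from .manifest import (
    GRADES,
    MANIFEST_COLUMNS,
    UNASSIGNED,
    CohortManifest,
    largest_remainder,
    read_mask,
)
from .metrics import auroc

LATERALITIES = ("L", "R")


def render_background(size: int, rng: np.random.Generator, background_max: float = 0.45,
                      smooth_frac: float = 1 / 16) -> np.ndarray:
    """Smooth low-frequency texture inside a breast-like region.

    Values lie in ``[0, background_max] ⊂ [0, 1)``; the border is near zero.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    field = rng.standard_normal((size, size))
    field = gaussian_filter(field, sigma=max(1.0, size * smooth_frac))
    lo, hi = field.min(), field.max()
    field = (field - lo) / (hi - lo) if hi > lo else np.zeros_like(field)

    rr, cc = np.mgrid[0:size, 0:size]
    breast = (((rr - size / 2) / (0.46 * size)) ** 2 + (cc / (0.85 * size)) ** 2) <= 1.0
    feather = gaussian_filter(breast.astype(float), sigma=max(1.0, size / 64))
    out = (0.35 + 0.65 * field) * feather * background_max
    return np.clip(out, 0.0, background_max)


def _clipped_line(r0, c0, r1, c1, shape, width: int = 1):
    rr, cc = draw_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    if width > 1:  # thicken by stacking unit offsets (staircase dilation)
        offs = [(dr, dc) for dr in range(width) for dc in range(width)]
        rr = np.concatenate([rr + dr for dr, dc in offs])
        cc = np.concatenate([cc + dc for dr, dc in offs])
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[keep], cc[keep]


def render_calcifications(
    class_label: str,
    center: Tuple[int, int],
    morph: ClassMorphology,
    size: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render one lesion; returns (overlay, binary mask).

    ``class_label`` is "low" (default: round granular blobs) or "high"
    (default: linear, branching segments).  The structure family is driven
    by the morphology itself — segments whenever ``n_segments`` is non-empty
    — so identical morphology parameters render identically for both
    classes.  The mask is exactly the overlay support.
    """
    if class_label not in ("low", "high"):
        raise ValueError(f"unknown class label {class_label!r}")
    r0, c0 = center
    if not (0 <= r0 < size and 0 <= c0 < size):
        raise ValueError(f"lesion center {center} outside image of size {size}")
    overlay = np.zeros((size, size))
    spread = morph.cluster_spread

    def put(rr, cc, val):
        overlay[rr, cc] = np.maximum(overlay[rr, cc], val)

    if morph.n_segments[1] == 0:
        n_blobs = int(rng.integers(morph.blob_count[0], morph.blob_count[1] + 1))
        for _ in range(max(1, n_blobs)):
            pr = r0 + rng.uniform(-spread, spread)
            pc = c0 + rng.uniform(-spread, spread)
            radius = rng.uniform(*morph.blob_radius)
            ratio = rng.uniform(*morph.blob_axis_ratio)
            angle = rng.uniform(0, np.pi)
            rr, cc = draw_ellipse(pr, pc, radius * ratio, radius, shape=overlay.shape, rotation=angle)
            put(rr, cc, rng.uniform(*morph.intensity))
    else:
        n_seg = int(rng.integers(morph.n_segments[0], morph.n_segments[1] + 1))
        for _ in range(max(1, n_seg)):
            pr = r0 + rng.uniform(-spread, spread)
            pc = c0 + rng.uniform(-spread, spread)
            angle = rng.uniform(0, np.pi)
            length = rng.uniform(*morph.segment_length)
            er = pr + length * np.sin(angle)
            ec = pc + length * np.cos(angle)
            rr, cc = _clipped_line(pr, pc, er, ec, overlay.shape, morph.segment_width)
            put(rr, cc, rng.uniform(*morph.intensity))
            if rng.random() < morph.branch_p:
                mr, mc = (pr + er) / 2, (pc + ec) / 2
                bangle = angle + rng.choice((-1, 1)) * rng.uniform(np.pi / 6, np.pi / 3)
                br = mr + 0.6 * length * np.sin(bangle)
                bc = mc + 0.6 * length * np.cos(bangle)
                rr, cc = _clipped_line(mr, mc, br, bc, overlay.shape, morph.segment_width)
                put(rr, cc, rng.uniform(*morph.intensity))

    if not overlay.any():  # everything fell outside; anchor at the center pixel
        overlay[r0, c0] = float(np.mean(morph.intensity))
    mask = (overlay > 0).astype(np.uint8)
    return overlay, mask


def morphology_class(grade: str, upstaged: bool) -> str:
    """Rendered morphology family: upstaged and grade III are high-risk."""
    return "high" if (grade == "III" or upstaged) else "low"


def _render_one(grade: str, upstaged: bool, config: SyntheticCohortConfig,
                rng: np.random.Generator):
    size = config.image_size
    bg = render_background(size, rng, config.background_max, config.background_smooth_frac)
    lo = int(size * 0.35)
    hi = int(size * 0.65)
    center = (int(rng.integers(lo, hi)), int(rng.integers(lo, hi)))
    cls = morphology_class(grade, upstaged)
    morph = config.morphology["high" if cls == "high" else grade]
    overlay, mask = render_calcifications(cls, center, morph, size, rng)
    image = np.clip(bg + overlay, 0.0, 1.0)
    return image, mask, center


def generate_cohort(config: SyntheticCohortConfig, output_dir) -> CohortManifest:
    """Write one image + mask per patient-view and return the manifest.

    Deterministic given ``config.seed``: byte-identical manifest and
    pixel-identical images on every run.
    """
    config.validate()
    output_dir = Path(output_dir)
    n = config.n_patients
    if n == 0:
        return CohortManifest.empty()
    (output_dir / "images").mkdir(parents=True, exist_ok=True)
    (output_dir / "masks").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 0)))
    counts = largest_remainder(config.grade_mix, n)
    grades = np.repeat(list(GRADES), counts)
    grades = grades[rng.permutation(n)]
    n_up = int(np.floor(n * config.upstage_rate + 0.5))
    upstaged = np.zeros(n, dtype=bool)
    upstaged[rng.choice(n, size=n_up, replace=False)] = True

    width = max(4, len(str(n)))
    rows = []
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        lat = LATERALITIES[int(rng.integers(0, 2))]
        for view in config.views_per_patient:
            image, mask, center = _render_one(grades[i], bool(upstaged[i]), config, rng)
            img_path = output_dir / "images" / f"{pid}_{view}.png"
            mask_path = output_dir / "masks" / f"{pid}_{view}_mask.png"
            iio.imwrite(img_path, np.round(image * 65535).astype(np.uint16))
            iio.imwrite(mask_path, (mask * 255).astype(np.uint8))
            rows.append(
                {
                    "patient_id": pid,
                    "image_path": str(img_path),
                    "mask_path": str(mask_path),
                    "view": view,
                    "laterality": lat,
                    "lesion_center_row": center[0],
                    "lesion_center_col": center[1],
                    "grade": grades[i],
                    "upstaged": bool(upstaged[i]),
                    "split": UNASSIGNED,
                    "fold": UNASSIGNED,
                }
            )
    manifest = CohortManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    manifest.validate(check_paths=True)
    return manifest


def image_shape_statistic(mask: np.ndarray) -> float:
    """Mean eccentricity of the mask's connected components (0 if empty)."""
    labeled = cc_label(mask > 0)
    props = regionprops(labeled)
    if not props:
        return 0.0
    return float(np.mean([p.eccentricity for p in props]))


def separability_check(manifest: CohortManifest) -> float:
    """AUROC of a handcrafted shape statistic against the binary class.

    The statistic is the per-image mean connected-component eccentricity of
    the ground-truth mask; the class is the rendered morphology family.
    A healthy generator configuration scores >= 0.90.
    """
    scores, labels = [], []
    for _, row in manifest.df.iterrows():
        mask = read_mask(row["mask_path"], annotated=False).mask
        scores.append(image_shape_statistic(mask))
        labels.append(1 if morphology_class(row["grade"], bool(row["upstaged"])) == "high" else 0)
    if len(set(labels)) < 2:
        raise ValueError("separability_check requires both classes in the manifest")
    return auroc(scores, labels)
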