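"""Cohort manifest I/O, scenario labels, patient-level split and folds.

The manifest is a versioned CSV with one row per image.  All partitioning is
done at *patient* granularity: every image of a patient shares its split and
fold, no patient ever crosses the train/test boundary, and both the split
and the fold assignment are stratified by surgical grade.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import module_rng
from .formats.dicom import VoiLut, read_dicom
from .formats.nrrd import read_nrrd

MANIFEST_VERSION = 1
MANIFEST_COLUMNS = [
    "patient_id",
    "image_path",
    "mask_path",
    "view",
    "laterality",
    "lesion_center_row",
    "lesion_center_col",
    "grade",
    "upstaged",
    "split",
    "fold",
]
VIEWS = ("CC", "MLO", "OTHER")
GRADES = ("I", "II", "III")
UNASSIGNED = "unassigned"

#: Sentinel returned by :func:`scenario_label` for excluded cases.
EXCLUDED = None


class ManifestError(ValueError):
    pass


@dataclass
class MammogramSample:
    patient_id: str
    image: np.ndarray  # 2-D, non-negative, higher = brighter
    view: str = "OTHER"
    laterality: str = "L"
    lesion_center: Tuple[int, int] = (0, 0)
    lut_family: List[VoiLut] = field(default_factory=list)

    def validate(self) -> None:
        h, w = self.image.shape
        r, c = self.lesion_center
        if not (0 <= r < h and 0 <= c < w):
            raise ManifestError(f"lesion_center {self.lesion_center} outside image {self.image.shape}")
        if self.view not in VIEWS:
            raise ManifestError(f"unknown view {self.view!r}")


@dataclass
class LesionMask:
    mask: np.ndarray  # binary {0,1}

    def validate(self, image_shape: Optional[Tuple[int, int]] = None, annotated: bool = True) -> None:
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ManifestError("mask is not binary")
        if image_shape is not None and self.mask.shape != tuple(image_shape):
            raise ManifestError(f"mask shape {self.mask.shape} != image shape {image_shape}")
        if annotated and self.mask.sum() == 0:
            raise ManifestError("annotated lesion mask has no positive pixel")


@dataclass
class CaseLabel:
    grade: str  # I | II | III
    upstaged: bool

    def __post_init__(self):
        if self.grade not in GRADES:
            raise ManifestError(f"invalid grade {self.grade!r}")


def scenario_label(label: CaseLabel, scenario: str) -> Optional[int]:
    """Binary scenario label, or :data:`EXCLUDED` (None).

    pure:    upstaged cases are excluded; grade III -> 1, I/II -> 0.
    upstage: grade III and/or upstaged -> 1, else 0.
    """
    if scenario == "pure":
        if label.upstaged:
            return EXCLUDED
        return 1 if label.grade == "III" else 0
    if scenario == "upstage":
        return 1 if (label.grade == "III" or label.upstaged) else 0
    raise ValueError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# image / mask readers
# ---------------------------------------------------------------------------

def read_image(path, row: Optional[dict] = None) -> MammogramSample:
    """Read DICOM / 16-bit PNG / TIFF into a sample (brighter = higher).

    Non-pixel metadata comes from the optional manifest ``row``; for DICOM,
    the vendor VOI LUT family is parsed from the file itself.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    luts: List[VoiLut] = []
    if suffix in (".dcm", ".dicom"):
        d = read_dicom(path)
        arr = d.pixels.astype(np.int64)
        if d.photometric == "MONOCHROME1":  # stored low = bright; normalize
            arr = (2**d.bits_stored - 1) - arr
        luts = d.luts
    elif suffix == ".png":
        arr = np.asarray(iio.imread(path))
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        raise ManifestError(f"unsupported image format {suffix!r}")
    if arr.ndim != 2:
        raise ManifestError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    sample = MammogramSample(
        patient_id=str(row["patient_id"]) if row else "",
        image=np.asarray(arr),
        view=str(row["view"]) if row else "OTHER",
        laterality=str(row["laterality"]) if row else "L",
        lesion_center=(
            (int(row["lesion_center_row"]), int(row["lesion_center_col"]))
            if row
            else (arr.shape[0] // 2, arr.shape[1] // 2)
        ),
        lut_family=luts,
    )
    if row:
        sample.validate()
    return sample


def read_mask(path, image_shape: Optional[Tuple[int, int]] = None, annotated: bool = True) -> LesionMask:
    """Read an 8-bit PNG or NRRD mask; any nonzero value becomes 1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".nrrd":
        arr = read_nrrd(path)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise ManifestError(f"NRRD mask is not 2-D after squeezing: {arr.shape}")
    elif path.suffix.lower() == ".png":
        arr = np.asarray(iio.imread(path))
    else:
        raise ManifestError(f"unsupported mask format {path.suffix!r}")
    mask = LesionMask(mask=(arr != 0).astype(np.uint8))
    mask.validate(image_shape=image_shape, annotated=annotated)
    return mask


# ---------------------------------------------------------------------------
# manifest table
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.df.columns]
        extra = [c for c in self.df.columns if c not in MANIFEST_COLUMNS]
        if missing or extra:
            raise ManifestError(f"bad manifest columns: missing={missing} extra={extra}")
        self.df = self.df[MANIFEST_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls) -> "CohortManifest":
        return cls(pd.DataFrame(columns=MANIFEST_COLUMNS))

    def patients(self) -> List[str]:
        return sorted(self.df["patient_id"].unique())

    def patient_labels(self) -> Dict[str, CaseLabel]:
        out = {}
        for _, r in self.df.drop_duplicates("patient_id").iterrows():
            out[r["patient_id"]] = CaseLabel(grade=r["grade"], upstaged=bool(r["upstaged"]))
        return out

    def rows(self, split: Optional[str] = None, fold=None, exclude_fold=None) -> pd.DataFrame:
        df = self.df
        if split is not None:
            df = df[df["split"] == split]
        if fold is not None:
            df = df[df["fold"] == fold]
        if exclude_fold is not None:
            df = df[(df["fold"] != exclude_fold)]
        return df.reset_index(drop=True)

    def validate(self, require_folds: bool = False, check_paths: bool = False) -> None:
        df = self.df
        if len(df) == 0:
            return
        for col, allowed in (("view", VIEWS), ("grade", GRADES)):
            bad = set(df[col]) - set(allowed)
            if bad:
                raise ManifestError(f"invalid {col} values {sorted(bad)}")
        by_pat = df.groupby("patient_id")
        if (by_pat["split"].nunique() > 1).any():
            raise ManifestError("a patient appears in more than one split")
        if (by_pat["fold"].nunique() > 1).any():
            raise ManifestError("a patient appears in more than one fold")
        if (by_pat["grade"].nunique() > 1).any() or (by_pat["upstaged"].nunique() > 1).any():
            raise ManifestError("inconsistent labels within a patient")
        bad_split = set(df["split"]) - {"train", "test", UNASSIGNED}
        if bad_split:
            raise ManifestError(f"invalid split values {sorted(bad_split)}")
        if require_folds:
            train = df[df["split"] == "train"]
            if (train["fold"] == UNASSIGNED).any():
                raise ManifestError("training patients without fold assignment")
        if check_paths:
            for col in ("image_path", "mask_path"):
                for p in df[col]:
                    if not os.path.exists(p):
                        raise ManifestError(f"missing file {p}")


def write_manifest(manifest: CohortManifest, path) -> None:
    df = manifest.df.copy()
    df["upstaged"] = df["upstaged"].astype(bool)
    with open(path, "w", newline="") as fh:
        fh.write(f"# calcinet-manifest v{MANIFEST_VERSION}\n")
        df.to_csv(fh, index=False)


def read_manifest(path) -> CohortManifest:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# calcinet-manifest"):
            raise ManifestError("missing manifest version header")
        version = int(first.rsplit("v", 1)[1])
        if version != MANIFEST_VERSION:
            raise ManifestError(f"unsupported manifest version {version}")
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    if len(df) == 0:
        m = CohortManifest.empty()
        m.validate()
        return m
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"bad manifest columns: missing={missing}")
    df["lesion_center_row"] = df["lesion_center_row"].astype(int)
    df["lesion_center_col"] = df["lesion_center_col"].astype(int)
    df["upstaged"] = df["upstaged"].map({"True": True, "False": False})
    if df["upstaged"].isna().any():
        raise ManifestError("upstaged column must be True/False")
    df["fold"] = [f if f == UNASSIGNED else int(f) for f in df["fold"]]
    m = CohortManifest(df)
    m.validate()
    return m


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def largest_remainder(weights: Sequence[float], total: int) -> List[int]:
    """Integer quota allocation: floors plus largest fractional remainders.

    Remainder ties break toward the earlier index (deterministic).
    """
    w = np.asarray(weights, dtype=float)
    if total == 0 or w.sum() == 0:
        return [0] * len(w)
    quotas = w / w.sum() * total
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    short = total - counts.sum()
    order = np.argsort(-rem, kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return counts.tolist()


def split_patient_level(
    manifest: CohortManifest,
    test_fraction: float = 0.20,
    seed: int = 0,
) -> CohortManifest:
    """Grade-stratified patient-level train/test split.

    The total test count is the nearest integer to ``n_patients *
    test_fraction``; per-grade counts follow largest-remainder allocation of
    that total across strata.
    """
    if len(manifest) == 0:
        raise ManifestError("cannot split an empty manifest")
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    rng = module_rng(seed, "split")
    pat = manifest.df.drop_duplicates("patient_id")[["patient_id", "grade"]]
    n = len(pat)
    n_test = int(np.floor(n * test_fraction + 0.5))

    strata = {g: sorted(pat.loc[pat["grade"] == g, "patient_id"]) for g in GRADES if (pat["grade"] == g).any()}
    grades = list(strata)
    counts = largest_remainder([len(strata[g]) for g in grades], n_test)
    test_patients = set()
    for g, k in zip(grades, counts):
        ids = strata[g]
        if k > 0 and len(ids) < 2:
            warnings.warn(f"grade {g} stratum too small to split; keeping all in train")
            continue
        k = min(k, len(ids) - 1)
        perm = rng.permutation(len(ids))
        test_patients.update(ids[i] for i in perm[:k])

    df = manifest.df.copy()
    df["split"] = np.where(df["patient_id"].isin(test_patients), "test", "train")
    df["fold"] = UNASSIGNED
    out = CohortManifest(df)
    out.validate()
    return out


def assign_folds(manifest: CohortManifest, k: int = 5, seed: int = 0) -> CohortManifest:
    """Assign each training patient a validation fold in 1..k.

    Stratified by grade; a single round-robin deal runs across strata so
    fold sizes are balanced both per stratum and globally (within 1).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = module_rng(seed, "folds")
    train = manifest.df[manifest.df["split"] == "train"]
    pat = train.drop_duplicates("patient_id")[["patient_id", "grade"]]
    if len(pat) < k:
        raise ManifestError(f"fewer training patients ({len(pat)}) than folds ({k})")
    assignment: Dict[str, int] = {}
    cursor = 0
    for g in GRADES:
        ids = sorted(pat.loc[pat["grade"] == g, "patient_id"])
        if not ids:
            continue
        perm = rng.permutation(len(ids))
        for i in perm:
            assignment[ids[i]] = cursor % k + 1
            cursor += 1
    df = manifest.df.copy()
    df["fold"] = [
        assignment.get(p, UNASSIGNED) if s == "train" else UNASSIGNED
        for p, s in zip(df["patient_id"], df["split"])
    ]
    out = CohortManifest(df)
    out.validate(require_folds=True)
    return out
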