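"""Evaluation metrics: DICE, rank-based AUROC, PPV/NPV, view averaging.

AUROC is the Mann-Whitney rank statistic with midrank tie handling,
P(score+ > score-) + 0.5 * P(score+ = score-).  PPV/NPV use the fixed
decision threshold 0.5 with ``score >= threshold`` counting positive.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

DEFAULT_THRESHOLD = 0.5


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``.

    Both masks empty is defined as 1.0 (nothing to find, nothing found).
    """
    a = np.asarray(pred_mask)
    b = np.asarray(true_mask)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    for m, name in ((a, "pred_mask"), (b, "true_mask")):
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} is not binary (values {vals[:5]})")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the midrank Mann-Whitney statistic."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes present")
    ranks = rankdata(s)  # midranks
    rank_sum_pos = float(ranks[y == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def patient_score(view_probs: Dict[str, Sequence[float]]) -> float:
    """Aggregate per-image probabilities of one patient into a single score.

    The mean of available CC and MLO probabilities; views outside {CC, MLO}
    participate only when neither standard view exists.
    """
    probs = []
    for view in ("CC", "MLO"):
        probs.extend(view_probs.get(view, ()))
    if not probs:
        for view, vals in sorted(view_probs.items()):
            probs.extend(vals)
    if not probs:
        raise ValueError("patient has no image probabilities")
    return float(np.mean(probs))


def ppv_npv(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[Optional[float], Optional[float]]:
    """Predictive values at ``threshold``; an undefined rate is ``None``."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    return ppv, npv


@dataclass
class PredictionRecord:
    patient_id: str
    view: str
    probability: float
    dice: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")


@dataclass
class EvalReport:
    scenario: str
    auroc: float
    ppv: Optional[float]
    npv: Optional[float]
    threshold: float
    mean_dice: float
    n_patients: int
    n_images: int
    per_patient: Dict[str, dict] = dataclasses.field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def report_from_predictions(
    records: Iterable[PredictionRecord],
    patient_labels: Dict[str, int],
    scenario: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> EvalReport:
    """Build an :class:`EvalReport` from per-image predictions.

    ``patient_labels`` holds the scenario labels; patients absent from it are
    treated as excluded and dropped together with their records.
    """
    records = list(records)
    by_patient: Dict[str, Dict[str, list]] = {}
    dices = []
    n_images = 0
    for rec in records:
        if rec.patient_id not in patient_labels:
            continue
        n_images += 1
        by_patient.setdefault(rec.patient_id, {}).setdefault(rec.view, []).append(
            rec.probability
        )
        if rec.dice is not None:
            dices.append(rec.dice)
    if not by_patient:
        raise ValueError("no eligible patients after scenario exclusions")
    pids = sorted(by_patient)
    scores = [patient_score(by_patient[p]) for p in pids]
    labels = [patient_labels[p] for p in pids]
    auc = auroc(scores, labels)
    ppv, npv = ppv_npv(scores, labels, threshold)
    per_patient = {
        p: {"score": s, "label": int(l)} for p, s, l in zip(pids, scores, labels)
    }
    return EvalReport(
        scenario=scenario,
        auroc=auc,
        ppv=ppv,
        npv=npv,
        threshold=threshold,
        mean_dice=float(np.mean(dices)) if dices else float("nan"),
        n_patients=len(pids),
        n_images=n_images,
        per_patient=per_patient,
    )


def evaluate(
    models,
    manifest,
    scenario: str,
    augment_config,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[EvalReport, list[PredictionRecord]]:
    """Score fold models on a manifest under one labeling scenario.

    Per image: deterministic eval transform, fold-model probability
    averaging, then patient-level CC/MLO view averaging.  DICE is computed
    per image from the model-averaged segmentation probability at 0.5.
    Patients excluded by the scenario are dropped before any metric.
    """
    from .augment import eval_transform
    from .manifest import CaseLabel, read_image, read_mask, scenario_label

    models = list(models)
    if not models:
        raise ValueError("evaluate needs at least one model")
    records = []
    patient_labels = {}
    for _, row in manifest.df.iterrows():
        lbl = scenario_label(
            CaseLabel(grade=row["grade"], upstaged=bool(row["upstaged"])), scenario
        )
        if lbl is None:
            continue
        patient_labels[row["patient_id"]] = lbl
        sample = read_image(row["image_path"], row=dict(row))
        mask = read_mask(row["mask_path"], image_shape=sample.image.shape).mask
        img, m = eval_transform(sample, mask, augment_config)
        probs, seg_probs = [], []
        for net in models:
            out = net.forward(img[None, None])
            probs.append(float(out.cls_probs[0, 1]))
            z = out.seg_scores[0] - out.seg_scores[0].max(axis=0, keepdims=True)
            e = np.exp(z)
            seg_probs.append(e[1] / e.sum(axis=0))
        seg_mean = np.mean(seg_probs, axis=0)
        d = dice((seg_mean >= 0.5).astype(np.uint8), m)
        records.append(
            PredictionRecord(
                patient_id=row["patient_id"],
                view=row["view"],
                probability=float(np.mean(probs)),
                dice=d,
            )
        )
    if not records:
        raise ValueError(f"no eligible patients for scenario {scenario!r}")
    report = report_from_predictions(records, patient_labels, scenario, threshold)
    return report, records
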