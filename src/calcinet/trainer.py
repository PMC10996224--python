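"""Training loop: Adam with a step-decay schedule, per-fold training and
5-fold cross-validation.

The learning rate starts at ``initial_lr`` and is multiplied by
``lr_decay_factor`` every ``lr_decay_interval`` optimizer iterations, with a
configurable floor (a literal unbounded decay is numerically degenerate over
long runs).  Training labels are the upstage-scenario binary labels (grade
III and/or upstaged = positive), which is also the grouping used to render
the synthetic morphology; evaluation can then score either scenario.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .augment import eval_transform, train_transform
from .config import NetworkConfig, TrainConfig, module_rng
from .losses import combined_loss_with_grads
from .manifest import CaseLabel, CohortManifest, read_image, read_mask, scenario_label
from .metrics import auroc, dice, patient_score
from .network import DualBranchNet, build_network
from .nn import Adam

TRAIN_SCENARIO = "upstage"


def lr_at(iteration: int, config: TrainConfig) -> float:
    """Closed-form schedule: ``max(lr0 * f^floor(it / interval), floor)``."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    steps = iteration // config.lr_decay_interval
    return max(config.initial_lr * config.lr_decay_factor**steps, config.lr_floor)


@dataclass
class TrainingHistory:
    records: List[dict] = field(default_factory=list)

    def append(self, **kwargs):
        self.records.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


class ImageStore:
    """In-memory cache of (sample, mask) pairs keyed by image path."""

    def __init__(self):
        self._cache: Dict[str, tuple] = {}

    def get(self, row) -> tuple:
        key = row["image_path"]
        if key not in self._cache:
            sample = read_image(row["image_path"], row=dict(row))
            mask = read_mask(row["mask_path"], image_shape=sample.image.shape).mask
            self._cache[key] = (sample, mask)
        return self._cache[key]


def _row_label(row) -> int:
    lbl = scenario_label(CaseLabel(grade=row["grade"], upstaged=bool(row["upstaged"])), TRAIN_SCENARIO)
    assert lbl is not None
    return lbl


def _validate_network(
    net: DualBranchNet, rows: pd.DataFrame, train_cfg: TrainConfig, store: ImageStore
) -> Tuple[float, float]:
    """Patient-level AUROC (nan if single-class) and mean DICE on rows."""
    probs_by_patient: Dict[str, Dict[str, list]] = {}
    labels: Dict[str, int] = {}
    dices = []
    for _, row in rows.iterrows():
        sample, mask = store.get(row)
        img, m = eval_transform(sample, mask, train_cfg.augment)
        out = net.forward(img[None, None])
        p = float(out.cls_probs[0, 1])
        probs_by_patient.setdefault(row["patient_id"], {}).setdefault(row["view"], []).append(p)
        labels[row["patient_id"]] = _row_label(row)
        seg_p = _seg_prob(out.seg_scores[0])
        dices.append(dice((seg_p >= 0.5).astype(np.uint8), m))
    pids = sorted(probs_by_patient)
    scores = [patient_score(probs_by_patient[p]) for p in pids]
    y = [labels[p] for p in pids]
    try:
        auc = auroc(scores, y)
    except ValueError:
        auc = float("nan")
    return auc, float(np.mean(dices))


def _seg_prob(seg_scores: np.ndarray) -> np.ndarray:
    """Per-pixel probability of the lesion class (softmax channel 1)."""
    z = seg_scores - seg_scores.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e[1] / e.sum(axis=0)


def train_fold(
    train_rows: pd.DataFrame,
    val_rows: pd.DataFrame,
    network_config: NetworkConfig,
    train_config: TrainConfig,
    store: Optional[ImageStore] = None,
    fold: int = 1,
) -> Tuple[DualBranchNet, TrainingHistory]:
    """Train one fold; returns the best-validation-AUROC model and history."""
    train_config.validate()
    if len(train_rows) == 0:
        raise ValueError("empty training rows")
    overlap = set(train_rows["patient_id"]) & set(val_rows["patient_id"])
    if overlap:
        raise ValueError(f"patient overlap between train and validation: {sorted(overlap)[:3]}")
    store = store or ImageStore()

    init_rng = module_rng(train_config.seed + fold, "init")
    shuffle_rng = module_rng(train_config.seed + fold, "train")
    aug_rng = module_rng(train_config.seed + fold, "augment")

    net = build_network(network_config, rng=init_rng)
    history = TrainingHistory()
    if train_config.epochs == 0:
        return net, history

    optimizer = Adam(
        net.parameters(),
        beta1=train_config.adam_beta1,
        beta2=train_config.adam_beta2,
        eps=train_config.adam_eps,
    )
    rows = train_rows.reset_index(drop=True)
    labels = np.array([_row_label(r) for _, r in rows.iterrows()])
    n = len(rows)
    bs = train_config.batch_size
    iteration = 0
    best_key = (-np.inf, -np.inf)
    best_state = net.state_dict()

    for epoch in range(1, train_config.epochs + 1):
        perm = shuffle_rng.permutation(n)
        tot, seg_tot, cls_tot, nb = 0.0, 0.0, 0.0, 0
        epoch_lr = lr_at(iteration, train_config)
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            imgs, masks = [], []
            for i in idx:
                sample, mask = store.get(rows.iloc[i])
                img, m = train_transform(sample, mask, train_config.augment, aug_rng)
                imgs.append(img)
                masks.append(m)
            x = np.stack(imgs)[:, None]
            m = np.stack(masks).astype(int)
            y = labels[idx]
            out = net.forward(x)
            res, dseg, dcls = combined_loss_with_grads(
                out.seg_scores, out.cls_scores, m, y, train_config.loss
            )
            optimizer.zero_grad()
            net.backward(dseg, dcls)
            epoch_lr = lr_at(iteration, train_config)
            optimizer.step(epoch_lr)
            iteration += 1
            tot += res.total
            seg_tot += res.seg
            cls_tot += res.cls
            nb += 1
        val_auc, val_dice = (
            _validate_network(net, val_rows, train_config, store)
            if len(val_rows)
            else (float("nan"), float("nan"))
        )
        history.append(
            fold=fold,
            epoch=epoch,
            loss=tot / nb,
            seg_loss=seg_tot / nb,
            cls_loss=cls_tot / nb,
            val_auroc=val_auc,
            val_dice=val_dice,
            lr=epoch_lr,
            iteration=iteration,
        )
        # model selection: best validation AUROC, ties broken by DICE
        if np.isfinite(val_auc) and (val_auc, val_dice) > best_key:
            best_key = (val_auc, val_dice)
            best_state = copy.deepcopy(net.state_dict())
    if np.isfinite(best_key[0]):
        net.load_state_dict(best_state)
    return net, history


def train_cv(
    manifest: CohortManifest,
    network_config: NetworkConfig,
    train_config: TrainConfig,
    store: Optional[ImageStore] = None,
) -> List[Tuple[DualBranchNet, TrainingHistory]]:
    """One model per validation fold over the training split."""
    manifest.validate(require_folds=True)
    train_df = manifest.rows(split="train")
    if len(train_df) == 0:
        raise ValueError("manifest has no training rows")
    folds = sorted(set(train_df["fold"]))
    if folds == ["unassigned"] or not folds:
        raise ValueError("folds are not assigned")
    store = store or ImageStore()
    results = []
    for f in range(1, train_config.n_folds + 1):
        tr = train_df[train_df["fold"] != f].reset_index(drop=True)
        va = train_df[train_df["fold"] == f].reset_index(drop=True)
        results.append(
            train_fold(tr, va, network_config, train_config, store=store, fold=f)
        )
    return results
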