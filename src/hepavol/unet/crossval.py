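"""Group-stratified k-fold cross-validation for the segmentation model."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationParams
from .network import UNetConfig
from .train import VesselSegmentationModel


@dataclass
class FoldReport:
    fold_id: int
    train_ids: list[str]
    test_ids: list[str]
    per_case_dice: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def mean_vessel_dice(self) -> float:
        vals = [d["vessel_dice"] for d in self.per_case_dice.values()]
        return float(np.mean(vals)) if vals else float("nan")


def stratified_folds(
    ids: list[str],
    group_labels: dict[str, str],
    k: int,
    seed: int = 0,
) -> list[list[str]]:
    """Partition case ids into k folds, stratified by group label.

    Falls back to an unstratified partition (with a warning) when any
    stratum is smaller than k. Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"cannot make {k} folds from {len(ids)} cases")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {}
    for cid in ids:
        strata.setdefault(group_labels.get(cid, "all"), []).append(cid)
    if any(len(members) < k for members in strata.values()):
        warnings.warn("a stratum is smaller than k; falling back to unstratified folds")
        strata = {"all": list(ids)}
    folds: list[list[str]] = [[] for _ in range(k)]
    for members in strata.values():
        members = list(members)
        rng.shuffle(members)
        for i, cid in enumerate(members):
            folds[i % k].append(cid)
    return folds


def crossvalidate(
    cases: dict[str, tuple],
    k: int = 3,
    group_labels: dict[str, str] | None = None,
    seed: int = 0,
    config: UNetConfig | None = None,
    augmentation: AugmentationParams | None = None,
    epochs: int | None = None,
    steps_per_epoch: int = 1,
) -> list[FoldReport]:
    """k-fold cross-validation: train on k-1 folds, evaluate Dice on the
    held-out fold; every case appears in exactly one test fold."""
    cfg = config or UNetConfig()
    ids = list(cases)
    folds = stratified_folds(ids, group_labels or {}, k, seed)
    reports = []
    for fold_id, test_ids in enumerate(folds):
        train_ids = [cid for cid in ids if cid not in test_ids]
        model = VesselSegmentationModel(
            {cid: cases[cid] for cid in train_ids},
            cfg,
            augmentation=augmentation,
            steps_per_epoch=steps_per_epoch,
        )
        results = model.fit(epochs=epochs)
        report = FoldReport(fold_id=fold_id, train_ids=train_ids, test_ids=list(test_ids))
        report.per_case_dice = results.evaluate({cid: cases[cid] for cid in test_ids})
        reports.append(report)
    return reports
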