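"""Training and inference for the vessel-segmentation U-Net.

The public surface is the model / results pair:
:class:`VesselSegmentationModel` holds the annotated cases and the
configuration; ``fit()`` runs patch-based training (Adam, batch size 1)
and returns a :class:`SegmentationResults` carrying the trained network,
the per-epoch loss trace, and prediction / evaluation methods.

Desk-scale schedule: each epoch processes ``steps_per_epoch`` patches
(default 1), visiting the training cases in fixed rotation at per-case
patch origins chosen once (foreground-biased, seeded). Stochastic
variation across epochs comes from the augmentation draw; with
augmentation disabled the schedule is fully deterministic, so a zero
learning rate yields a constant loss trace on a single case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io import ImageVolume
from ..volumetry import LABEL_HEPATIC, LABEL_PORTAL, dice
from .augment import AugmentationParams, augment
from .network import UNet3D, UNetConfig, segmentation_loss, softmax
from .patches import pad_to_patch, patch_origins, sample_patches


def _as_array(volume) -> np.ndarray:
    return volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Per-volume z-scoring, the only intensity preprocessing applied."""
    v = np.asarray(volume, dtype=np.float32)
    sd = float(v.std())
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class SegmentationResults:
    """Fit results: trained network, loss trace, and inference helpers."""

    network: UNet3D
    config: UNetConfig
    loss_trace: list[float]
    case_ids: list[str]

    def predict(self, volume) -> np.ndarray:
        return predict(self.network, volume)

    def evaluate(self, cases: dict[str, tuple]) -> dict[str, dict[str, float]]:
        """Per-case Dice: overall vessel union plus per vessel class."""
        out = {}
        for cid, (image, labels) in cases.items():
            pred = self.predict(image)
            gt = np.asarray(labels)
            out[cid] = {
                "vessel_dice": dice(
                    np.isin(pred, (LABEL_PORTAL, LABEL_HEPATIC)),
                    np.isin(gt, (LABEL_PORTAL, LABEL_HEPATIC)),
                ),
                "portal_dice": dice(pred == LABEL_PORTAL, gt == LABEL_PORTAL),
                "hepatic_dice": dice(pred == LABEL_HEPATIC, gt == LABEL_HEPATIC),
            }
        return out

    def save(self, weights_path, config_path=None) -> None:
        self.network.save(weights_path, config_path)


class VesselSegmentationModel:
    """Patch-based 3D U-Net segmentation model over annotated cases.

    Parameters
    ----------
    cases : mapping of case id to ``(image, labels)``; images may be
        :class:`~hepavol.io.ImageVolume` or plain arrays. Labels are
        integer class maps on the same grid.
    config : :class:`UNetConfig`.
    augmentation : optional :class:`AugmentationParams`; None disables
        augmentation entirely.
    """

    def __init__(
        self,
        cases: dict[str, tuple],
        config: UNetConfig,
        augmentation: AugmentationParams | None = None,
        steps_per_epoch: int = 1,
        foreground_bias: float = 0.9,
    ):
        if not cases:
            raise ValueError("at least one training case is required")
        self.case_ids = list(cases)
        self.config = config
        self.augmentation = augmentation
        self.steps_per_epoch = steps_per_epoch
        self._images = []
        self._labels = []
        for cid in self.case_ids:
            image, labels = cases[cid]
            img = normalize_volume(_as_array(image))
            lab = np.asarray(labels)
            if img.shape != lab.shape:
                raise ValueError(f"case {cid}: image/label shapes differ")
            if lab.max() >= config.n_classes:
                raise ValueError(
                    f"case {cid}: label {lab.max()} outside the {config.n_classes}-class model"
                )
            img, _ = pad_to_patch(img, config.patch_size)
            lab, _ = pad_to_patch(lab, config.patch_size)
            self._images.append(np.ascontiguousarray(img, dtype=np.float32))
            self._labels.append(np.ascontiguousarray(lab))
        # fixed per-case patch origins, foreground-biased, chosen once
        rng = np.random.default_rng(config.seed)
        self._origins = []
        for img, lab in zip(self._images, self._labels):
            fg = np.isin(lab, (LABEL_PORTAL, LABEL_HEPATIC))
            self._origins.append(
                sample_patches(
                    img.shape, config.patch_size, config.stride,
                    n=max(4, self.steps_per_epoch),
                    foreground=fg, foreground_bias=foreground_bias, rng=rng,
                )
            )

    def _patch(self, case: int, slot: int) -> tuple[np.ndarray, np.ndarray]:
        o = self._origins[case][slot % len(self._origins[case])]
        p = self.config.patch_size
        sl = tuple(slice(o[i], o[i] + p[i]) for i in range(3))
        return self._images[case][sl], self._labels[case][sl]

    def fit(self, epochs: int | None = None, verbose: bool = False) -> SegmentationResults:
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        network = UNet3D(cfg)
        optimizer = network.make_optimizer()
        aug_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
        trace: list[float] = []
        n_cases = len(self.case_ids)
        step = 0
        for epoch in range(epochs):
            losses = []
            for s in range(self.steps_per_epoch):
                case = step % n_cases
                img, lab = self._patch(case, step // n_cases)
                if self.augmentation is not None:
                    img, lab = augment(img, lab, self.augmentation, aug_rng)
                scores = network.forward(img)
                loss, dscores = segmentation_loss(scores, lab, cfg.loss)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss {loss} at epoch {epoch}, step {s} "
                        f"(case {self.case_ids[case]})"
                    )
                network.backward(dscores)
                optimizer.step()
                losses.append(loss)
                step += 1
            trace.append(float(np.mean(losses)))
            if verbose and (epoch % 20 == 0 or epoch == epochs - 1):
                print(f"epoch {epoch:4d}  loss {trace[-1]:.4f}")
        return SegmentationResults(
            network=network, config=cfg, loss_trace=trace, case_ids=self.case_ids
        )


def predict(network: UNet3D, volume) -> np.ndarray:
    """Sliding-window inference: softmax scores of overlapping patches are
    accumulated by averaging, then argmax per voxel (ties break to the
    lowest class index). Output is congruent with the input grid."""
    img = normalize_volume(_as_array(volume))
    original_shape = img.shape
    cfg = network.config
    img, pads = pad_to_patch(img, cfg.patch_size)
    scores = np.zeros((cfg.n_classes,) + img.shape, dtype=np.float32)
    counts = np.zeros(img.shape, dtype=np.float32)
    p = cfg.patch_size
    for o in patch_origins(img.shape, p, cfg.stride):
        sl = tuple(slice(o[i], o[i] + p[i]) for i in range(3))
        probs = softmax(network.forward(img[sl]))
        scores[(slice(None),) + sl] += probs
        counts[sl] += 1.0
    scores /= counts[None]
    labels = scores.argmax(axis=0).astype(np.uint8)
    crop = tuple(
        slice(lo, lo + n) for (lo, _), n in zip(pads, original_shape)
    )
    return labels[crop]
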