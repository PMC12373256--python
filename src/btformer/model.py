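"""Model/Results facade over the training pipeline.

``BlastocystSegmenter`` is constructed from data plus configuration and
``fit()`` returns a ``SegmentationFit`` carrying the trained parameters,
the per-epoch history, held-out metrics and a ``summary()`` table;
prediction, evaluation, the receptive-field probe and plotting hang off
the results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import evaluate_masks, METRIC_NAMES
from .network import BTFormer, NetworkConfig, count_params_flops
from .phantom import CLASS_NAMES, make_dataset
from .training import (TrainConfig, TrainingHistory, compute_erf, evaluate,
                       load_checkpoint, predict, save_checkpoint, train)

__all__ = ["BlastocystSegmenter", "SegmentationFit"]


class BlastocystSegmenter:
    """Blastocyst-component segmentation model built from (image, mask) pairs.

    Parameters
    ----------
    train_pairs : list of (image, mask)
        Grayscale float images in [0, 1] with integer 5-class masks.
    val_pairs : list of (image, mask), optional
        Held-out pairs scored after every ``val_every`` epochs; when omitted,
        a seeded fraction of the training pairs is split off.
    network, training : configuration dataclasses (defaults documented in
        the methods note).
    """

    def __init__(self, train_pairs, val_pairs=None,
                 network: NetworkConfig | None = None,
                 training: TrainConfig | None = None):
        if not train_pairs:
            raise ValueError("train_pairs must be non-empty")
        self.train_pairs = list(train_pairs)
        self.val_pairs = list(val_pairs) if val_pairs is not None else None
        size = np.asarray(train_pairs[0][0]).shape[-1]
        self.network = network if network is not None else NetworkConfig.tiny(input_size=size)
        self.training = training if training is not None else TrainConfig()

    @classmethod
    def from_phantoms(cls, n_train: int = 200, n_val: int = 50, size: int = 64,
                      seed: int = 0, difficulty: str = "medium",
                      network: NetworkConfig | None = None,
                      training: TrainConfig | None = None) -> "BlastocystSegmenter":
        """Build a model on freshly generated phantoms (train and held-out
        sets come from disjoint seeds)."""
        train_ds = make_dataset(n_train, seed=seed, size=size, difficulty=difficulty)
        val_ds = make_dataset(n_val, seed=seed + 1_000_000, size=size, difficulty=difficulty)
        return cls(train_ds.pairs(), val_ds.pairs(), network=network, training=training)

    def fit(self, progress: bool = False) -> "SegmentationFit":
        model, history, best = train(self.train_pairs, self.network, self.training,
                                     val_pairs=self.val_pairs, progress=progress)
        return SegmentationFit(model=model, history=history, best=best,
                               network=self.network, training=self.training,
                               val_pairs=self.val_pairs)


@dataclass
class SegmentationFit:
    """Results of fitting a :class:`BlastocystSegmenter`."""

    model: BTFormer
    history: TrainingHistory
    best: dict
    network: NetworkConfig
    training: TrainConfig
    val_pairs: list | None = None

    @property
    def params(self) -> dict:
        return self.model.state_dict()

    def use_best(self) -> "SegmentationFit":
        """Load the best-validation-Dice parameters into the model."""
        if self.best.get("state"):
            self.model.load_state_dict(self.best["state"])
        return self

    # -- inference -------------------------------------------------------
    def predict(self, images, out_dir=None, names=None):
        return predict(self.model, images, out_dir=out_dir, names=names)

    def evaluate(self, pairs, reduction: str = "macro") -> dict:
        return evaluate(self.model, pairs, num_classes=self.network.class_count,
                        reduction=reduction)

    def erf(self, image, output_location=None, threshold_frac: float = 0.01) -> dict:
        if output_location is None:
            h = np.asarray(image).shape[-1] // 2
            output_location = (h, h)
        return compute_erf(self.model, image, output_location, threshold_frac)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        n_params, n_macs = count_params_flops(self.network)
        lines = [
            "Blastocyst segmentation fit",
            "=" * 60,
            f"network: {len(self.network.stage_channels)} attention stages "
            f"{self.network.stage_channels}, D={self.network.D}, "
            f"heads={self.network.heads}, pe={self.network.pe}, agg={self.network.agg}",
            f"parameters: {n_params:,}   forward MACs @{self.network.input_size}px: {n_macs:,}",
            f"loss: {self.training.loss}   epochs: {len(self.history.epochs)}"
            f"   base_lr: {self.training.base_lr}",
        ]
        final = self.history.epochs[-1]
        lines.append(f"final training loss: {final['loss']:.4f}")
        if "val_dice" in self.best and self.best.get("state") is not None:
            lines.append(f"best val macro Dice: {self.best['val_dice']:.2f}% "
                         f"(epoch {self.best['epoch']})")
        scored = [e for e in self.history.epochs if "val_dice_per_class" in e]
        if scored:
            lines.append("-" * 60)
            lines.append("per-class validation Dice (%) at last scored epoch:")
            for name, v in zip(CLASS_NAMES, scored[-1]["val_dice_per_class"]):
                lines.append(f"  {name:<12s} {v:6.2f}")
        lines.append("=" * 60)
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path):
        save_checkpoint(path, self.model, history=self.history,
                        extra={"best_epoch": self.best.get("epoch", -1),
                               "best_val_dice": self.best.get("val_dice")})

    @classmethod
    def load(cls, path) -> "SegmentationFit":
        model, meta = load_checkpoint(path)
        history = TrainingHistory(epochs=meta.get("history", []))
        best = {"epoch": meta["extra"].get("best_epoch", -1),
                "val_dice": meta["extra"].get("best_val_dice"), "state": None}
        return cls(model=model, history=history, best=best,
                   network=model.cfg, training=TrainConfig())

    # -- plotting ----------------------------------------------------------
    def plot_history(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        epochs = [e["epoch"] for e in self.history.epochs]
        losses = [e["loss"] for e in self.history.epochs]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(epochs, losses, label="training loss")
        scored = [(e["epoch"], e["val_dice"]) for e in self.history.epochs if "val_dice" in e]
        if scored:
            ax2 = ax.twinx()
            ax2.plot(*zip(*scored), color="C1", label="val macro Dice (%)")
            ax2.set_ylabel("val macro Dice (%)")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def plot_erf(self, image, output_location=None, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        erf = self.erf(image, output_location)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(np.asarray(image), cmap="gray")
        ys, xs = np.nonzero(erf["active"])
        ax.scatter(xs, ys, s=1, c="red", alpha=0.5)
        ax.plot(erf["location"][1], erf["location"][0], "b+")
        ax.set_title(f"ERF: {erf['count']} active pixels")
        ax.axis("off")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
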