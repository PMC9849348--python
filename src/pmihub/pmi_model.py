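"""The peritumoral microenvironment index (PMI) model.

A 2-class convolutional network is trained on 16x16 free-water patches from
vasogenic (``high_fw``) versus infiltrative (``low_fw``) edema.  Its softmax
probability of the ``low_fw`` (glioblastoma-like, infiltrative) class is the
PMI: at inference, the three cardinal-plane patches centered at each edema
voxel are evaluated and averaged, so HIGH PMI means infiltrative-looking
tissue.

Training uses SGD with momentum 0.9, weight decay 5e-5 and initial learning
rate 1e-4 (all configurable), with an internal held-out split reported in
the :class:`TrainReport`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cnn import CNN, SGDMomentum, softmax
from .nifti_io import FreeWaterVolume, SubjectMasks
from .patches import Patch, LABELS, _PLANE_AXES, PLANES

logger = logging.getLogger(__name__)

#: class index of the infiltrative, low-free-water class
LOW_FW = LABELS.index("low_fw")
HIGH_FW = LABELS.index("high_fw")


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published hyperparameters
    (lr 1e-4, momentum 0.9, weight decay 5e-5) with desk-scale epochs."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 5e-5
    epochs: int = 12
    batch_size: int = 16
    val_fraction: float = 0.2
    channels: tuple[int, ...] = (8, 8, 16, 16, 32, 32)
    seed: int = 0


@dataclass
class TrainReport:
    """Fit diagnostics: held-out accuracy and per-epoch loss trace."""

    val_accuracy: float
    train_accuracy: float
    n_train: int
    n_val: int
    loss_history: list = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"PMI patch classifier: train acc {self.train_accuracy:.3f} "
            f"(n={self.n_train}), held-out acc {self.val_accuracy:.3f} "
            f"(n={self.n_val}), final loss {self.loss_history[-1]:.4f}"
        )


class PMIModel:
    """Trained patch classifier producing voxel-wise PMI maps."""

    def __init__(self, patch_size: int = 16, cfg: TrainConfig | None = None):
        self.cfg = cfg or TrainConfig()
        self.patch_size = patch_size
        self.net = CNN(patch_size=patch_size, channels=self.cfg.channels, seed=self.cfg.seed)
        self.report: TrainReport | None = None
        #: orientation flag: probability column LOW_FW is the infiltrative class
        self.low_fw_index = LOW_FW

    # ------------------------------------------------------------------ fit
    def fit(self, patches: list[Patch]) -> TrainReport:
        """Train on labeled patches; returns (and stores) the train report."""
        if not patches:
            raise ValueError("no patches given")
        labels = {p.label for p in patches}
        if None in labels:
            raise ValueError("all training patches must be labeled")
        if len(labels) < 2:
            raise ValueError(f"training needs both classes, got only {labels}")
        sizes = {p.values.shape for p in patches}
        if len(sizes) != 1:
            raise ValueError(f"patches have mixed sizes: {sizes}")
        if next(iter(sizes)) != (self.patch_size, self.patch_size):
            raise ValueError("patch size does not match model configuration")

        x = np.stack([p.values for p in patches]).astype(np.float32)
        y = np.array([LABELS.index(p.label) for p in patches], dtype=np.int64)
        rng = np.random.default_rng(self.cfg.seed)
        order = rng.permutation(len(x))
        x, y = x[order], y[order]
        n_val = max(1, int(round(self.cfg.val_fraction * len(x))))
        x_val, y_val = x[:n_val], y[:n_val]
        x_tr, y_tr = x[n_val:], y[n_val:]
        if len(set(y_tr.tolist())) < 2:
            raise ValueError("training split ended up single-class; need more patches")

        opt = SGDMomentum(
            self.net, self.cfg.learning_rate, self.cfg.momentum, self.cfg.weight_decay
        )
        losses = []
        bs = self.cfg.batch_size
        for epoch in range(self.cfg.epochs):
            perm = rng.permutation(len(x_tr))
            epoch_loss = 0.0
            for start in range(0, len(x_tr), bs):
                idx = perm[start : start + bs]
                loss, _ = self.net.loss_and_grad(x_tr[idx], y_tr[idx])
                opt.step()
                epoch_loss += loss * len(idx)
            losses.append(epoch_loss / len(x_tr))
        self.report = TrainReport(
            val_accuracy=self._accuracy(x_val, y_val),
            train_accuracy=self._accuracy(x_tr, y_tr),
            n_train=len(x_tr),
            n_val=n_val,
            loss_history=losses,
        )
        logger.info(self.report.summary())
        return self.report

    def _accuracy(self, x: np.ndarray, y: np.ndarray, batch: int = 512) -> float:
        preds = []
        for start in range(0, len(x), batch):
            logits = self.net.forward(x[start : start + batch])
            preds.append(np.argmax(logits, axis=1))
        return float(np.mean(np.concatenate(preds) == y))

    # ------------------------------------------------------------- predict
    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a batch of patch arrays (B, p, p)."""
        values = np.asarray(values)
        if values.ndim == 2:
            values = values[None]
        if values.shape[-2:] != (self.patch_size, self.patch_size):
            raise ValueError(
                f"patch shape {values.shape[-2:]} does not match model "
                f"patch size {self.patch_size}"
            )
        return softmax(self.net.forward(values))

    def predict_patch(self, p: Patch | np.ndarray) -> float:
        """Probability of the low-free-water (infiltrative) class for one patch."""
        values = p.values if isinstance(p, Patch) else p
        return float(self.predict_proba(values)[0, self.low_fw_index])

    # ------------------------------------------------------------- persist
    def save(self, path: str | Path) -> None:
        """Checkpoint: weights plus config and class-orientation flag."""
        meta = {
            "patch_size": self.patch_size,
            "low_fw_index": self.low_fw_index,
            "cfg": asdict(self.cfg),
            "report": asdict(self.report) if self.report else None,
        }
        np.savez_compressed(path, __meta__=json.dumps(meta), **self.net.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "PMIModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = TrainConfig(**{**meta["cfg"], "channels": tuple(meta["cfg"]["channels"])})
            model = cls(patch_size=meta["patch_size"], cfg=cfg)
            model.low_fw_index = int(meta["low_fw_index"])
            model.net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
            if meta["report"]:
                model.report = TrainReport(**meta["report"])
        return model


def train(patches: list[Patch], cfg: TrainConfig | None = None, patch_size: int = 16) -> PMIModel:
    """Convenience wrapper: build a :class:`PMIModel` and fit it."""
    model = PMIModel(patch_size=patch_size, cfg=cfg)
    model.fit(patches)
    return model


# ---------------------------------------------------------------- PMI maps
@dataclass
class PMIMap:
    """Voxel-wise infiltration index, defined exactly on edema voxels.

    ``data`` is NaN outside edema; defined values lie in [0, 1].
    """

    data: np.ndarray
    edema: np.ndarray

    def __post_init__(self) -> None:
        defined = self.data[self.edema]
        if defined.size and (np.nanmin(defined) < -1e-9 or np.nanmax(defined) > 1 + 1e-9):
            raise ValueError("PMI values must lie in [0, 1]")

    def defined_values(self) -> np.ndarray:
        return self.data[self.edema]


def _plane_slices(shape, fixed_axis: int, index: int):
    sl = [slice(None)] * 3
    sl[fixed_axis] = index
    return tuple(sl)


def pmi_map(model, vol: FreeWaterVolume, masks: SubjectMasks) -> PMIMap:
    """Compute the PMI map: per edema voxel, the mean p(low_fw) of the three
    cardinal-plane patches centered there.

    The volume is zero-padded by ``patch_size // 2`` per side so border
    voxels always have fully defined patches.  ``model`` needs a
    ``predict_proba`` / ``low_fw_index`` /  ``patch_size`` surface; when it
    also exposes a fully convolutional ``net.dense_logits`` (as
    :class:`PMIModel` does) whole slices are evaluated in one pass.
    """
    ps = model.patch_size
    half = ps // 2
    edema = masks.edema
    out = np.full(vol.shape, np.nan)
    if not edema.any():
        logger.warning("empty edema mask: returning empty PMI map")
        return PMIMap(out, edema)

    padded = np.pad(vol.data, half)
    accum = np.zeros(vol.shape)
    idx = np.argwhere(edema)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)

    fast = hasattr(model, "net") and hasattr(model.net, "dense_logits_batch")
    slice_chunk = 8  # slices per dense batch; bounds peak im2col memory
    for plane in PLANES:
        a1, a2 = _PLANE_AXES[plane]
        fixed_axis = ({0, 1, 2} - {a1, a2}).pop()
        if fast:
            # crop the padded volume to the edema bounding box in-plane:
            # dense position (r, c) in the crop is the patch centered at
            # voxel (lo1 + r, lo2 + c)
            lo1, lo2 = lo[a1], lo[a2]
            n1 = hi[a1] - lo1 + 1
            n2 = hi[a2] - lo2 + 1
            crop = [slice(None)] * 3
            crop[a1] = slice(lo1, hi[a1] + 1 + ps)
            crop[a2] = slice(lo2, hi[a2] + 1 + ps)
            crop[fixed_axis] = slice(lo[fixed_axis] + half, hi[fixed_axis] + 1 + half)
            sub = np.moveaxis(padded[tuple(crop)], fixed_axis, 0)
            emask = np.moveaxis(edema, fixed_axis, 0)[
                lo[fixed_axis] : hi[fixed_axis] + 1,
                lo1 : hi[a1] + 1,
                lo2 : hi[a2] + 1,
            ]
            acc_view = np.moveaxis(accum, fixed_axis, 0)
            for start in range(0, sub.shape[0], slice_chunk):
                chunk = sub[start : start + slice_chunk]
                logits = model.net.dense_logits_batch(chunk)
                probs = softmax(logits)[..., model.low_fw_index][:, :n1, :n2]
                msk = emask[start : start + slice_chunk]
                acc_view[
                    lo[fixed_axis] + start : lo[fixed_axis] + start + len(chunk),
                    lo1 : hi[a1] + 1,
                    lo2 : hi[a2] + 1,
                ] += np.where(msk, probs, 0.0)
        else:
            for s in range(lo[fixed_axis], hi[fixed_axis] + 1):
                mask2d = np.take(edema, s, axis=fixed_axis)
                if not mask2d.any():
                    continue
                plane2d = np.take(padded, s + half, axis=fixed_axis)
                rr, cc = np.nonzero(mask2d)
                batch = np.empty((len(rr), ps, ps), dtype=np.float64)
                for b, (r, c) in enumerate(zip(rr, cc)):
                    batch[b] = plane2d[r : r + ps, c : c + ps]
                probs = model.predict_proba(batch)[:, model.low_fw_index]
                sl = _plane_slices(vol.shape, fixed_axis, s)
                target = accum[sl]
                target[rr, cc] += probs
    out[edema] = accum[edema] / len(PLANES)
    return PMIMap(np.clip(out, 0.0, 1.0), edema)
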