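"""Patch-based classification of wound tissue.

The region of interest is black-masked (pixels outside the wound set to
zero), cropped to its bounding box, resized to 200 x 200, and divided
into a non-overlapping grid of 5 x 5-pixel patches.  Each patch is
labelled by the majority tissue label of its cell (necrotic, slough or
granulated); cells with more than 50% background are dropped.  Training
patches may be augmented with horizontal flips and mild zooms, the
dataset is split 80/20 stratified by tissue class with whole source
images kept on one side of the split, and a compact convolutional
network is trained by mini-batch SGD on the tissue cross-entropy.

The classification head is: flatten -> dense with ReLU -> dropout at
rate 0.3 -> dense with softmax over the tissue classes.  The feature
extractor in front of it is a small two-layer convolutional backbone
trained from scratch; at 5 x 5-patch scale colour is the dominant
signal, which matches the clinical rationale that tissue proportions
are judged by colour.  The per-example losses are the standard
multi-class cross-entropies

    Ls(y_i) = -sum_j y_ij log Ps(y_ij),   Lt(z_i) = -sum_k z_ik log Pt(z_ik)

for the size and tissue tasks, and the overall objective is their sum
over examples, J = sum_i (Ls_i + Lt_i).  The size branch itself is a
deterministic thresholding of the measured area into small / medium /
large categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import zoom as nd_zoom
from skimage.transform import resize

from woundmetric.raster_io import BinaryMask, LabelMask, RgbImage

TISSUE_CLASSES = ("necrotic", "slough", "granulated")
PATCH_SIZE = 5
ROI_SIZE = 200

#: (small_max, medium_max) in cm^2: area < 5 is small, < 20 medium, else large
DEFAULT_SIZE_THRESHOLDS = (5.0, 20.0)
SIZE_CLASSES = ("small", "medium", "large")


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TissueExample:
    """One labelled 5x5 patch with normalised intensities in [0, 1]."""

    patch: np.ndarray  # (5, 5, 3) float
    tissue_label: str
    source_scene: str
    split: str | None = None  # "train" | "test" | None


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_roi(image: RgbImage, roi: BinaryMask) -> np.ndarray:
    """Black-mask, crop to the ROI bounding box, resize to 200x200.

    Returns a float raster with intensities in [0, 1]; pixels outside
    the ROI are black.  Bilinear interpolation.
    """
    if roi.area_px == 0:
        raise ValueError("empty ROI")
    if roi.shape != (image.height, image.width):
        raise ValueError("ROI shape does not match image")
    masked = image.pixels.astype(float) / 255.0
    masked[~roi.pixels] = 0.0
    rows = np.any(roi.pixels, axis=1)
    cols = np.any(roi.pixels, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    crop = masked[r0:r1 + 1, c0:c1 + 1]
    return resize(crop, (ROI_SIZE, ROI_SIZE, 3), order=1,
                  anti_aliasing=False, preserve_range=True)


def align_labels(labels: LabelMask, roi: BinaryMask) -> LabelMask:
    """Apply the same crop/resize to the label raster, nearest-neighbour.

    Labels outside the ROI are zeroed so patch extraction sees the same
    black-masked support as the processed image.
    """
    if roi.area_px == 0:
        raise ValueError("empty ROI")
    lab = np.where(roi.pixels, labels.pixels, 0)
    rows = np.any(roi.pixels, axis=1)
    cols = np.any(roi.pixels, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    crop = lab[r0:r1 + 1, c0:c1 + 1]
    out = resize(crop.astype(float), (ROI_SIZE, ROI_SIZE), order=0,
                 anti_aliasing=False, preserve_range=True)
    return LabelMask(out.astype(np.uint8), labels.legend)


def extract_patches(processed: np.ndarray, labels: LabelMask,
                    source_scene: str = "scene-0") -> list[TissueExample]:
    """Cut the 200x200 ROI into a 40x40 grid of 5x5 patches.

    Each cell is labelled by the majority non-background tissue label;
    cells with more than 50% background pixels are dropped.
    """
    if processed.shape[:2] != labels.shape:
        raise ValueError("processed raster and labels are misaligned")
    H, W = labels.shape
    legend = dict(labels.legend)
    examples = []
    for r in range(0, H - PATCH_SIZE + 1, PATCH_SIZE):
        for c in range(0, W - PATCH_SIZE + 1, PATCH_SIZE):
            cell = labels.pixels[r:r + PATCH_SIZE, c:c + PATCH_SIZE]
            n_bg = int(np.count_nonzero(cell == 0))
            if n_bg * 2 > cell.size:
                continue
            fg = cell[cell > 0]
            counts = np.bincount(fg)
            majority = int(np.argmax(counts))
            examples.append(TissueExample(
                patch=np.ascontiguousarray(
                    processed[r:r + PATCH_SIZE, c:c + PATCH_SIZE]),
                tissue_label=legend.get(majority, str(majority)),
                source_scene=source_scene,
            ))
    return examples


def augment(examples: list[TissueExample], seed: int = 0,
            zoom_range: tuple[float, float] = (0.9, 1.1)) -> list[TissueExample]:
    """Add horizontally flipped and mildly zoomed copies of each patch.

    Only training examples may be augmented; n inputs yield 3n outputs.
    Deterministic under the seed.
    """
    if any(ex.split == "test" for ex in examples):
        raise ValueError("test examples must not be augmented")
    rng = np.random.default_rng(seed)
    out = list(examples)
    for ex in examples:
        out.append(replace(ex, patch=ex.patch[:, ::-1].copy()))
        z = float(rng.uniform(*zoom_range))
        out.append(replace(ex, patch=_zoom_patch(ex.patch, z)))
    return out


def _zoom_patch(patch: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return patch.copy()
    zoomed = nd_zoom(patch, (factor, factor, 1.0), order=1)
    return np.clip(
        resize(zoomed, (PATCH_SIZE, PATCH_SIZE, 3), order=1,
               anti_aliasing=False, preserve_range=True),
        0.0, 1.0,
    )


def split_dataset(examples: list[TissueExample], fraction: float = 0.8,
                  seed: int = 0) -> tuple[list[TissueExample], list[TissueExample]]:
    """Stratified 80/20 train/test split, assigned per source scene.

    Whole scenes go to one side so no scene leaks across the split;
    scenes are assigned greedily (in seeded shuffled order) to whichever
    side has the larger remaining per-class need, which keeps each
    class's train fraction as close to ``fraction`` as the scene
    granularity allows (exactly within one example when every scene
    holds a single example).
    """
    classes = sorted({ex.tissue_label for ex in examples})
    class_totals = {c: sum(ex.tissue_label == c for ex in examples) for c in classes}
    for c, n in class_totals.items():
        if n < 10:
            raise ValueError(f"class {c!r} has only {n} examples (need >= 10)")

    by_scene: dict[str, list[TissueExample]] = {}
    for ex in examples:
        by_scene.setdefault(ex.source_scene, []).append(ex)
    scene_ids = sorted(by_scene)
    rng = np.random.default_rng(seed)
    rng.shuffle(scene_ids)

    target_train = {c: fraction * n for c, n in class_totals.items()}
    target_test = {c: (1 - fraction) * n for c, n in class_totals.items()}
    got_train = dict.fromkeys(classes, 0)
    got_test = dict.fromkeys(classes, 0)

    train: list[TissueExample] = []
    test: list[TissueExample] = []
    for sid in scene_ids:
        scene_counts = {c: sum(ex.tissue_label == c for ex in by_scene[sid])
                        for c in classes}
        need_train = sum(
            scene_counts[c] * max(target_train[c] - got_train[c], 0.0)
            for c in classes)
        need_test = sum(
            scene_counts[c] * max(target_test[c] - got_test[c], 0.0)
            for c in classes)
        if need_train >= need_test:
            for ex in by_scene[sid]:
                train.append(replace(ex, split="train"))
                got_train[ex.tissue_label] += 1
        else:
            for ex in by_scene[sid]:
                test.append(replace(ex, split="test"))
                got_test[ex.tissue_label] += 1
    return train, test


# ---------------------------------------------------------------------------
# losses and objective


def cross_entropy_loss(true_onehot: np.ndarray, predicted_probs: np.ndarray) -> float:
    """Multi-class cross-entropy, natural log; probabilities clamped at 1e-12."""
    z = np.asarray(true_onehot, dtype=float)
    p = np.asarray(predicted_probs, dtype=float)
    if z.shape != p.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {p.shape}")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("predicted probabilities must sum to 1")
    return float(-np.sum(z * np.log(np.clip(p, 1e-12, None))))


@dataclass(frozen=True)
class CombinedObjective:
    total: float
    mean_per_example: float

    def __float__(self) -> float:
        return self.total


def combined_objective(size_losses, tissue_losses) -> CombinedObjective:
    """Overall objective J = sum_i (Ls_i + Lt_i) over the same examples."""
    ls = np.asarray(size_losses, dtype=float)
    lt = np.asarray(tissue_losses, dtype=float)
    if ls.shape != lt.shape:
        raise ValueError("loss lists must be index-aligned and equal length")
    total = float(np.sum(ls + lt))
    return CombinedObjective(total, total / len(ls) if len(ls) else 0.0)


def size_category(area_cm2: float,
                  thresholds: tuple[float, float] = DEFAULT_SIZE_THRESHOLDS) -> str:
    """Deterministic size branch: small / medium / large by measured area.

    Left-closed boundaries: area equal to a threshold falls in the
    larger category.
    """
    small_max, medium_max = thresholds
    if not (0 < small_max < medium_max):
        raise ValueError("thresholds must be increasing and positive")
    if area_cm2 < 0:
        raise ValueError("area must be non-negative")
    if area_cm2 < small_max:
        return "small"
    if area_cm2 < medium_max:
        return "medium"
    return "large"


# ---------------------------------------------------------------------------
# the compact network


@dataclass
class TrainingConfig:
    epochs: int = 120
    batch_size: int = 64
    learning_rate: float = 0.05
    dropout: float = 0.3
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0


@dataclass
class TissueModel:
    """Compact convolutional tissue classifier.

    Backbone: two valid-padding 3x3 convolutions (3->8 and 8->16
    channels, ReLU) reducing a 5x5x3 patch to a 16-vector.  Head:
    flatten -> dense(32, ReLU) -> dropout(0.3) -> dense(softmax over the
    tissue classes).
    """

    weights: dict[str, np.ndarray]
    classes: tuple[str, ...] = TISSUE_CLASSES
    training_config: TrainingConfig = field(default_factory=TrainingConfig)
    loss_history: list[float] = field(default_factory=list)

    HIDDEN = 32
    C1, C2 = 8, 16

    @classmethod
    def initialise(cls, seed: int = 0, n_classes: int = 3,
                   config: TrainingConfig | None = None) -> "TissueModel":
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)

        w = {
            "W1": he((27, cls.C1), 27), "b1": np.zeros(cls.C1),
            "W2": he((9 * cls.C1, cls.C2), 9 * cls.C1), "b2": np.zeros(cls.C2),
            "W3": he((cls.C2, cls.HIDDEN), cls.C2), "b3": np.zeros(cls.HIDDEN),
            "W4": he((cls.HIDDEN, n_classes), cls.HIDDEN), "b4": np.zeros(n_classes),
        }
        return cls(weights=w,
                   classes=TISSUE_CLASSES[:n_classes],
                   training_config=config or TrainingConfig(seed=seed))

    # -- forward/backward ---------------------------------------------------

    @staticmethod
    def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
        """(B, H, W, C) -> (B, positions, k*k*C) for valid k x k windows."""
        B, H, W, C = x.shape
        out_h, out_w = H - k + 1, W - k + 1
        s = x.strides
        windows = np.lib.stride_tricks.as_strided(
            x, (B, out_h, out_w, k, k, C),
            (s[0], s[1], s[2], s[1], s[2], s[3]), writeable=False)
        return windows.reshape(B, out_h * out_w, k * k * C)

    def _forward(self, x: np.ndarray, dropout_rng: np.random.Generator | None):
        w = self.weights
        cache: dict[str, np.ndarray] = {}
        cols1 = self._im2col(x)                         # (B, 9, 27)
        z1 = cols1 @ w["W1"] + w["b1"]                  # (B, 9, 8)
        a1 = np.maximum(z1, 0.0)
        a1_img = a1.reshape(-1, 3, 3, self.C1)
        cols2 = self._im2col(a1_img)                    # (B, 1, 72)
        z2 = cols2 @ w["W2"] + w["b2"]                  # (B, 1, 16)
        a2 = np.maximum(z2, 0.0).reshape(-1, self.C2)   # flatten
        z3 = a2 @ w["W3"] + w["b3"]
        a3 = np.maximum(z3, 0.0)
        if dropout_rng is not None:
            keep = 1.0 - self.training_config.dropout
            mask = (dropout_rng.random(a3.shape) < keep) / keep
            d3 = a3 * mask
            cache["dropout_mask"] = mask
        else:
            d3 = a3
        z4 = d3 @ w["W4"] + w["b4"]
        z4 = z4 - z4.max(axis=1, keepdims=True)
        expz = np.exp(z4)
        probs = expz / expz.sum(axis=1, keepdims=True)
        cache.update(cols1=cols1, z1=z1, cols2=cols2, z2=z2, a2=a2,
                     z3=z3, d3=d3, probs=probs)
        return probs, cache

    def _backward(self, onehot: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        w = self.weights
        B = onehot.shape[0]
        g: dict[str, np.ndarray] = {}
        dz4 = (cache["probs"] - onehot) / B             # (B, K)
        g["W4"] = cache["d3"].T @ dz4
        g["b4"] = dz4.sum(axis=0)
        dd3 = dz4 @ w["W4"].T
        if "dropout_mask" in cache:
            dd3 = dd3 * cache["dropout_mask"]
        dz3 = dd3 * (cache["z3"] > 0)
        g["W3"] = cache["a2"].T @ dz3
        g["b3"] = dz3.sum(axis=0)
        da2 = dz3 @ w["W3"].T                           # (B, 16)
        dz2 = (da2 * (cache["z2"].reshape(-1, self.C2) > 0))[:, None, :]  # (B,1,16)
        g["W2"] = np.einsum("bpk,bpc->kc", cache["cols2"], dz2)
        g["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = dz2 @ w["W2"].T                        # (B, 1, 72)
        da1 = dcols2.reshape(-1, 3, 3, self.C1).reshape(-1, 9, self.C1)
        dz1 = da1 * (cache["z1"] > 0)
        g["W1"] = np.einsum("bpk,bpc->kc", cache["cols1"], dz1)
        g["b1"] = dz1.sum(axis=(0, 1))
        return g

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Softmax class probabilities; rows sum to 1."""
        probs, _ = self._forward(np.asarray(patches, dtype=float), None)
        return probs

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return self.predict_proba(patches).argmax(axis=1)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        import json
        doc = {
            "classes": list(self.classes),
            "weights": {k: v.tolist() for k, v in self.weights.items()},
            "config": vars(self.training_config),
            "loss_history": self.loss_history,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "TissueModel":
        import json
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            weights={k: np.asarray(v) for k, v in doc["weights"].items()},
            classes=tuple(doc["classes"]),
            training_config=TrainingConfig(**doc["config"]),
            loss_history=list(doc["loss_history"]),
        )


def _examples_to_arrays(examples: list[TissueExample],
                        classes: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([ex.patch for ex in examples]).astype(float)
    idx = {c: i for i, c in enumerate(classes)}
    y = np.array([idx[ex.tissue_label] for ex in examples])
    return x, y


def train(model: TissueModel, train_examples: list[TissueExample],
          config: TrainingConfig | None = None) -> TissueModel:
    """Mini-batch SGD on the mean tissue cross-entropy.

    Deterministic under the config seed (fixed initialisation, fixed
    shuffles, fixed dropout draws).  A held-out 10% of the training
    examples drives early stopping: training halts when validation loss
    has not improved for ``patience`` epochs, and the best-validation
    weights are returned.  The per-epoch mean training loss is recorded
    on the returned model.
    """
    cfg = config or model.training_config
    model = TissueModel(weights={k: v.copy() for k, v in model.weights.items()},
                        classes=model.classes, training_config=cfg)
    if cfg.epochs == 0:
        return model
    if not train_examples:
        raise ValueError("empty training set")

    x, y = _examples_to_arrays(train_examples, model.classes)
    n_classes = len(model.classes)
    onehot = np.eye(n_classes)[y]

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(x))
    n_val = max(int(round(cfg.val_fraction * len(x))), 1) if len(x) >= 10 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    xv, ov = x[val_idx], onehot[val_idx]
    xt, ot = x[tr_idx], onehot[tr_idx]

    best_val = np.inf
    best_weights = {k: v.copy() for k, v in model.weights.items()}
    stale = 0
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(len(xt))
        epoch_losses = []
        for start in range(0, len(xt), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            probs, cache = model._forward(xt[idx], rng)
            loss = float(-np.mean(
                np.sum(ot[idx] * np.log(np.clip(probs, 1e-12, None)), axis=1)))
            if not np.isfinite(loss):
                raise TrainingError(
                    f"loss diverged at epoch {_epoch} (loss={loss})")
            grads = model._backward(ot[idx], cache)
            for k, gk in grads.items():
                model.weights[k] -= cfg.learning_rate * gk
            epoch_losses.append(loss)
        model.loss_history.append(float(np.mean(epoch_losses)))

        if n_val:
            pv = model.predict_proba(xv)
            val_loss = float(-np.mean(
                np.sum(ov * np.log(np.clip(pv, 1e-12, None)), axis=1)))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = {k: v.copy() for k, v in model.weights.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if n_val:
        model.weights = best_weights
    return model


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class EvalReport:
    """Per-class precision/recall/F1 with supports, macro averages,
    overall accuracy and the raw confusion matrix (rows = true class)."""

    per_class: dict[str, dict[str, float]]
    macro_avg: dict[str, float]
    overall_accuracy: float
    confusion: np.ndarray
    classes: tuple[str, ...]


def evaluate(model: TissueModel, test_examples: list[TissueExample]) -> EvalReport:
    """Argmax predictions scored against the labels of a held-out set."""
    if not test_examples:
        raise ValueError("empty test set")
    x, y = _examples_to_arrays(test_examples, model.classes)
    pred = model.predict(x)
    k = len(model.classes)
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y, pred), 1)

    per_class: dict[str, dict[str, float]] = {}
    f1s, precs, recs = [], [], []
    for i, name in enumerate(model.classes):
        tp = confusion[i, i]
        support = int(confusion[i].sum())
        pred_pos = int(confusion[:, i].sum())
        if support == 0:
            warnings.warn(f"class {name!r} absent from test set", stacklevel=2)
            rec = float("nan")
        else:
            rec = tp / support
        prec = tp / pred_pos if pred_pos else 0.0
        f1 = (2 * prec * rec / (prec + rec)
              if support and (prec + rec) > 0 else
              (float("nan") if support == 0 else 0.0))
        per_class[name] = {"precision": float(prec), "recall": float(rec),
                           "f1": float(f1), "support": support}
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    macro = {"precision": float(np.mean(precs)), "recall": float(np.mean(recs)),
             "f1": float(np.mean(f1s))}
    return EvalReport(
        per_class=per_class,
        macro_avg=macro,
        overall_accuracy=float(confusion.trace() / confusion.sum()),
        confusion=confusion,
        classes=model.classes,
    )


def tissue_fractions(model: TissueModel, processed: np.ndarray,
                     roi_labels: LabelMask | None = None,
                     wound_patch_mask: np.ndarray | None = None) -> dict[str, float]:
    """Predicted per-tissue fractions of the wound area.

    Classifies every 5x5 grid cell of the processed ROI that contains
    wound (non-black) pixels and returns the class frequencies; the
    fractions sum to 1.
    """
    cells = []
    for r in range(0, ROI_SIZE - PATCH_SIZE + 1, PATCH_SIZE):
        for c in range(0, ROI_SIZE - PATCH_SIZE + 1, PATCH_SIZE):
            patch = processed[r:r + PATCH_SIZE, c:c + PATCH_SIZE]
            n_bg = int(np.count_nonzero(patch.sum(axis=2) == 0))
            if n_bg * 2 > PATCH_SIZE * PATCH_SIZE:
                continue
            cells.append(patch)
    if not cells:
        raise ValueError("ROI contains no classifiable patches")
    pred = model.predict(np.stack(cells))
    counts = np.bincount(pred, minlength=len(model.classes))
    fr = counts / counts.sum()
    return {name: float(f) for name, f in zip(model.classes, fr)}


def build_dataset(scenes, max_patches_per_scene: int | None = None,
                  seed: int = 0) -> list[TissueExample]:
    """Patch dataset from rendered scenes with ground-truth labels."""
    rng = np.random.default_rng(seed)
    examples: list[TissueExample] = []
    for i, scene in enumerate(scenes):
        processed = preprocess_roi(scene.image, scene.wound_mask)
        labels = align_labels(scene.tissue_labels, scene.wound_mask)
        ex = extract_patches(processed, labels, source_scene=f"scene-{i}")
        if max_patches_per_scene is not None and len(ex) > max_patches_per_scene:
            keep = rng.choice(len(ex), size=max_patches_per_scene, replace=False)
            ex = [ex[j] for j in sorted(keep)]
        examples.extend(ex)
    return examples
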