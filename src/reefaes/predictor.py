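"""Image-to-rating predictor: split, augmentation, training, evaluation.

The protocol mirrors the survey-to-model pipeline: the rated photo set
is partitioned 70/15/15 into train/validation/test, training images
are augmented with random rotation and flips, the model state with the
best validation loss is kept, and accuracy is the squared Pearson
correlation between predictions and held-out ratings.

Two backends are provided: a compact convolutional regressor trained
from scratch on small crops (``small_cnn``), and an ordinary linear
model on the nine photograph features (``linear_on_features``) that
serves as a transparent baseline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import pearsonr
from skimage.transform import rotate as sk_rotate
from sklearn.linear_model import LinearRegression

from ._cnn import SmallCNN
from .elo import EloRatings

__all__ = [
    "SplitSpec",
    "PredictorConfig",
    "TrainedModel",
    "split_dataset",
    "augment",
    "hflip",
    "vflip",
    "train",
    "evaluate_r2",
    "predict_all",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (largest-remainder rounding)."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")


@dataclass(frozen=True)
class PredictorConfig:
    backend: str = "small_cnn"
    input_side: int = 64
    epochs: int = 40
    learning_rate: float = 3e-3
    batch_size: int = 32
    augmentations: tuple[str, ...] = ("rotation", "hflip", "vflip")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("small_cnn", "linear_on_features"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.input_side < 16:
            raise ValueError("input_side must be >= 16")
        bad = set(self.augmentations) - {"rotation", "hflip", "vflip"}
        if bad:
            raise ValueError(f"unknown augmentations: {sorted(bad)}")


def split_dataset(
    ids: Sequence[str], spec: SplitSpec | None = None
) -> tuple[list[str], list[str], list[str]]:
    """Disjoint, exhaustive train/val/test partition of the photo ids.

    Sizes follow largest-remainder rounding of the fractions (ties
    resolved in train > val > test order); the shuffle is fixed by the
    spec seed.
    """
    if spec is None:
        spec = SplitSpec()
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    n = len(ids)
    raw = [f * n for f in spec.fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainder = n - sum(sizes)
    by_frac = sorted(range(3), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in range(remainder):
        sizes[by_frac[i % 3]] += 1
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    train_ids = shuffled[: sizes[0]]
    val_ids = shuffled[sizes[0] : sizes[0] + sizes[1]]
    test_ids = shuffled[sizes[0] + sizes[1] :]
    return train_ids, val_ids, test_ids


def hflip(img: np.ndarray) -> np.ndarray:
    return img[:, ::-1].copy()


def vflip(img: np.ndarray) -> np.ndarray:
    return img[::-1].copy()


def augment(
    img: np.ndarray,
    cfg: PredictorConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Randomly rotate (+-180 deg, reflect padding) and/or flip an image."""
    cfg = cfg or PredictorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = img
    if "rotation" in cfg.augmentations:
        angle = float(rng.uniform(-180.0, 180.0))
        out = rotate_image(out, angle)
    if "hflip" in cfg.augmentations and rng.random() < 0.5:
        out = hflip(out)
    if "vflip" in cfg.augmentations and rng.random() < 0.5:
        out = vflip(out)
    return out


def rotate_image(img: np.ndarray, angle: float) -> np.ndarray:
    """Rotate by ``angle`` degrees with edge reflection; 0 is the identity."""
    if angle == 0.0:
        return img.copy()
    was_uint8 = img.dtype == np.uint8
    rot = sk_rotate(
        img.astype(float), angle, mode="reflect", preserve_range=True, order=1
    )
    return np.clip(rot, 0, 255).astype(np.uint8) if was_uint8 else rot


def _prep_image(img: np.ndarray, side: int) -> np.ndarray:
    if img.shape[0] != side or img.shape[1] != side:
        im = Image.fromarray(np.asarray(img, dtype=np.uint8))
        # nearest-neighbour subsampling: unlike interpolation it invents no
        # blended colours, so the image's colour distribution (which the
        # diversity-driven aesthetic signal lives in) is preserved
        img = np.asarray(im.resize((side, side), resample=Image.NEAREST))
    return img.astype(np.float32) / 255.0 - 0.5


def _ratings_lookup(ratings) -> Mapping[str, float]:
    if isinstance(ratings, EloRatings):
        return ratings.as_series().to_dict()
    if isinstance(ratings, pd.Series):
        return ratings.to_dict()
    return dict(ratings)


@dataclass
class TrainedModel:
    """A fitted predictor plus the state needed to apply it."""

    backend: str
    config: PredictorConfig
    net: SmallCNN | None = None
    linear: LinearRegression | None = None
    feature_names: tuple[str, ...] = ()
    y_mean: float = 0.0
    y_sd: float = 1.0
    history: list = field(default_factory=list)
    val_r2: float = float("nan")

    def predict_ids(self, data, ids: Sequence[str]) -> np.ndarray:
        """Predict ratings for ``ids``; ``data`` is the image mapping
        (small_cnn) or the image_id-indexed feature frame (linear)."""
        if self.backend == "small_cnn":
            xs = []
            for i in ids:
                if i not in data:
                    raise KeyError(f"no image available for id {i!r}")
                xs.append(_prep_image(data[i], self.config.input_side))
            z = self.net.predict(np.stack(xs))
        else:
            missing = [i for i in ids if i not in data.index]
            if missing:
                raise KeyError(f"no features available for ids {missing}")
            x = data.loc[list(ids), list(self.feature_names)].to_numpy(dtype=float)
            z = self.linear.predict(x)
        return z * self.y_sd + self.y_mean

    # checkpointing: single npz with a json metadata sidecar
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {} if self.net is None else self.net.params()
        if self.linear is not None:
            arrays = {"coef": self.linear.coef_, "intercept": np.asarray(self.linear.intercept_)}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "backend": self.backend,
            "config": self.config.__dict__ | {"augmentations": list(self.config.augmentations)},
            "feature_names": list(self.feature_names),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "val_r2": self.val_r2,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_d = dict(meta["config"])
        cfg_d["augmentations"] = tuple(cfg_d["augmentations"])
        cfg = PredictorConfig(**cfg_d)
        data = np.load(path.with_suffix(".npz"))
        model = cls(
            backend=meta["backend"], config=cfg,
            feature_names=tuple(meta["feature_names"]),
            y_mean=meta["y_mean"], y_sd=meta["y_sd"],
            history=meta["history"], val_r2=meta["val_r2"],
        )
        if model.backend == "small_cnn":
            net = SmallCNN(in_side=cfg.input_side, seed=cfg.seed)
            net.set_params({k: data[k] for k in data.files})
            model.net = net
        else:
            lin = LinearRegression()
            lin.coef_ = data["coef"]
            lin.intercept_ = float(data["intercept"])
            model.linear = lin
        return model


def _make_augment_fn(cfg: PredictorConfig):
    if not cfg.augmentations:
        return None

    def fn(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty_like(batch)
        for i, img in enumerate(batch):
            # augment operates on the prepared float image; rotation's
            # reflect padding and flips are value-preserving there
            out[i] = augment(img, cfg, rng)
        return out

    return fn


def train(
    train_ids: Sequence[str],
    val_ids: Sequence[str],
    ratings,
    cfg: PredictorConfig | None = None,
    images: Mapping[str, np.ndarray] | None = None,
    features: pd.DataFrame | None = None,
) -> TrainedModel:
    """Fit the configured backend on the training ids.

    Only train and validation entries of ``images`` / ``features`` are
    ever read, so held-out test photographs cannot leak into training.
    Targets are standardized by the training-set mean/SD; predictions
    are returned on the original rating scale.
    """
    cfg = cfg or PredictorConfig()
    if not train_ids:
        raise ValueError("empty training set")
    look = _ratings_lookup(ratings)
    missing = [i for i in list(train_ids) + list(val_ids) if i not in look]
    if missing:
        raise ValueError(f"ids without ratings: {missing}")

    y_train = np.array([look[i] for i in train_ids], dtype=float)
    y_val = np.array([look[i] for i in val_ids], dtype=float)
    y_mean, y_sd = float(y_train.mean()), float(y_train.std())
    if y_sd == 0:
        y_sd = 1.0
    z_train = (y_train - y_mean) / y_sd
    z_val = (y_val - y_mean) / y_sd

    if cfg.backend == "small_cnn":
        if images is None:
            raise ValueError("small_cnn backend requires images")
        x_train = np.stack([_prep_image(images[i], cfg.input_side) for i in train_ids])
        x_val = np.stack([_prep_image(images[i], cfg.input_side) for i in val_ids])
        net = SmallCNN(in_side=cfg.input_side, seed=cfg.seed)
        history = net.fit(
            x_train, z_train, x_val, z_val,
            epochs=cfg.epochs, learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size, seed=cfg.seed,
            augment_fn=_make_augment_fn(cfg),
        )
        model = TrainedModel(
            backend=cfg.backend, config=cfg, net=net,
            y_mean=y_mean, y_sd=y_sd, history=history,
        )
        data = images
    else:
        if features is None:
            raise ValueError("linear_on_features backend requires a feature frame")
        feature_names = tuple(c for c in features.columns if c != "image_id")
        x_train = features.loc[list(train_ids), list(feature_names)].to_numpy(dtype=float)
        lin = LinearRegression().fit(x_train, z_train)
        model = TrainedModel(
            backend=cfg.backend, config=cfg, linear=lin,
            feature_names=feature_names, y_mean=y_mean, y_sd=y_sd,
        )
        data = features

    if len(val_ids) >= 3:
        val_pred = model.predict_ids(data, val_ids)
        if np.std(val_pred) > 0 and np.std(y_val) > 0:
            model.val_r2 = float(pearsonr(val_pred, y_val)[0] ** 2)
    return model


def evaluate_r2(model: TrainedModel, test_ids: Sequence[str], ratings, data) -> float:
    """Squared Pearson correlation between predictions and held-out ratings."""
    if len(test_ids) < 3:
        raise ValueError("need at least 3 test points to estimate r^2")
    look = _ratings_lookup(ratings)
    y = np.array([look[i] for i in test_ids], dtype=float)
    pred = model.predict_ids(data, test_ids)
    if np.std(pred) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: constant predictions or ratings")
    r = float(pearsonr(pred, y)[0])
    if r < 0:
        warnings.warn(
            f"predictions anti-correlate with ratings (r = {r:.3f}); "
            "r^2 ignores the sign",
            stacklevel=2,
        )
    return r * r


def predict_all(model: TrainedModel, ids: Sequence[str], data) -> pd.Series:
    """One finite predicted rating per photo id."""
    pred = model.predict_ids(data, ids)
    if not np.all(np.isfinite(pred)):
        bad = [i for i, p in zip(ids, pred) if not np.isfinite(p)]
        raise ValueError(f"non-finite predictions for ids {bad}")
    return pd.Series(pred, index=pd.Index(ids, name="image_id"), name="predicted_rating")
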