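"""Benthic annotation: point-intercept cover and morphology counts.

Percent cover is estimated the way a human annotator works through
point-count software: a fixed number of random points is dropped on
the photograph, the benthic class beneath each point is recorded, and
hits are converted to percent (50 points -> each hit worth 2%).  Coral
growth forms (branching, digitate, encrusting, foliose, massive,
submassive, mushroom, tabulate) are counted from the mask labels as a
proxy for coral diversity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .imaging import (
    ColorThumbprint,
    GroupShares,
    QuadratImage,
    count_colours,
    simpson_diversity,
)

__all__ = [
    "BENTHIC_CLASSES",
    "MORPHOLOGIES",
    "BenthicMask",
    "FeatureVector",
    "point_count_cover",
    "morphology_richness",
    "assemble_features",
]

BENTHIC_CLASSES = (
    "hard_coral",
    "soft_coral",
    "sponge",
    "CCA",
    "gorgonian",
    "dead_coral",
    "rubble",
    "sand",
    "rock",
    "frame",
)

MORPHOLOGIES = (
    "branching",
    "digitate",
    "encrusting",
    "foliose",
    "massive",
    "submassive",
    "mushroom",
    "tabulate",
)


@dataclass
class BenthicMask:
    """Per-pixel benthic labels with a legend.

    ``legend`` maps each integer label to ``(class, morphology)`` where
    morphology is ``None`` for non-coral classes.
    """

    image_id: str
    labels: np.ndarray  # H x W integer grid
    legend: dict[int, tuple[str, str | None]]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        self.labels = lab.astype(np.int32)
        for code, (cls, morph) in self.legend.items():
            if cls not in BENTHIC_CLASSES:
                raise ValueError(f"legend code {code}: unknown class {cls!r}")
            if morph is not None and morph not in MORPHOLOGIES:
                raise ValueError(f"legend code {code}: unknown morphology {morph!r}")
            if (morph is not None) != (cls == "hard_coral"):
                raise ValueError(
                    f"legend code {code}: morphology labels belong to hard_coral only"
                )
        present = np.unique(self.labels)
        unknown = sorted(set(present.tolist()) - set(self.legend))
        if unknown:
            raise ValueError(f"labels not in legend: {unknown}")

    # -- exact (whole-grid) accounting, used as the ground-truth oracle --

    def exact_class_fractions(self) -> dict[str, float]:
        """Exact per-class pixel fractions in percent (sum to 100)."""
        counts = np.bincount(self.labels.ravel(), minlength=max(self.legend) + 1)
        total = self.labels.size
        out = dict.fromkeys(BENTHIC_CLASSES, 0.0)
        for code, (cls, _) in self.legend.items():
            out[cls] += 100.0 * counts[code] / total if code < len(counts) else 0.0
        return out

    def morphologies_present(self) -> set[str]:
        present = np.unique(self.labels)
        return {
            self.legend[int(c)][1]
            for c in present
            if self.legend[int(c)][1] is not None
        }

    # -- PNG + JSON legend round-trip --

    def save(self, png_path: str | Path, legend_path: str | Path) -> None:
        Image.fromarray(self.labels.astype(np.uint8)).save(png_path, format="PNG")
        legend = {
            str(code): {"class": cls, "morphology": morph}
            for code, (cls, morph) in self.legend.items()
        }
        Path(legend_path).write_text(json.dumps({"image_id": self.image_id, "legend": legend}, indent=1))

    @classmethod
    def load(cls, png_path: str | Path, legend_path: str | Path) -> "BenthicMask":
        with Image.open(png_path) as im:
            labels = np.asarray(im, dtype=np.int32)
        meta = json.loads(Path(legend_path).read_text())
        legend = {
            int(code): (entry["class"], entry["morphology"])
            for code, entry in meta["legend"].items()
        }
        return cls(image_id=meta["image_id"], labels=labels, legend=legend)


@dataclass
class FeatureVector:
    """The nine per-photograph features feeding the rating regression."""

    image_id: str
    simpson: float
    pct_black: float
    pct_blue: float
    pct_green: float
    pct_yellow: float
    pct_grey: float
    n_colours: int
    n_morphologies: int
    pct_live_coral: float

    FEATURE_NAMES = (
        "simpson",
        "pct_black",
        "pct_blue",
        "pct_green",
        "pct_yellow",
        "pct_grey",
        "n_colours",
        "n_morphologies",
        "pct_live_coral",
    )

    def __post_init__(self) -> None:
        for name in ("pct_black", "pct_blue", "pct_green", "pct_yellow", "pct_grey", "pct_live_coral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0 + 1e-9:
                raise ValueError(f"{name} outside [0, 100]: {v}")
        if self.n_colours < 0 or self.n_morphologies < 0:
            raise ValueError("counts must be non-negative")
        if self.n_morphologies > len(MORPHOLOGIES):
            raise ValueError(f"n_morphologies cannot exceed {len(MORPHOLOGIES)}")

    def as_dict(self) -> dict[str, float | int | str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def point_count_cover(
    mask: BenthicMask, n_points: int = 50, seed: int | np.random.Generator = 0
) -> dict[str, float]:
    """Percent cover per benthic class from random point sampling.

    Points are placed uniformly at pixel centres without replacement;
    percent = hits / n_points * 100 (with the default 50 points each
    hit is worth 2%).  Every legend class gets an entry, zeros
    included, and entries sum to 100.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    n_pixels = mask.labels.size
    if n_points > n_pixels:
        raise ValueError(f"n_points={n_points} exceeds pixel count {n_pixels}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat_idx = rng.choice(n_pixels, size=n_points, replace=False)
    hits = mask.labels.ravel()[flat_idx]
    counts = np.bincount(hits, minlength=max(mask.legend) + 1)
    out = dict.fromkeys(BENTHIC_CLASSES, 0.0)
    for code, (cls, _) in mask.legend.items():
        out[cls] += 100.0 * counts[code] / n_points
    return out


def morphology_richness(mask: BenthicMask) -> int:
    """Number of distinct coral growth forms with at least one pixel."""
    return len(mask.morphologies_present())


def assemble_features(
    img: QuadratImage,
    tp: ColorThumbprint,
    groups: GroupShares,
    mask: BenthicMask,
    n_points: int = 50,
    seed: int | np.random.Generator = 0,
) -> FeatureVector:
    """Combine colour and shape measurements into the nine-feature vector.

    ``pct_live_coral`` comes from point-intercept sampling of the mask
    (the hard_coral entry); ``pct_black`` doubles as the shadow /
    structural-complexity proxy.  All inputs must describe the same
    photograph.
    """
    if img.image_id != mask.image_id:
        raise ValueError(
            f"image/mask id mismatch: {img.image_id!r} vs {mask.image_id!r}"
        )
    cover = point_count_cover(mask, n_points=n_points, seed=seed)
    return FeatureVector(
        image_id=img.image_id,
        simpson=simpson_diversity(tp.proportions),
        pct_black=groups.black,
        pct_blue=groups.blue,
        pct_green=groups.green,
        pct_yellow=groups.yellow,
        pct_grey=groups.grey,
        n_colours=count_colours(tp),
        n_morphologies=morphology_richness(mask),
        pct_live_coral=cover["hard_coral"],
    )


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame([f.as_dict() for f in features])


def frame_to_features(df: pd.DataFrame) -> list[FeatureVector]:
    cols = ("image_id",) + FeatureVector.FEATURE_NAMES
    return [
        FeatureVector(**{c: (int(row[c]) if c in ("n_colours", "n_morphologies") else row[c]) for c in cols})
        for _, row in df.iterrows()
    ]
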