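"""Photograph standardization and colour-based features.

A benthic quadrat photograph is reduced to a *colour thumbprint*: the
proportion of its pixels falling into each box of a regular 4x4x4
partition of RGB colourspace (64 bins).  Bins are merged into named
colour groups (black, blue, green, yellow, grey, other); black acts as
a shadow / structural-complexity proxy and grey tracks rubble and sand.
Colour diversity is summarised by the Gini-Simpson index and by the
count of bins holding more than 1% of pixels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "QuadratImage",
    "ColorThumbprint",
    "GroupShares",
    "COLOUR_GROUPS",
    "N_BINS",
    "BIN_DIVISIONS",
    "standardize_image",
    "colour_thumbprint",
    "default_bin_group_mapping",
    "load_bin_group_mapping",
    "save_bin_group_mapping",
    "group_shares",
    "simpson_diversity",
    "count_colours",
]

#: number of equal divisions per RGB channel; 4**3 = 64 colour bins
BIN_DIVISIONS = 4
N_BINS = BIN_DIVISIONS**3
#: width of one channel division in 8-bit units
_DIV_WIDTH = 256 // BIN_DIVISIONS

COLOUR_GROUPS = ("black", "blue", "green", "yellow", "grey", "other")

HABITATS = ("healthy", "restored", "degraded")


@dataclass
class QuadratImage:
    """A standardized quadrat photograph with survey metadata."""

    image_id: str
    pixels: np.ndarray  # H x W x 3 uint8
    site_id: str = ""
    habitat: str = ""
    depth_m: float = float("nan")
    qc_pass: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in 0..255")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.habitat and self.habitat not in HABITATS:
            raise ValueError(f"habitat must be one of {HABITATS}, got {self.habitat!r}")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ColorThumbprint:
    """64-bin RGB histogram expressed as pixel proportions."""

    proportions: np.ndarray
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(0, 257, _DIV_WIDTH)
    )

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (N_BINS,):
            raise ValueError(f"thumbprint must have exactly {N_BINS} entries")
        if (p < 0).any():
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        self.proportions = p


@dataclass
class GroupShares:
    """Percent of pixels in each named colour group; sums to 100."""

    black: float
    blue: float
    green: float
    yellow: float
    grey: float
    other: float

    def __post_init__(self) -> None:
        total = sum(self.as_dict().values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"group shares must sum to 100, got {total}")
        for name, v in self.as_dict().items():
            if not 0.0 <= v <= 100.0 + 1e-9:
                raise ValueError(f"share {name} outside [0, 100]: {v}")

    def as_dict(self) -> dict[str, float]:
        return {g: getattr(self, g) for g in COLOUR_GROUPS}


def standardize_image(raw: np.ndarray, target_side: int = 700) -> np.ndarray:
    """Centre-crop to a square and resample to ``target_side`` pixels.

    Already-conforming images are returned unchanged (copy), so
    standardization is idempotent.  Resampling uses bilinear
    interpolation and is deterministic.
    """
    raw = np.asarray(raw)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    h, w = raw.shape[:2]
    if h == w == target_side:
        return raw.astype(np.uint8, copy=True)
    side = min(h, w)
    top = (h - side) // 2
    left = (w - side) // 2
    cropped = raw[top : top + side, left : left + side]
    im = Image.fromarray(cropped.astype(np.uint8))
    im = im.resize((target_side, target_side), resample=Image.BILINEAR)
    return np.asarray(im, dtype=np.uint8)


def bin_index(pixels: np.ndarray) -> np.ndarray:
    """Map uint8 RGB pixels to red-major bin indices in 0..63.

    Divisions are half-open: [0,64), [64,128), [128,192), [192,256).
    """
    px = np.asarray(pixels)
    r = px[..., 0] // _DIV_WIDTH
    g = px[..., 1] // _DIV_WIDTH
    b = px[..., 2] // _DIV_WIDTH
    return (
        r.astype(np.int64) * BIN_DIVISIONS**2
        + g.astype(np.int64) * BIN_DIVISIONS
        + b.astype(np.int64)
    )


def colour_thumbprint(img: QuadratImage | np.ndarray) -> ColorThumbprint:
    """Proportion of pixels in each of the 64 RGB colourspace boxes."""
    px = img.pixels if isinstance(img, QuadratImage) else np.asarray(img)
    if px.size == 0:
        raise ValueError("cannot compute a thumbprint of an empty image")
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    idx = bin_index(px).ravel()
    counts = np.bincount(idx, minlength=N_BINS).astype(float)
    return ColorThumbprint(proportions=counts / counts.sum())


def _bin_divs(i: int) -> tuple[int, int, int]:
    return (
        i // BIN_DIVISIONS**2,
        (i // BIN_DIVISIONS) % BIN_DIVISIONS,
        i % BIN_DIVISIONS,
    )


def default_bin_group_mapping() -> dict[int, str]:
    """Rule-based assignment of the 64 bins to colour groups.

    black  - the all-lowest division (darkest box; shadow);
    grey   - equal divisions on all channels above the lowest
             (achromatic; rubble and sand);
    blue   - blue division strictly dominant;
    green  - green division strictly dominant;
    yellow - red and green within one division of each other, both
             bright (>= division 2) and above blue;
    other  - everything else (browns, reds, purples, dark mixes).

    The mapping is configurable: a published bin-to-group table can be
    dropped in via :func:`load_bin_group_mapping`.
    """
    mapping: dict[int, str] = {}
    for i in range(N_BINS):
        r, g, b = _bin_divs(i)
        if r == g == b == 0:
            mapping[i] = "black"
        elif r == g == b:
            mapping[i] = "grey"
        elif b > max(r, g):
            mapping[i] = "blue"
        elif g > max(r, b):
            mapping[i] = "green"
        elif abs(r - g) <= 1 and min(r, g) >= 2 and b < min(r, g):
            mapping[i] = "yellow"
        else:
            mapping[i] = "other"
    return mapping


def save_bin_group_mapping(mapping: dict[int, str], path: str | Path) -> None:
    rows = [
        {"bin_index": i, "r_div": d[0], "g_div": d[1], "b_div": d[2], "group": mapping[i]}
        for i in sorted(mapping)
        for d in [_bin_divs(i)]
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_bin_group_mapping(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path)
    return {int(row.bin_index): str(row.group) for row in df.itertuples()}


def _validate_mapping(mapping: dict[int, str]) -> None:
    seen: dict[int, str] = {}
    bad_group = [i for i, g in mapping.items() if g not in COLOUR_GROUPS]
    if bad_group:
        raise ValueError(f"bins assigned to unknown groups: {sorted(bad_group)}")
    for i, g in mapping.items():
        if i in seen:
            raise ValueError(f"bin {i} assigned more than once")
        seen[i] = g
    missing = sorted(set(range(N_BINS)) - set(mapping))
    if missing:
        raise ValueError(f"mapping missing bins: {missing}")
    extra = sorted(set(mapping) - set(range(N_BINS)))
    if extra:
        raise ValueError(f"mapping contains out-of-range bins: {extra}")


def group_shares(
    tp: ColorThumbprint, mapping: dict[int, str] | None = None
) -> GroupShares:
    """Merge thumbprint bins into colour-group percentages."""
    if mapping is None:
        mapping = default_bin_group_mapping()
    _validate_mapping(mapping)
    totals = dict.fromkeys(COLOUR_GROUPS, 0.0)
    for i, p in enumerate(tp.proportions):
        totals[mapping[i]] += 100.0 * p
    # guard against float drift so GroupShares' own invariant holds;
    # assign it to the largest share, which cannot go negative from it
    drift = 100.0 - sum(totals.values())
    totals[max(totals, key=totals.get)] += drift
    return GroupShares(**totals)


def simpson_diversity(proportions: np.ndarray, tol: float = 1e-6) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2) of a proportion vector.

    0 for a monochrome distribution, approaching 1 - 1/k for the
    uniform distribution over k bins.
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"proportions must sum to 1 (got {p.sum()})")
    return float(1.0 - np.sum(p**2))


def count_colours(tp: ColorThumbprint, threshold: float = 0.01) -> int:
    """Number of bins holding strictly more than ``threshold`` of pixels."""
    return int(np.sum(tp.proportions > threshold))


def write_image_png(pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path, format="PNG")


def read_image(path: str | Path | io.BytesIO) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)
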