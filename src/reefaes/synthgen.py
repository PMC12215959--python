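"""Synthetic quadrat photographs and simulated survey respondents.

Renders desk-scale stand-ins for benthic quadrat photographs: coral
colonies drawn as parametric shapes per growth form over a sand /
rubble substrate, with shadow painted next to colonies as a
structural-complexity proxy, and a pixel-exact label mask as ground
truth.  Habitat presets carry the field means and SDs of coral and
rubble cover for healthy, restored and degraded reefs, so a batch of
generated quadrats reproduces the cover statistics of each habitat.

Survey respondents are simulated with socio-cultural attributes and
make forced pairwise choices between photographs via the Elo-scale
logistic rule, so that downstream rating recovery is self-consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import truncnorm
from scipy.ndimage import binary_dilation
from skimage import draw as skdraw
from skimage.morphology import disk

from .annotation import MORPHOLOGIES, BenthicMask
from .imaging import QuadratImage, colour_thumbprint, group_shares

logger = logging.getLogger(__name__)

__all__ = [
    "HabitatPreset",
    "GroundTruth",
    "RespondentAttrs",
    "PreferenceRecord",
    "HABITAT_PRESETS",
    "LATENT_FEATURE_NAMES",
    "DEFAULT_LATENT_WEIGHTS",
    "generate_quadrat",
    "latent_score",
    "sample_respondents",
    "simulate_choices",
    "exclude_colour_deficient",
    "win_probability",
]

# ---------------------------------------------------------------------------
# label codes shared by the generator and the mask legend

SAND, RUBBLE, ROCK, DEAD_CORAL, FRAME = 0, 1, 2, 3, 4
CORAL_BASE = 10  # hard_coral with morphology m -> code CORAL_BASE + m

_BASE_LEGEND: dict[int, tuple[str, str | None]] = {
    SAND: ("sand", None),
    RUBBLE: ("rubble", None),
    ROCK: ("rock", None),
    DEAD_CORAL: ("dead_coral", None),
    FRAME: ("frame", None),
}
_BASE_LEGEND.update(
    {CORAL_BASE + m: ("hard_coral", name) for m, name in enumerate(MORPHOLOGIES)}
)

# substrate base colours (achromatic so they land in the grey group)
_CLASS_COLOUR = {
    SAND: (168.0, 168.0, 168.0),
    RUBBLE: (100.0, 100.0, 100.0),
    ROCK: (135.0, 100.0, 70.0),  # turf-algae brown, not an achromatic grey
    DEAD_CORAL: (140.0, 140.0, 140.0),
    FRAME: (82.0, 82.0, 82.0),
}
_SHADOW_COLOUR = 14.0

# coral colour archetypes (RGB); names are for preset bookkeeping only
CORAL_PALETTE: dict[str, tuple[int, int, int]] = {
    "blue": (70, 110, 210),
    "pale_blue": (95, 140, 225),
    "green": (60, 165, 95),
    "bright_green": (110, 185, 80),
    "yellow": (215, 195, 75),
    "pale_yellow": (225, 205, 100),
    "brown": (150, 105, 60),
    "dark_brown": (125, 95, 70),
    "pink": (200, 120, 160),
}

_VIVID = ("blue", "pale_blue", "green", "bright_green", "yellow", "pale_yellow", "brown", "pink")
_DRAB = ("brown", "dark_brown", "green")


@dataclass(frozen=True)
class HabitatPreset:
    """Generation parameters for one habitat condition.

    Cover means and SDs are in percent and describe the *realized*
    per-quadrat covers: sampling uses a [0, 100]-truncated normal whose
    location is adjusted so the post-truncation mean equals
    ``coral_cover_mean`` (resp. ``rubble_cover_mean``).
    """

    name: str
    coral_cover_mean: float
    coral_cover_sd: float
    rubble_cover_mean: float
    rubble_cover_sd: float
    morphology_pool: tuple[str, ...] = MORPHOLOGIES
    palette: tuple[str, ...] = _VIVID
    shadow_scale: float = 0.25
    frame_present: bool = False

    def __post_init__(self) -> None:
        if self.name not in ("healthy", "restored", "degraded"):
            raise ValueError(f"name must be healthy/restored/degraded, got {self.name!r}")
        for f_ in ("coral_cover_mean", "rubble_cover_mean"):
            v = getattr(self, f_)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{f_} must lie in [0, 100], got {v}")
        for f_ in ("coral_cover_sd", "rubble_cover_sd"):
            if getattr(self, f_) < 0:
                raise ValueError(f"{f_} must be >= 0")
        if self.shadow_scale < 0:
            raise ValueError("shadow_scale must be >= 0")
        bad = set(self.morphology_pool) - set(MORPHOLOGIES)
        if bad:
            raise ValueError(f"morphology_pool contains unknown forms: {sorted(bad)}")
        if not self.morphology_pool:
            raise ValueError("morphology_pool must not be empty")
        bad = set(self.palette) - set(CORAL_PALETTE)
        if bad:
            raise ValueError(f"palette contains unknown colour archetypes: {sorted(bad)}")
        if not self.palette:
            raise ValueError("palette must not be empty")

    def shifted(self, coral_shift: float = 0.0, rubble_shift: float = 0.0) -> "HabitatPreset":
        """Copy with cover means offset (clipped to [0, 100]); used for site effects."""
        return replace(
            self,
            coral_cover_mean=float(np.clip(self.coral_cover_mean + coral_shift, 0, 100)),
            rubble_cover_mean=float(np.clip(self.rubble_cover_mean + rubble_shift, 0, 100)),
        )

    def site_realization(
        self, rng: np.random.Generator, coral_site_sd: float, rubble_site_sd: float
    ) -> "HabitatPreset":
        """Draw one site's preset: the habitat's total cover SD is split
        into a between-site shift (drawn here) and the residual
        within-site SD, so a batch over many sites keeps the habitat
        mean and total spread."""
        resid_c = float(np.sqrt(max(self.coral_cover_sd**2 - coral_site_sd**2, 1.0)))
        resid_r = float(np.sqrt(max(self.rubble_cover_sd**2 - rubble_site_sd**2, 1.0)))
        shifted = self.shifted(
            coral_shift=float(rng.normal(0.0, min(coral_site_sd, self.coral_cover_sd))),
            rubble_shift=float(rng.normal(0.0, min(rubble_site_sd, self.rubble_cover_sd))),
        )
        return replace(shifted, coral_cover_sd=resid_c, rubble_cover_sd=resid_r)


#: field cover statistics per habitat (percent, mean and SD)
HABITAT_PRESETS: dict[str, HabitatPreset] = {
    "healthy": HabitatPreset(
        name="healthy",
        coral_cover_mean=70.46, coral_cover_sd=23.02,
        rubble_cover_mean=5.89, rubble_cover_sd=14.70,
        morphology_pool=MORPHOLOGIES, palette=_VIVID,
        shadow_scale=0.28, frame_present=False,
    ),
    "restored": HabitatPreset(
        name="restored",
        coral_cover_mean=61.32, coral_cover_sd=22.01,
        rubble_cover_mean=10.36, rubble_cover_sd=15.92,
        morphology_pool=MORPHOLOGIES, palette=_VIVID,
        shadow_scale=0.25, frame_present=True,
    ),
    "degraded": HabitatPreset(
        name="degraded",
        coral_cover_mean=11.71, coral_cover_sd=21.27,
        rubble_cover_mean=74.91, rubble_cover_sd=29.64,
        morphology_pool=("branching", "encrusting", "massive", "submassive"),
        palette=_DRAB,
        shadow_scale=0.12, frame_present=False,
    ),
}


@dataclass
class GroundTruth:
    """Pixel-exact truth for one generated quadrat."""

    image_id: str
    true_cover: dict[str, float]  # percent per benthic class, sums to 100
    true_morphologies: set[str]
    true_colour_shares: dict[str, float]  # percent per colour group
    colour_simpson: float = 0.0  # Gini-Simpson of the image's 64 colour bins
    latent_aesthetic: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.true_cover.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"true_cover must sum to 100, got {total}")
        if any(v < 0 for v in self.true_cover.values()):
            raise ValueError("true_cover entries must be >= 0")
        if not np.isfinite(self.latent_aesthetic):
            raise ValueError("latent_aesthetic must be finite")


# ---------------------------------------------------------------------------
# cover sampling


@lru_cache(maxsize=128)
def _adjusted_loc(target_mean: float, sd: float) -> float:
    """Location of a [0,100]-truncated normal whose mean equals target_mean."""
    if sd == 0.0:
        return target_mean
    # deep in a tail the truncated mean decays like sd^2 / |mu - bound|,
    # so edge targets get the asymptotic location directly (the bracket
    # search below would have to expand over thousands of SDs)
    edge = 0.2 * sd
    if target_mean <= edge:
        return -sd * sd / max(target_mean, 0.01)
    if target_mean >= 100.0 - edge:
        return 100.0 + sd * sd / max(100.0 - target_mean, 0.01)

    def trunc_mean(mu: float) -> float:
        a, b = (0.0 - mu) / sd, (100.0 - mu) / sd
        return float(truncnorm.mean(a, b, loc=mu, scale=sd))

    lo, hi = target_mean - 3.0 * sd, target_mean + 3.0 * sd
    while trunc_mean(lo) > target_mean and lo > target_mean - 60.0 * sd:
        lo -= 3.0 * sd
    while trunc_mean(hi) < target_mean and hi < target_mean + 60.0 * sd:
        hi += 3.0 * sd
    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean, lo, hi, xtol=1e-6))


def _sample_trunc(target_mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0.0:
        return float(target_mean)
    mu = _adjusted_loc(round(target_mean, 6), round(sd, 6))
    a, b = (0.0 - mu) / sd, (100.0 - mu) / sd
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def sample_covers(preset: HabitatPreset, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (coral%, rubble%) for one quadrat.

    If the draws exceed 100% combined, the habitat's dominant substrate
    (the class with the larger preset mean) keeps its draw and the
    minor class is capped at the remainder; this keeps batch means on
    the preset means, which a joint rescale would bias downward.
    """
    coral = _sample_trunc(preset.coral_cover_mean, preset.coral_cover_sd, rng)
    rubble = _sample_trunc(preset.rubble_cover_mean, preset.rubble_cover_sd, rng)
    if coral + rubble > 100.0:
        if preset.coral_cover_mean >= preset.rubble_cover_mean:
            rubble = 100.0 - coral
        else:
            coral = 100.0 - rubble
    return coral, rubble


# ---------------------------------------------------------------------------
# colony rendering


def _paint(canvas_labels, canvas_colour, rr, cc, code, colour):
    side = canvas_labels.shape[0]
    ok = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
    canvas_labels[rr[ok], cc[ok]] = code
    canvas_colour[rr[ok], cc[ok]] = colour


def _draw_colony(
    labels: np.ndarray,
    colour: np.ndarray,
    morph: str,
    centre: tuple[int, int],
    rad: int,
    code: int,
    rgb: np.ndarray,
    rng: np.random.Generator,
) -> None:
    r0, c0 = centre
    if morph in ("massive", "submassive"):
        n_lobes = 1 if morph == "massive" else rng.integers(2, 4)
        for _ in range(n_lobes):
            dr, dc = rng.integers(-rad // 2, rad // 2 + 1, size=2)
            ry = max(2, int(rad * rng.uniform(0.6, 1.0)))
            rx = max(2, int(rad * rng.uniform(0.6, 1.0)))
            rr, cc = skdraw.ellipse(r0 + dr, c0 + dc, ry, rx, shape=labels.shape)
            _paint(labels, colour, rr, cc, code, rgb)
    elif morph in ("tabulate", "mushroom"):
        rad_eff = rad if morph == "tabulate" else max(2, int(rad * 0.6))
        rr, cc = skdraw.disk((r0, c0), rad_eff, shape=labels.shape)
        _paint(labels, colour, rr, cc, code, rgb)
    elif morph == "encrusting":
        ry = max(2, int(rad * rng.uniform(0.3, 0.5)))
        rx = max(3, int(rad * rng.uniform(0.9, 1.4)))
        rot = rng.uniform(0, np.pi)
        rr, cc = skdraw.ellipse(r0, c0, ry, rx, shape=labels.shape, rotation=rot)
        _paint(labels, colour, rr, cc, code, rgb)
    elif morph == "foliose":
        rr, cc = skdraw.disk((r0, c0), rad, shape=labels.shape)
        keep = ((rr - r0) ** 2 + (cc - c0) ** 2) >= (rad * 0.45) ** 2
        _paint(labels, colour, rr[keep], cc[keep], code, rgb)
    elif morph in ("branching", "digitate"):
        n_arms = rng.integers(5, 10) if morph == "branching" else rng.integers(4, 7)
        arm_len = rad * (2 if morph == "branching" else 1)
        for _ in range(n_arms):
            ang = rng.uniform(0, 2 * np.pi)
            r1 = int(r0 + arm_len * np.sin(ang))
            c1 = int(c0 + arm_len * np.cos(ang))
            for off in (-1, 0, 1):  # stroke thickness ~3 px
                rr, cc = skdraw.line(r0 + off, c0, r1 + off, c1)
                _paint(labels, colour, rr, cc, code, rgb)
    else:  # pragma: no cover - pool validation precludes this
        raise ValueError(f"unknown morphology {morph!r}")


def _trim_to_target(
    labels: np.ndarray, mask_of: np.ndarray, target_px: int, revert_code: int,
    colour: np.ndarray, revert_colour: tuple[float, float, float],
    rng: np.random.Generator,
) -> None:
    """Revert a random subset of painted pixels so the count hits target_px."""
    flat = np.flatnonzero(mask_of.ravel())
    excess = flat.size - target_px
    if excess > 0:
        drop = rng.choice(flat, size=excess, replace=False)
        labels.ravel()[drop] = revert_code
        colour.reshape(-1, 3)[drop] = revert_colour


def _hex_frame(labels, colour, side, rng):
    """Hexagonal restoration-frame bars (painted over substrate only)."""
    r0, c0 = side // 2 + rng.integers(-side // 8, side // 8 + 1), side // 2 + rng.integers(-side // 8, side // 8 + 1)
    rad = int(side * 0.38)
    angles = np.linspace(0, 2 * np.pi, 7) + rng.uniform(0, np.pi / 3)
    pts = [(int(r0 + rad * np.sin(a)), int(c0 + rad * np.cos(a))) for a in angles]
    substrate = labels < CORAL_BASE
    for (ra, ca), (rb, cb) in zip(pts[:-1], pts[1:]):
        for off in (-1, 0, 1):
            rr, cc = skdraw.line(ra + off, ca, rb + off, cb)
            ok = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
            rr, cc = rr[ok], cc[ok]
            keep = substrate[rr, cc]
            labels[rr[keep], cc[keep]] = FRAME
            colour[rr[keep], cc[keep]] = _CLASS_COLOUR[FRAME]


def generate_quadrat(
    preset: HabitatPreset,
    seed: int,
    side: int = 256,
    image_id: str | None = None,
    site_id: str = "",
    depth_m: float = 3.0,
    qc_pass: bool = True,
    latent_weights: Sequence[float] | None = None,
    latent_noise_sd: float = 60.0,
) -> tuple[QuadratImage, BenthicMask, GroundTruth]:
    """Render one synthetic quadrat with a pixel-exact mask and ground truth.

    The seed fixes every random element (covers, colony count and
    placement, colours, shapes, shadow), so identical calls are
    bit-identical.  Ground-truth covers are the exact pixel fractions
    of the returned mask.
    """
    rng = np.random.default_rng(seed)
    if image_id is None:
        image_id = f"{preset.name}-{seed}"
    n_px = side * side

    coral_pct, rubble_pct = sample_covers(preset, rng)
    coral_target = int(round(coral_pct / 100.0 * n_px))
    rubble_target = int(round(rubble_pct / 100.0 * n_px))

    labels = np.full((side, side), SAND, dtype=np.int32)
    colour = np.empty((side, side, 3), dtype=np.float64)
    # per-quadrat substrate tints: carbonate sand runs from neutral grey to
    # warm cream, rubble from bare grey to brown turf cover -- so the grey
    # colour-group share is only loosely coupled to the benthic covers
    sand_warmth = rng.uniform(0.0, 1.0)
    sand_rgb = (1 - sand_warmth) * np.array([168.0, 168.0, 168.0]) + sand_warmth * np.array([200.0, 180.0, 120.0])
    turf = rng.uniform(0.0, 1.0)
    rubble_rgb = (1 - turf) * np.array([100.0, 100.0, 100.0]) + turf * np.array([130.0, 105.0, 75.0])
    pale_coral_p = rng.uniform(0.0, 0.35)  # bleached / pale colonies
    colour[:] = sand_rgb

    # -- coral colonies ----------------------------------------------------
    realized_morphs: set[str] = set()
    if coral_target > 0:
        # morphology richness loosely follows cover, with enough quadrat-to-
        # quadrat scatter that shape and cover stay only weakly correlated
        pool = list(preset.morphology_pool)
        p_morph = 0.45 + 0.25 * min(1.0, coral_pct / 70.0)
        k = 1 + int(rng.binomial(len(pool) - 1, p_morph))
        active = list(rng.choice(pool, size=k, replace=False))
        # each quadrat hosts its own subset of the habitat palette (a stand
        # of one colour morph is as common as a mixed garden), so colour
        # diversity varies largely independently of coral cover
        k_pal = 1 + int(rng.integers(0, len(preset.palette)))
        active_palette = list(rng.choice(preset.palette, size=k_pal, replace=False))
        guard = 0
        while int((labels >= CORAL_BASE).sum()) < coral_target and guard < 4000:
            guard += 1
            morph = active[int(rng.integers(len(active)))]
            if rng.random() < pale_coral_p:
                rgb = np.array([172.0, 172.0, 172.0])  # pale / bleached colony
            else:
                archetype = active_palette[int(rng.integers(len(active_palette)))]
                rgb = np.array(CORAL_PALETTE[archetype], dtype=float)
            rgb = rgb + rng.uniform(-12, 12, size=3)
            centre = tuple(int(v) for v in rng.integers(0, side, size=2))
            rad = max(3, int(side * rng.uniform(0.03, 0.10)))
            _draw_colony(labels, colour, morph, centre, rad,
                         CORAL_BASE + MORPHOLOGIES.index(morph), rgb, rng)
        coral_mask = labels >= CORAL_BASE
        _trim_to_target(labels, coral_mask, coral_target, SAND, colour,
                        sand_rgb, rng)
        realized_morphs = {
            MORPHOLOGIES[c - CORAL_BASE] for c in np.unique(labels) if c >= CORAL_BASE
        }

    # -- restoration frame -------------------------------------------------
    if preset.frame_present:
        _hex_frame(labels, colour, side, rng)

    # -- rubble on remaining sand ------------------------------------------
    if rubble_target > 0:
        sand_available = int((labels == SAND).sum())
        target = min(rubble_target, sand_available)
        guard = 0
        while int((labels == RUBBLE).sum()) < target and guard < 6000:
            guard += 1
            r0, c0 = (int(v) for v in rng.integers(0, side, size=2))
            rad = max(2, int(side * rng.uniform(0.02, 0.07)))
            rr, cc = skdraw.ellipse(
                r0, c0,
                max(2, int(rad * rng.uniform(0.5, 1.0))),
                max(2, int(rad * rng.uniform(0.5, 1.0))),
                shape=labels.shape,
                rotation=rng.uniform(0, np.pi),
            )
            keep = labels[rr, cc] == SAND
            shade = rng.uniform(-12, 12)
            labels[rr[keep], cc[keep]] = RUBBLE
            colour[rr[keep], cc[keep]] = rubble_rgb + shade
        shortfall = target - int((labels == RUBBLE).sum())
        if shortfall > 0:
            # loose-rubble speckle: finish off with scattered sand->rubble pixels
            sand_idx = np.flatnonzero((labels == SAND).ravel())
            pick = rng.choice(sand_idx, size=min(shortfall, sand_idx.size), replace=False)
            labels.ravel()[pick] = RUBBLE
            colour.reshape(-1, 3)[pick] = rubble_rgb
        rubble_mask = labels == RUBBLE
        _trim_to_target(labels, rubble_mask, target, SAND, colour,
                        sand_rgb, rng)

    # -- turf-covered rock: a per-quadrat slice of the leftover substrate --
    sand_idx = np.flatnonzero((labels == SAND).ravel())
    rock_target = int(round(rng.uniform(0.0, 0.5) * sand_idx.size))
    if rock_target > 0:
        placed = 0
        guard = 0
        while placed < rock_target and guard < 2000:
            guard += 1
            r0, c0 = (int(v) for v in rng.integers(0, side, size=2))
            rad = max(2, int(side * rng.uniform(0.03, 0.09)))
            rr, cc = skdraw.ellipse(
                r0, c0, max(2, int(rad * rng.uniform(0.5, 1.0))),
                max(2, int(rad * rng.uniform(0.5, 1.0))),
                shape=labels.shape, rotation=rng.uniform(0, np.pi),
            )
            keep = labels[rr, cc] == SAND
            shade = rng.uniform(-10, 10)
            labels[rr[keep], cc[keep]] = ROCK
            colour[rr[keep], cc[keep]] = tuple(v + shade for v in _CLASS_COLOUR[ROCK])
            placed = int((labels == ROCK).sum())

    # -- compose image: luminance noise (correlated across channels) plus
    #    small chroma noise; substrate stays achromatic ---------------------
    lum_sd = np.where(labels == RUBBLE, 9.0, 5.0)[..., None]
    img = colour + rng.normal(0.0, 1.0, size=(side, side, 1)) * lum_sd
    img = img + rng.normal(0.0, 2.0, size=colour.shape)

    # -- shadow adjacent to colonies (image only; mask keeps substrate) ----
    coral_mask = labels >= CORAL_BASE
    coral_frac = coral_mask.mean()
    if preset.shadow_scale > 0 and coral_frac > 0:
        frac = min(0.18, preset.shadow_scale * coral_frac * rng.uniform(0.4, 1.6))
        candidates = binary_dilation(coral_mask, structure=disk(3)) & ~coral_mask
        cand_idx = np.flatnonzero(candidates.ravel())
        n_shadow = min(cand_idx.size, int(round(frac * n_px)))
        if n_shadow > 0:
            pick = rng.choice(cand_idx, size=n_shadow, replace=False)
            img.reshape(-1, 3)[pick] = _SHADOW_COLOUR
            img.reshape(-1, 3)[pick] += rng.normal(0.0, 2.0, size=(n_shadow, 3))

    pixels = np.clip(img, 0, 255).astype(np.uint8)

    habitat = preset.name
    quadrat = QuadratImage(
        image_id=image_id, pixels=pixels, site_id=site_id,
        habitat=habitat, depth_m=depth_m, qc_pass=qc_pass,
    )
    mask = BenthicMask(image_id=image_id, labels=labels, legend=dict(_BASE_LEGEND))

    tp = colour_thumbprint(pixels)
    truth = GroundTruth(
        image_id=image_id,
        true_cover=mask.exact_class_fractions(),
        true_morphologies=realized_morphs,
        true_colour_shares=group_shares(tp).as_dict(),
        colour_simpson=float(1.0 - np.sum(tp.proportions**2)),
        latent_aesthetic=0.0,
    )
    truth.latent_aesthetic = latent_score(
        truth, weights=latent_weights, noise_sd=latent_noise_sd,
        seed=rng,
    )
    return quadrat, mask, truth


# ---------------------------------------------------------------------------
# latent aesthetic scores and choice simulation

#: ground-truth features entering the latent aesthetic score, in order
LATENT_FEATURE_NAMES = (
    "colour_simpson",    # Gini-Simpson diversity of the photo's 64 colour bins
    "pct_live_coral",    # percent hard coral cover
    "n_morphologies",    # coral growth forms present
    "pct_rubble",        # percent rubble cover
)

#: Elo-scale weights: colour diversity and live coral cover dominate,
#: morphological variety contributes, rubble carries no extra penalty
#: beyond the cover and colour it displaces
DEFAULT_LATENT_WEIGHTS = (2600.0, 6.0, 40.0, 0.0)


def latent_features(truth: GroundTruth) -> np.ndarray:
    return np.array([
        truth.colour_simpson,
        truth.true_cover.get("hard_coral", 0.0),
        float(len(truth.true_morphologies)),
        truth.true_cover.get("rubble", 0.0),
    ])


def latent_score(
    truth: GroundTruth,
    weights: Sequence[float] | None = None,
    noise_sd: float = 60.0,
    seed: int | np.random.Generator = 0,
) -> float:
    """Linear latent aesthetic score on the Elo (400-point base-10) scale."""
    w = np.asarray(DEFAULT_LATENT_WEIGHTS if weights is None else weights, dtype=float)
    feats = latent_features(truth)
    if w.shape != feats.shape:
        raise ValueError(
            f"weights length {w.size} does not match feature list {feats.size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    return float(feats @ w + noise)


def win_probability(score_a: float, score_b: float) -> float:
    """P(A beats B) under the Elo logistic rule on the 400-point scale."""
    return 1.0 / (1.0 + 10.0 ** ((score_b - score_a) / 400.0))


AGE_CLASSES = ("<12", "13-18", "19-39", "40-59", ">60")
COUNTRIES = ("France", "Indonesia", "UK", "USA", "Australia", "Other")
EDUCATION = ("secondary", "high_school", "bachelor", "master", "phd")
DIVING = ("diving", "snorkelling", "none")
KNOWLEDGE = ("poor", "low", "average", "good", "excellent")
GENDERS = ("female", "male", "other")

# marginal frequencies of the survey population (country/education/
# knowledge/diving as published; gender and age filled in as plausible)
_ATTR_DISTS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "gender": (GENDERS, (0.52, 0.46, 0.02)),
    "age_class": (AGE_CLASSES, (0.01, 0.06, 0.53, 0.30, 0.10)),
    "country": (COUNTRIES, (0.285, 0.162, 0.14, 0.099, 0.071, 0.243)),
    "education": (EDUCATION, (0.0481, 0.1039, 0.2772, 0.3235, 0.2473)),
    "diving": (DIVING, (0.5332, 0.2437, 0.2231)),
    "coral_knowledge": (KNOWLEDGE, (0.1266, 0.2506, 0.2628, 0.2318, 0.1282)),
}
#: share of respondents reporting colour-vision deficiency (96 / 3348)
COLOUR_DEFICIENCY_RATE = 96.0 / 3348.0

ATTRIBUTE_NAMES = tuple(_ATTR_DISTS)


@dataclass(frozen=True)
class RespondentAttrs:
    """Socio-cultural attributes of one simulated survey respondent."""

    respondent_id: str
    gender: str
    age_class: str
    country: str
    education: str
    diving: str
    coral_knowledge: str
    colour_deficiency: bool

    def __post_init__(self) -> None:
        for name in ATTRIBUTE_NAMES:
            levels = _ATTR_DISTS[name][0]
            if getattr(self, name) not in levels:
                raise ValueError(f"{name} must be one of {levels}")


@dataclass(frozen=True)
class PreferenceRecord:
    """One forced pairwise choice (no ties)."""

    respondent_id: str
    photo_a: str
    photo_b: str
    winner: str
    attrs: RespondentAttrs

    def __post_init__(self) -> None:
        if self.photo_a == self.photo_b:
            raise ValueError("photo_a and photo_b must differ")
        if self.winner not in (self.photo_a, self.photo_b):
            raise ValueError("winner must be photo_a or photo_b")


def sample_respondents(n: int, seed: int | np.random.Generator = 0) -> list[RespondentAttrs]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n):
        kw = {
            name: levels[rng.choice(len(levels), p=probs)]
            for name, (levels, probs) in _ATTR_DISTS.items()
        }
        out.append(
            RespondentAttrs(
                respondent_id=f"resp-{i:05d}",
                colour_deficiency=bool(rng.random() < COLOUR_DEFICIENCY_RATE),
                **kw,
            )
        )
    return out


def _attr_shift(attrs: RespondentAttrs, attr_effects: Mapping[str, Mapping[str, float]]) -> float:
    return sum(
        float(levels.get(getattr(attrs, name), 0.0))
        for name, levels in attr_effects.items()
    )


def simulate_choices(
    scores: Mapping[str, float],
    n_respondents: int,
    pairs_each: int = 30,
    attr_effects: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | np.random.Generator = 0,
    respondents: Sequence[RespondentAttrs] | None = None,
) -> list[PreferenceRecord]:
    """Simulate the pairwise-preference survey.

    Each respondent judges ``pairs_each`` distinct random photograph
    pairs; A beats B with probability ``1 / (1 + 10**((s_b - s_a')/400))``
    where ``s_a'`` is A's latent score optionally shifted by the
    respondent's attribute effects (default: no effect).
    """
    ids = list(scores)
    if len(ids) < 2:
        raise ValueError("need at least 2 images to form pairs")
    max_pairs = len(ids) * (len(ids) - 1) // 2
    if pairs_each > max_pairs:
        raise ValueError(f"pairs_each={pairs_each} exceeds available pairs {max_pairs}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if respondents is None:
        respondents = sample_respondents(n_respondents, rng)
    elif len(respondents) != n_respondents:
        raise ValueError("len(respondents) must equal n_respondents")
    attr_effects = attr_effects or {}
    s = np.array([scores[i] for i in ids])

    records: list[PreferenceRecord] = []
    for attrs in respondents:
        shift = _attr_shift(attrs, attr_effects)
        seen: set[tuple[int, int]] = set()
        while len(seen) < pairs_each:
            a, b = rng.choice(len(ids), size=2, replace=False)
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            p_a = win_probability(s[a] + shift, s[b])
            winner = ids[a] if rng.random() < p_a else ids[b]
            records.append(
                PreferenceRecord(
                    respondent_id=attrs.respondent_id,
                    photo_a=ids[a], photo_b=ids[b],
                    winner=winner, attrs=attrs,
                )
            )
    return records


def exclude_colour_deficient(records: Iterable[PreferenceRecord]) -> list[PreferenceRecord]:
    """Drop records from respondents reporting colour-vision deficiency."""
    records = list(records)
    kept = [r for r in records if not r.attrs.colour_deficiency]
    if records and not kept:
        logger.warning("all %d records came from colour-deficient respondents", len(records))
    return kept


def records_to_frame(records: Sequence[PreferenceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "respondent_id": r.respondent_id,
            "photo_a": r.photo_a,
            "photo_b": r.photo_b,
            "winner": r.winner,
            "colour_deficiency": r.attrs.colour_deficiency,
        }
        row.update({name: getattr(r.attrs, name) for name in ATTRIBUTE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[PreferenceRecord]:
    out = []
    for _, row in df.iterrows():
        attrs = RespondentAttrs(
            respondent_id=row["respondent_id"],
            colour_deficiency=bool(row["colour_deficiency"]),
            **{name: row[name] for name in ATTRIBUTE_NAMES},
        )
        out.append(
            PreferenceRecord(
                respondent_id=row["respondent_id"],
                photo_a=row["photo_a"], photo_b=row["photo_b"],
                winner=row["winner"], attrs=attrs,
            )
        )
    return out
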