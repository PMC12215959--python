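"""Desk-scale orchestration of the whole aesthetic-value study.

``run_study`` executes the full chain on synthetic data: generate
quadrats for 3 habitats x sites x photos, apply the QC filter, extract
the nine photograph features, simulate the pairwise-preference survey
on a habitat-balanced photo subset, compute bootstrapped Elo ratings,
train the image predictor on the rated subset, predict ratings for
every QC-passed photo, and run the feature regression plus the habitat
mixed-model comparisons.  One master seed spawns a named substream per
stage, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import annotation, elo, imaging, predictor, stats, synthgen

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "qc_filter", "simulate_qc_flags", "run_study"]

#: stage order used when spawning per-stage seed substreams
_STAGES = (
    "generate", "qc", "points", "subset", "survey", "elo", "predictor",
)


@dataclass
class StudyConfig:
    """Sizes, rates and module settings for one synthetic study."""

    n_sites_per_habitat: int = 6
    photos_per_site: int = 50
    survey_subset_per_habitat: int = 100
    n_respondents: int = 300
    pairs_each: int = 30
    qc_fail_rate: float = 17.0 / 900.0
    qc_mode: str = "exact"  # "exact": round(rate*n) failures; or "bernoulli"
    image_side: int = 192
    n_points: int = 50
    # the habitat presets' cover SDs are the total within-habitat spread;
    # the study splits them into a between-site component (below) and a
    # residual within-site component, so generated batches keep the
    # habitat-level statistics while sites differ from one another
    site_coral_sd: float = 14.0
    site_rubble_sd: float = 12.0
    latent_noise_sd: float = 60.0
    attr_effects: dict | None = None
    elo_start: float = 0.0
    elo_k: float = 100.0
    elo_bootstrap: int = 1000
    cnn_epochs: int = 40
    cnn_learning_rate: float = 3e-3
    cnn_batch_size: int = 32
    cnn_input_side: int = 64
    run_respondent_effects: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites_per_habitat", "photos_per_site",
                     "survey_subset_per_habitat", "n_respondents", "pairs_each"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        per_habitat = self.n_sites_per_habitat * self.photos_per_site
        if self.survey_subset_per_habitat > per_habitat:
            raise ValueError(
                "survey_subset_per_habitat exceeds photos available per habitat"
            )
        if self.qc_mode not in ("exact", "bernoulli"):
            raise ValueError("qc_mode must be 'exact' or 'bernoulli'")
        if not 0.0 <= self.qc_fail_rate < 1.0:
            raise ValueError("qc_fail_rate must lie in [0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def simulate_qc_flags(
    images: Sequence[imaging.QuadratImage],
    rate: float,
    mode: str = "exact",
    seed: int | np.random.Generator = 0,
) -> None:
    """Simulate the visual colour-card QC judgement as metadata flags.

    ``exact`` flags round(rate * n) photos sampled without replacement
    (fixing the discard count); ``bernoulli`` flags each photo
    independently with probability ``rate``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(images)
    if mode == "exact":
        n_fail = int(round(rate * n))
        fail_idx = set(rng.choice(n, size=n_fail, replace=False).tolist()) if n_fail else set()
        for i, img in enumerate(images):
            img.qc_pass = i not in fail_idx
    elif mode == "bernoulli":
        flags = rng.random(n) < rate
        for img, f in zip(images, flags):
            img.qc_pass = not f
    else:
        raise ValueError("mode must be 'exact' or 'bernoulli'")


def qc_filter(
    images: Sequence[imaging.QuadratImage],
) -> tuple[list[imaging.QuadratImage], list[dict]]:
    """Keep QC-passed photos; log every discard with its id."""
    kept, discarded = [], []
    for img in images:
        if img.qc_pass:
            kept.append(img)
        else:
            discarded.append(
                {"image_id": img.image_id, "reason": "colour-card QC check failed"}
            )
    if not kept:
        logger.warning("QC filter discarded all %d photographs", len(images))
    return kept, discarded


@dataclass
class StudyResult:
    report: dict
    features: pd.DataFrame
    ratings: elo.EloRatings
    predictions: pd.Series
    regression: stats.RegressionResult
    habitat_tests: dict[str, stats.HabitatTestResult]
    respondent_table: pd.DataFrame | None = None
    records: list = field(default_factory=list)


#: response -> model family, mirroring the analysis defaults
HABITAT_MODEL_FAMILIES = {
    "predicted_rating": "gaussian",
    "pct_black": "gaussian",
    "pct_live_coral": "gaussian",
    "simpson": "gamma",
    "pct_blue": "gamma",
    "n_colours": "poisson",
    "n_morphologies": "poisson",
}


def _stage_seed(ss_children, name: str) -> np.random.Generator:
    return np.random.default_rng(ss_children[_STAGES.index(name)])


def run_study(cfg: StudyConfig | None = None, outdir: str | Path | None = None) -> StudyResult:
    """Run the full study; optionally write CSVs and a JSON report."""
    cfg = cfg or StudyConfig()
    ss_children = np.random.SeedSequence(cfg.seed).spawn(len(_STAGES))
    stage = "generate"
    try:
        # ---- generate -----------------------------------------------------
        gen_rng = _stage_seed(ss_children, "generate")
        images: list[imaging.QuadratImage] = []
        small_images: dict[str, np.ndarray] = {}
        truths: dict[str, synthgen.GroundTruth] = {}
        masks: dict[str, annotation.BenthicMask] = {}
        for habitat in ("healthy", "restored", "degraded"):
            preset = synthgen.HABITAT_PRESETS[habitat]
            for s in range(cfg.n_sites_per_habitat):
                site_id = f"{habitat}-site{s}"
                site_preset = preset.site_realization(
                    gen_rng, cfg.site_coral_sd, cfg.site_rubble_sd
                )
                for p in range(cfg.photos_per_site):
                    image_id = f"{habitat}-s{s}-p{p:03d}"
                    img_seed = int(gen_rng.integers(0, 2**31 - 1))
                    img, mask, truth = synthgen.generate_quadrat(
                        site_preset, seed=img_seed, side=cfg.image_side,
                        image_id=image_id, site_id=site_id,
                        depth_m=float(np.round(gen_rng.uniform(2.0, 4.0), 2)),
                        latent_noise_sd=cfg.latent_noise_sd,
                    )
                    images.append(img)
                    masks[image_id] = mask
                    truths[image_id] = truth
                    small_images[image_id] = _downsize(img.pixels, cfg.cnn_input_side)
        n_generated = len(images)

        # ---- QC -----------------------------------------------------------
        stage = "qc"
        simulate_qc_flags(images, cfg.qc_fail_rate, cfg.qc_mode,
                          _stage_seed(ss_children, "qc"))
        kept, discard_log = qc_filter(images)
        meta = pd.DataFrame(
            {
                "image_id": [i.image_id for i in kept],
                "site_id": [i.site_id for i in kept],
                "habitat": [i.habitat for i in kept],
                "depth_m": [i.depth_m for i in kept],
            }
        ).set_index("image_id")

        # ---- features -----------------------------------------------------
        stage = "points"
        pt_rng = _stage_seed(ss_children, "points")
        feat_rows = []
        for img in kept:
            tp = imaging.colour_thumbprint(img.pixels)
            groups = imaging.group_shares(tp)
            fv = annotation.assemble_features(
                img, tp, groups, masks[img.image_id],
                n_points=cfg.n_points, seed=int(pt_rng.integers(0, 2**31 - 1)),
            )
            feat_rows.append(fv.as_dict())
        features = pd.DataFrame(feat_rows).set_index("image_id")
        features = features.join(meta)

        # ---- survey subset ------------------------------------------------
        stage = "subset"
        sub_rng = _stage_seed(ss_children, "subset")
        subset_ids: list[str] = []
        for habitat in ("healthy", "restored", "degraded"):
            pool = [i.image_id for i in kept if i.habitat == habitat]
            if len(pool) < cfg.survey_subset_per_habitat:
                raise ValueError(
                    f"not enough QC-passed photos in {habitat} for the survey subset"
                )
            pick = sub_rng.choice(len(pool), cfg.survey_subset_per_habitat, replace=False)
            subset_ids.extend(pool[i] for i in sorted(pick))

        # ---- survey -------------------------------------------------------
        stage = "survey"
        latent = {i: truths[i].latent_aesthetic for i in subset_ids}
        records = synthgen.simulate_choices(
            latent, n_respondents=cfg.n_respondents, pairs_each=cfg.pairs_each,
            attr_effects=cfg.attr_effects, seed=_stage_seed(ss_children, "survey"),
        )
        n_records_raw = len(records)
        records = synthgen.exclude_colour_deficient(records)

        # ---- Elo ----------------------------------------------------------
        stage = "elo"
        elo_seed = int(_stage_seed(ss_children, "elo").integers(0, 2**31 - 1))
        ratings = elo.rate(
            records,
            elo.EloConfig(
                start_value=cfg.elo_start, k_factor=cfg.elo_k,
                n_bootstrap=cfg.elo_bootstrap, seed=elo_seed,
            ),
        )
        rated_ids = [i for i in subset_ids if i in ratings.table.index]
        elo_spearman = float(
            spearmanr(
                [ratings.mean_of(i) for i in rated_ids],
                [latent[i] for i in rated_ids],
            ).statistic
        )

        # ---- predictor ----------------------------------------------------
        stage = "predictor"
        pred_rng = _stage_seed(ss_children, "predictor")
        split_seed = int(pred_rng.integers(0, 2**31 - 1))
        cnn_seed = int(pred_rng.integers(0, 2**31 - 1))
        train_ids, val_ids, test_ids = predictor.split_dataset(
            rated_ids, predictor.SplitSpec(seed=split_seed)
        )
        pcfg = predictor.PredictorConfig(
            backend="small_cnn", input_side=cfg.cnn_input_side,
            epochs=cfg.cnn_epochs, learning_rate=cfg.cnn_learning_rate,
            batch_size=cfg.cnn_batch_size, seed=cnn_seed,
        )
        model = predictor.train(
            train_ids, val_ids, ratings, pcfg, images=small_images
        )
        test_r2 = predictor.evaluate_r2(model, test_ids, ratings, small_images)
        all_ids = [i.image_id for i in kept]
        predictions = predictor.predict_all(model, all_ids, small_images)

        # ---- statistics ---------------------------------------------------
        stage = "stats"
        table = features.copy()
        table["predicted_rating"] = predictions
        feature_cols = list(annotation.FeatureVector.FEATURE_NAMES)
        retained, filter_log = stats.correlation_filter(
            table[feature_cols], table["predicted_rating"]
        )
        regression = stats.backward_stepwise(
            table[retained], table["predicted_rating"]
        )
        habitat_tests: dict[str, stats.HabitatTestResult] = {}
        for response, family in HABITAT_MODEL_FAMILIES.items():
            data = pd.DataFrame(
                {
                    "value": table[response],
                    "habitat": table["habitat"],
                    "site_id": table["site_id"],
                }
            )
            habitat_tests[response] = stats.fit_habitat_model(
                data, family=family, response_name=response
            )
        respondent_table = None
        if cfg.run_respondent_effects:
            stage = "respondent_effects"
            respondent_table = stats.respondent_effects(records)
    except Exception as err:
        raise RuntimeError(f"study stage {stage!r} failed: {err}") from err

    report = {
        "config": dataclasses.asdict(cfg),
        "counts": {
            "generated": n_generated,
            "qc_discarded": len(discard_log),
            "after_qc": len(kept),
            "survey_subset": len(subset_ids),
            "choice_records_raw": n_records_raw,
            "choice_records_used": len(records),
            "split": {"train": len(train_ids), "val": len(val_ids), "test": len(test_ids)},
        },
        "elo": {
            "rating_min": float(ratings.table["rating_mean"].min()),
            "rating_max": float(ratings.table["rating_mean"].max()),
            "spearman_vs_latent": elo_spearman,
        },
        "predictor": {"val_r2": model.val_r2, "test_r2": test_r2},
        "regression": {
            "correlation_filter_removed": [e["removed"] for e in filter_log],
            "retained": list(regression.retained),
            "r_squared": regression.r_squared,
            "coefficients": {k: float(v) for k, v in regression.coefficients.items()},
            "importance_pct": {k: float(v) for k, v in regression.importance.items()},
        },
        "habitat_tests": {
            resp: {
                "family": t.family,
                "chi2": t.chi2,
                "df": t.df,
                "p": t.p,
                "letters": t.letters,
                "singular": t.singular,
            }
            for resp, t in habitat_tests.items()
        },
        "respondent_effects": (
            None
            if respondent_table is None
            else respondent_table.to_dict(orient="records")
        ),
    }

    result = StudyResult(
        report=report, features=table, ratings=ratings,
        predictions=predictions, regression=regression,
        habitat_tests=habitat_tests, respondent_table=respondent_table,
        records=records,
    )
    if outdir is not None:
        _write_outputs(result, discard_log, Path(outdir))
    return result


def _downsize(pixels: np.ndarray, side: int) -> np.ndarray:
    from PIL import Image

    if pixels.shape[0] == side:
        return pixels
    im = Image.fromarray(pixels)
    # nearest-neighbour: keeps the colour distribution of the full-size
    # render (interpolation would invent blended colours)
    return np.asarray(im.resize((side, side), resample=Image.NEAREST))


def _write_outputs(result: StudyResult, discard_log: list[dict], outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(outdir / "features.csv")
    result.ratings.save_csv(outdir / "ratings.csv")
    result.predictions.to_csv(outdir / "predictions.csv")
    synthgen.records_to_frame(result.records).to_csv(outdir / "choices.csv", index=False)
    pd.DataFrame(discard_log).to_csv(outdir / "qc_discards.csv", index=False)
    contrasts = pd.concat(
        [t.contrasts.assign(response=r) for r, t in result.habitat_tests.items()],
        ignore_index=True,
    )
    contrasts.to_csv(outdir / "habitat_contrasts.csv", index=False)
    (outdir / "report.json").write_text(
        json.dumps(result.report, indent=1, sort_keys=True)
    )
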