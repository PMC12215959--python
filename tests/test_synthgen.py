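"""Synthetic quadrat generation and survey simulation."""

import dataclasses
import logging

import numpy as np
import pytest

from reefaes import synthgen
from reefaes.synthgen import (
    HABITAT_PRESETS,
    GroundTruth,
    HabitatPreset,
    exclude_colour_deficient,
    generate_quadrat,
    latent_score,
    sample_covers,
    sample_respondents,
    simulate_choices,
    win_probability,
)


class TestPresets:
    def test_invalid_cover_mean_names_the_field(self):
        with pytest.raises(ValueError, match="coral_cover_mean"):
            dataclasses.replace(HABITAT_PRESETS["healthy"], coral_cover_mean=130.0)

    def test_negative_sd_names_the_field(self):
        with pytest.raises(ValueError, match="rubble_cover_sd"):
            dataclasses.replace(HABITAT_PRESETS["healthy"], rubble_cover_sd=-1.0)

    def test_unknown_morphology_rejected(self):
        with pytest.raises(ValueError, match="morphology_pool"):
            dataclasses.replace(HABITAT_PRESETS["healthy"], morphology_pool=("fractal",))


class TestCoverSampling:
    @pytest.mark.parametrize(
        "habitat, which, target",
        [
            ("healthy", 0, 70.46),    # field mean hard-coral cover
            ("degraded", 1, 74.91),   # field mean rubble cover
        ],
    )
    def test_batch_means_match_field_statistics(self, habitat, which, target):
        rng = np.random.default_rng(42)
        draws = [sample_covers(HABITAT_PRESETS[habitat], rng)[which] for _ in range(500)]
        assert np.mean(draws) == pytest.approx(target, abs=3.0)

    def test_draws_stay_in_range(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            c, r = sample_covers(HABITAT_PRESETS["degraded"], rng)
            assert 0.0 <= c <= 100.0 and 0.0 <= r <= 100.0
            assert c + r <= 100.0 + 1e-9


class TestGenerateQuadrat:
    def test_zero_cover_preset_has_no_coral_pixels(self):
        preset = dataclasses.replace(
            HABITAT_PRESETS["degraded"], coral_cover_mean=0.0, coral_cover_sd=0.0
        )
        _, mask, truth = generate_quadrat(preset, seed=3, side=64)
        assert truth.true_cover["hard_coral"] == 0.0
        assert not (mask.labels >= synthgen.CORAL_BASE).any()

    def test_ground_truth_equals_exact_pixel_fractions(self, quadrat_batch):
        for i, mask in quadrat_batch["masks"].items():
            exact = mask.exact_class_fractions()
            truth = quadrat_batch["truths"][i]
            for cls, pct in truth.true_cover.items():
                assert pct == pytest.approx(exact[cls], abs=1e-9)
            assert sum(truth.true_cover.values()) == pytest.approx(100.0)

    def test_realized_cover_tracks_sampled_target(self):
        # rendering paints colonies until the sampled target is hit and
        # trims the overshoot, so the realized fraction is pixel-exact
        preset = HABITAT_PRESETS["restored"]
        for seed in (1, 2, 3):
            _, mask, truth = generate_quadrat(preset, seed=seed, side=96)
            rng = np.random.default_rng(seed)
            target_c, _ = sample_covers(preset, rng)
            n_px = 96 * 96
            assert truth.true_cover["hard_coral"] * n_px / 100 == pytest.approx(
                round(target_c / 100 * n_px), abs=1.0
            )

    def test_identical_seed_is_bit_identical(self):
        a = generate_quadrat(HABITAT_PRESETS["healthy"], seed=11, side=64)
        b = generate_quadrat(HABITAT_PRESETS["healthy"], seed=11, side=64)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].labels, b[1].labels)
        assert a[2].latent_aesthetic == b[2].latent_aesthetic

    def test_image_and_mask_share_dimensions(self, quadrat_batch):
        for i, img in quadrat_batch["images"].items():
            assert img.pixels.shape[:2] == quadrat_batch["masks"][i].labels.shape

    def test_coral_pixels_carry_morphology_labels(self, quadrat_batch):
        for mask in quadrat_batch["masks"].values():
            coral_codes = np.unique(mask.labels[mask.labels >= synthgen.CORAL_BASE])
            for c in coral_codes:
                cls, morph = mask.legend[int(c)]
                assert cls == "hard_coral" and morph is not None

    def test_restored_frames_present(self, quadrat_batch):
        frame_cover = [
            t.true_cover["frame"]
            for i, t in quadrat_batch["truths"].items()
            if i.startswith("restored")
        ]
        assert any(f > 0 for f in frame_cover)
        assert all(
            t.true_cover["frame"] == 0
            for i, t in quadrat_batch["truths"].items()
            if i.startswith("healthy")
        )


def _truth(cover=50.0, rubble=0.0, n_morph=2, simpson=0.5):
    return GroundTruth(
        image_id="t",
        true_cover={"hard_coral": cover, "rubble": rubble, "sand": 100 - cover - rubble},
        true_morphologies=set(list(synthgen.MORPHOLOGIES)[:n_morph]),
        true_colour_shares={g: 100 / 6 for g in ("black", "blue", "green", "yellow", "grey", "other")},
        colour_simpson=simpson,
    )


class TestLatentScore:
    def test_zero_weights_zero_noise_gives_zero(self):
        assert latent_score(_truth(), weights=[0, 0, 0, 0], noise_sd=0.0) == 0.0

    def test_unit_cover_weight_orders_by_cover(self):
        scores = [
            latent_score(_truth(cover=c), weights=[0, 1, 0, 0], noise_sd=0.0)
            for c in (10.0, 40.0, 90.0)
        ]
        assert scores == sorted(scores)
        assert scores[-1] == 90.0

    def test_weight_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            latent_score(_truth(), weights=[1.0, 2.0])

    def test_default_weights_correlate_with_coral_cover(self, quadrat_batch):
        from scipy.stats import spearmanr

        truths = list(quadrat_batch["truths"].values())
        rho = spearmanr(
            [t.latent_aesthetic for t in truths],
            [t.true_cover["hard_coral"] for t in truths],
        ).statistic
        assert rho > 0.3


class TestSimulateChoices:
    def test_equal_scores_split_evenly(self):
        recs = simulate_choices({"a": 0.0, "b": 0.0}, n_respondents=10000, pairs_each=1, seed=0)
        wins_a = sum(r.winner == "a" for r in recs) / len(recs)
        assert wins_a == pytest.approx(0.5, abs=0.02)

    def test_400_point_gap_wins_ten_elevenths(self):
        recs = simulate_choices({"hi": 400.0, "lo": 0.0}, n_respondents=10000, pairs_each=1, seed=1)
        wins = sum(r.winner == "hi" for r in recs) / len(recs)
        assert wins == pytest.approx(10 / 11, abs=0.02)

    @pytest.mark.parametrize("gap", [0.0, 200.0, 400.0])
    def test_calibrated_against_logistic_rule(self, gap):
        recs = simulate_choices({"x": gap, "y": 0.0}, n_respondents=10000, pairs_each=1, seed=2)
        p_expected = win_probability(gap, 0.0)
        p_obs = sum(r.winner == "x" for r in recs) / len(recs)
        se = np.sqrt(p_expected * (1 - p_expected) / len(recs))
        assert abs(p_obs - p_expected) < 4 * se + 1e-9

    def test_record_count(self):
        scores = {f"i{k}": float(k) for k in range(40)}
        recs = simulate_choices(scores, n_respondents=100, pairs_each=30, seed=3)
        assert len(recs) == 3000

    def test_pairs_unique_within_respondent(self):
        scores = {f"i{k}": 0.0 for k in range(10)}
        recs = simulate_choices(scores, n_respondents=5, pairs_each=30, seed=4)
        for rid in {r.respondent_id for r in recs}:
            pairs = [
                frozenset((r.photo_a, r.photo_b)) for r in recs if r.respondent_id == rid
            ]
            assert len(set(pairs)) == len(pairs)

    def test_fewer_than_two_images_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_choices({"only": 1.0}, n_respondents=1)

    def test_attribute_effect_shifts_left_photo_wins(self):
        effects = {"country": {lvl: 400.0 for lvl in synthgen.COUNTRIES}}
        recs = simulate_choices(
            {"a": 0.0, "b": 0.0}, n_respondents=5000, pairs_each=1,
            attr_effects=effects, seed=5,
        )
        left_wins = sum(r.winner == r.photo_a for r in recs) / len(recs)
        assert left_wins == pytest.approx(10 / 11, abs=0.02)


class TestRespondents:
    def test_attribute_vocabularies(self):
        for r in sample_respondents(200, seed=0):
            assert r.country in synthgen.COUNTRIES
            assert r.age_class in synthgen.AGE_CLASSES
            assert r.diving in synthgen.DIVING

    def test_exclusion_removes_only_flagged(self):
        resp = sample_respondents(300, seed=1)
        recs = simulate_choices(
            {"a": 0.0, "b": 1.0, "c": 2.0}, n_respondents=300, pairs_each=2,
            seed=1, respondents=resp,
        )
        kept = exclude_colour_deficient(recs)
        assert all(not r.attrs.colour_deficiency for r in kept)
        n_flagged = sum(r.colour_deficiency for r in resp)
        assert len(kept) == len(recs) - 2 * n_flagged
        assert n_flagged > 0  # ~2.9% of 300

    def test_no_flags_is_identity(self):
        resp = [
            dataclasses.replace(r, colour_deficiency=False)
            for r in sample_respondents(20, seed=2)
        ]
        recs = simulate_choices({"a": 0.0, "b": 1.0}, 20, pairs_each=1, seed=2, respondents=resp)
        assert exclude_colour_deficient(recs) == recs

    def test_all_flagged_warns_and_empties(self, caplog):
        resp = [
            dataclasses.replace(r, colour_deficiency=True)
            for r in sample_respondents(5, seed=3)
        ]
        recs = simulate_choices({"a": 0.0, "b": 1.0}, 5, pairs_each=1, seed=3, respondents=resp)
        with caplog.at_level(logging.WARNING):
            assert exclude_colour_deficient(recs) == []
        assert "colour-deficient" in caplog.text
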