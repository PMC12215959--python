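"""Elo aesthetic ratings from pairwise preference records.

Each pairwise choice updates the winner's and loser's ratings by
``k * (1 - E_w)`` where ``E_w = 1 / (1 + 10**((r_l - r_w) / 400))`` is
the winner's expected score.  Because the final ratings depend on the
order in which choices are processed, the sequence is re-shuffled many
times (order bootstrap) and the per-photo mean and SD across runs are
reported.  All runs are processed simultaneously as a ratings matrix,
so the bootstrap is a single vectorized pass over the record sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthgen import PreferenceRecord

__all__ = ["EloConfig", "EloRatings", "elo_update", "rate"]


@dataclass(frozen=True)
class EloConfig:
    """Rating parameters; defaults follow common paired-rating practice."""

    start_value: float = 0.0
    k_factor: float = 100.0
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_factor <= 0:
            raise ValueError("k_factor must be > 0")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclass
class EloRatings:
    """Per-photo mean rating and spread across bootstrap runs."""

    table: pd.DataFrame  # index image_id; rating_mean, rating_sd, n_comparisons
    config: EloConfig

    def __post_init__(self) -> None:
        if (self.table["rating_sd"] < 0).any():
            raise ValueError("rating_sd must be >= 0")

    def mean_of(self, image_id: str) -> float:
        return float(self.table.loc[image_id, "rating_mean"])

    def as_series(self) -> pd.Series:
        return self.table["rating_mean"]

    def save_csv(self, path) -> None:
        self.table.to_csv(path, index=True)

    @classmethod
    def load_csv(cls, path, config: EloConfig | None = None) -> "EloRatings":
        df = pd.read_csv(path, index_col="image_id")
        return cls(table=df, config=config or EloConfig())


def elo_update(
    r_winner: float, r_loser: float, k: float = 100.0
) -> tuple[float, float]:
    """One rating update; the total of the two ratings is conserved."""
    expect_w = 1.0 / (1.0 + 10.0 ** ((r_loser - r_winner) / 400.0))
    delta = k * (1.0 - expect_w)
    return r_winner + delta, r_loser - delta


def rate(records: Sequence[PreferenceRecord], cfg: EloConfig | None = None) -> EloRatings:
    """Order-bootstrapped Elo ratings for every photo in the records.

    Every bootstrap run starts all photos at ``start_value`` and
    processes the records in an independently shuffled order drawn from
    a per-run substream of the master seed.
    """
    if cfg is None:
        cfg = EloConfig()
    records = list(records)
    if not records:
        raise ValueError("cannot rate an empty record list")

    ids = sorted({r.photo_a for r in records} | {r.photo_b for r in records})
    idx = {im: i for i, im in enumerate(ids)}
    win = np.array([idx[r.winner] for r in records], dtype=np.int64)
    lose = np.array(
        [idx[r.photo_b if r.winner == r.photo_a else r.photo_a] for r in records],
        dtype=np.int64,
    )
    n_rec, n_img, n_runs = len(records), len(ids), cfg.n_bootstrap

    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(n_runs)]
    orders = np.stack([s.permutation(n_rec) for s in streams])  # runs x records

    ratings = np.full((n_runs, n_img), float(cfg.start_value))
    run_ix = np.arange(n_runs)
    for t in range(n_rec):
        rec = orders[:, t]
        w, l = win[rec], lose[rec]
        rw = ratings[run_ix, w]
        rl = ratings[run_ix, l]
        delta = cfg.k_factor * (1.0 - 1.0 / (1.0 + 10.0 ** ((rl - rw) / 400.0)))
        ratings[run_ix, w] = rw + delta
        ratings[run_ix, l] = rl - delta

    n_comp = np.bincount(np.concatenate([win, lose]), minlength=n_img)
    table = pd.DataFrame(
        {
            "rating_mean": ratings.mean(axis=0),
            "rating_sd": ratings.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(n_img),
            "n_comparisons": n_comp,
        },
        index=pd.Index(ids, name="image_id"),
    )
    return EloRatings(table=table, config=cfg)
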