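"""Pool residency and movement distances from consecutive recaptures.

Each pair of consecutive captures of an animal (one capture per occasion)
yields a movement: same pool or a distance between pool chainages. Residency
per sex–age class gets an exact Beta posterior; distance means get bootstrap
intervals. Residency feeds the apparent-survival adjustment S = Φ/r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .bayes import beta_binomial_test
from .io_data_model import (
    FIVE_CLASSES,
    CaptureRecord,
    Occasion,
    PoolMap,
    assign_occasion,
    survey_year,
)


@dataclass(frozen=True)
class MovePair:
    animal_id: str
    class_at_first: str  # five-class label at the earlier capture
    distance_m: float
    same_pool: bool

    def __post_init__(self) -> None:
        if self.distance_m < 0:
            raise ValueError("distance must be non-negative")
        if self.same_pool != (self.distance_m == 0):
            raise ValueError("same_pool must hold exactly when distance is zero")


def consecutive_moves(
    records: Sequence[CaptureRecord],
    pools: PoolMap,
    occasions: Optional[Sequence[Occasion]] = None,
    season_start_month: int = 7,
) -> list[MovePair]:
    """One MovePair per consecutive pair of occasions on which an animal was caught.

    Captures within one occasion collapse to the first; the pair's class is the
    animal's class at the earlier capture (when the movement decision was made).
    """
    by_animal: dict[str, list[CaptureRecord]] = {}
    for r in records:
        by_animal.setdefault(r.animal_id, []).append(r)

    pairs: list[MovePair] = []
    for aid, recs in by_animal.items():
        recs = sorted(recs, key=lambda r: r.date)
        per_occ: dict[int, CaptureRecord] = {}
        for r in recs:
            occ = (
                assign_occasion(r, occasions)
                if occasions is not None
                else survey_year(r.date, season_start_month)
            )
            per_occ.setdefault(occ, r)
        keys = sorted(per_occ)
        for a, b in zip(keys, keys[1:]):
            r1, r2 = per_occ[a], per_occ[b]
            dist = pools.distance(r1.pool_id, r2.pool_id)
            pairs.append(
                MovePair(
                    animal_id=aid,
                    class_at_first=r1.five_class,
                    distance_m=dist,
                    same_pool=dist == 0,
                )
            )
    return pairs


@dataclass
class ClassMovement:
    n_pairs: int
    residency_mean: float
    residency_interval: tuple
    mean_distance_m: float
    distance_interval_m: tuple
    max_distance_m: float
    fraction_over_2km: float


def residency_and_distances(
    moves: Sequence[MovePair],
    n_boot: int = 10_000,
    seed: int = 0,
    credible_level: float = 0.95,
) -> dict:
    """Per-class residency posteriors and movement-distance summaries.

    Residency is Beta(1+x, 1+n−x) over same-pool counts; the distance mean's
    central interval comes from a percentile bootstrap. Classes with no pairs
    are reported as absent (None).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, Optional[ClassMovement]] = {}
    for cls in FIVE_CLASSES:
        dists = np.array([m.distance_m for m in moves if m.class_at_first == cls])
        if len(dists) == 0:
            out[cls] = None
            continue
        same = int(sum(1 for m in moves if m.class_at_first == cls and m.same_pool))
        post = beta_binomial_test(same, len(dists), credible_level)
        boot_means = rng.choice(dists, size=(n_boot, len(dists)), replace=True).mean(axis=1)
        lo = (1 - credible_level) / 2
        out[cls] = ClassMovement(
            n_pairs=len(dists),
            residency_mean=post.mean,
            residency_interval=post.interval,
            mean_distance_m=float(dists.mean()),
            distance_interval_m=(
                float(np.quantile(boot_means, lo)),
                float(np.quantile(boot_means, 1 - lo)),
            ),
            max_distance_m=float(dists.max()),
            fraction_over_2km=float((dists > 2000).mean()),
        )
    return out
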