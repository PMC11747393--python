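"""Split-half internal reliability of the pairwise rating instrument.

Participants are randomly split into two halves; each half's 120-element
vector of per-pair mean ratings is computed and the two vectors are Pearson
correlated. The mean correlation over many random splits is reported both
raw and Spearman–Brown corrected (``2r / (1 + r)``), since a split-half
correlation understates the reliability of the full-length sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import RatingMatrix


@dataclass(frozen=True)
class ReliabilityResult:
    r_raw: float
    r_corrected: float
    r_splits_sd: float
    n_splits: int
    seed: int


def spearman_brown(r: float) -> float:
    """Prophecy correction for doubling test length: 2r / (1 + r)."""
    if r <= -1.0:
        raise ValueError("correction undefined at r = -1")
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    ratings: RatingMatrix, n_splits: int = 500, seed: int = 0
) -> ReliabilityResult:
    """Mean split-half correlation of per-pair mean-rating vectors.

    Splits depend only on the seed, not on input row order: participants are
    sorted by id before the random halving, so reordering rows leaves the
    result unchanged.
    """
    n = ratings.n_participants
    if n < 4:
        raise ValueError("split-half reliability needs at least 4 participants")
    order = np.argsort(np.asarray(ratings.participant_ids))
    values = ratings.values[order].astype(float)
    rng = np.random.default_rng(seed)
    half = n // 2
    rs = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(n)
        m1 = values[perm[:half]].mean(axis=0)
        m2 = values[perm[half:]].mean(axis=0)
        with np.errstate(invalid="ignore"):
            rs[s] = np.corrcoef(m1, m2)[0, 1]
    r = float(np.nanmean(rs))
    return ReliabilityResult(
        r_raw=r,
        r_corrected=spearman_brown(r),
        r_splits_sd=float(np.nanstd(rs)),
        n_splits=n_splits,
        seed=seed,
    )
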