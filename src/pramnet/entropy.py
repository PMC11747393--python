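"""Across-participant rating entropy and the entropy-vs-news-effect sigmoid.

The Shannon entropy of one concept pair,

    H = - sum_i p(x_i) * log2 p(x_i),

is computed over the empirical distribution of the 15 discrete rating
levels across participants (0 * log 0 = 0), so H ranges from 0 (everyone
gives the same rating) to log2(15) ≈ 3.9069 bits (uniform use of the
scale). The relation between a pair's entropy and the magnitude of its
news-bias regression effect is summarized with an offset sigmoid

    f(x) = 1 / (1 + exp(-a * (x - b))) + c

fit by nonlinear least squares with seeded multi-start initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.stats import norm

from .data_model import N_RATING_LEVELS, RATING_MAX, RATING_MIN, PairIndex, RatingMatrix

MAX_ENTROPY_BITS = float(np.log2(N_RATING_LEVELS))


def pair_entropy(ratings: np.ndarray, miller_madow: bool = False) -> float:
    """Shannon entropy (bits) of one pair's rating distribution.

    ``miller_madow=True`` adds the (K-1)/(2N ln 2) small-sample bias
    correction, with K the number of observed levels.
    """
    r = np.asarray(ratings)
    if r.size == 0:
        raise ValueError("entropy needs at least one rating")
    counts = np.bincount((r - RATING_MIN).astype(int), minlength=N_RATING_LEVELS)
    p = counts / counts.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    if miller_madow:
        h += (len(nz) - 1) / (2.0 * r.size * np.log(2.0))
    return h


@dataclass(frozen=True)
class EntropyTable:
    """Per-pair entropy and level distribution."""

    table: pd.DataFrame  # pair, concept_a, concept_b, entropy
    distributions: np.ndarray  # n_pairs x 15 empirical level frequencies
    pair_index: PairIndex


def entropy_table(ratings: RatingMatrix, miller_madow: bool = False) -> EntropyTable:
    pi = ratings.pair_index
    n_pairs = len(pi)
    dists = np.zeros((n_pairs, N_RATING_LEVELS))
    rows = []
    for k in range(n_pairs):
        col = ratings.values[:, k]
        counts = np.bincount(col - RATING_MIN, minlength=N_RATING_LEVELS)
        dists[k] = counts / counts.sum()
        a, b = pi.labels(k)
        rows.append(
            {
                "pair": k,
                "concept_a": a,
                "concept_b": b,
                "entropy": pair_entropy(col, miller_madow=miller_madow),
            }
        )
    return EntropyTable(pd.DataFrame(rows), dists, pi)


def offset_sigmoid(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a * (x - b))) + c


@dataclass(frozen=True)
class SigmoidFit:
    a: float
    b: float
    c: float
    se: tuple[float, float, float]
    ci95: tuple[tuple[float, float], ...]
    r_squared: float
    converged: bool
    degenerate: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        return offset_sigmoid(np.asarray(x, float), self.a, self.b, self.c)


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    span = np.ptp(x)
    a0 = 4.0 / span if span > 0 else 1.0
    # inflection guess: steepest local increase of a moving average of y
    order = np.argsort(x)
    ys = pd.Series(y[order]).rolling(5, min_periods=1, center=True).mean().to_numpy()
    dx = np.diff(x[order])
    dy = np.diff(ys)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(dx > 0, dy / dx, 0.0)
    b0 = float(x[order][np.argmax(slope)]) if slope.size else float(np.median(x))
    c0 = float(np.min(y))
    return a0, b0, c0


def fit_offset_sigmoid(
    x: np.ndarray,
    y: np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
) -> SigmoidFit:
    """Nonlinear least-squares fit of the offset sigmoid with multi-start.

    The base initialization sets the slope from the x-range, the inflection
    at the steepest rise of a smoothed y, and the offset at min(y); jittered
    restarts guard against local minima and the best SSE wins. A constant y
    (or fewer than 4 points) is flagged degenerate with R² = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must be the same length")
    if x.size < 4:
        raise ValueError("sigmoid fit needs at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if np.ptp(y) == 0 or ss_tot == 0.0:
        return SigmoidFit(
            np.nan, np.nan, np.nan, (np.nan,) * 3, ((np.nan, np.nan),) * 3,
            r_squared=0.0, converged=False, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    a0, b0, c0 = _initial_guess(x, y)
    best = None
    for trial in range(n_restarts):
        if trial == 0:
            p0 = (a0, b0, c0)
        else:
            p0 = (
                a0 * float(np.exp(rng.normal(0, 1))),
                b0 + float(rng.normal(0, 0.5 * np.std(x) + 1e-12)),
                c0 + float(rng.normal(0, 0.5 * np.std(y) + 1e-12)),
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(offset_sigmoid, x, y, p0=p0, maxfev=20_000)
        except (RuntimeError, TypeError):
            continue
        sse = float(((y - offset_sigmoid(x, *popt)) ** 2).sum())
        if np.isfinite(sse) and (best is None or sse < best[0]):
            best = (sse, popt, pcov)
    if best is None:
        return SigmoidFit(
            np.nan, np.nan, np.nan, (np.nan,) * 3, ((np.nan, np.nan),) * 3,
            r_squared=np.nan, converged=False,
        )
    sse, popt, pcov = best
    se = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0, np.inf)))
    zcrit = float(norm.ppf(0.975))
    ci = tuple((float(p - zcrit * s), float(p + zcrit * s)) for p, s in zip(popt, se))
    r2 = 1.0 - sse / ss_tot
    return SigmoidFit(
        a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
        se=se, ci95=ci, r_squared=float(r2), converged=True,
    )


@dataclass(frozen=True)
class EntropyEffectAnalysis:
    entropy: EntropyTable
    fit: SigmoidFit
    #: per-pair join of entropy with the (absolute) news-bias coefficient
    table: pd.DataFrame
    #: pairs with extreme entropy or effect magnitude, for labeling
    extremes: pd.DataFrame


def entropy_effect_analysis(
    edge_results,
    ratings: RatingMatrix,
    predictor: str = "news_bias",
    n_extremes: int = 3,
    miller_madow: bool = False,
    seed: int = 0,
) -> EntropyEffectAnalysis:
    """Join per-pair entropy with |news-bias effect| and fit the sigmoid.

    The fitted response is the absolute coefficient; signed coefficients are
    carried in the joined table for plotting but do not enter the fit.
    """
    ent = entropy_table(ratings, miller_madow=miller_madow)
    eff = edge_results.for_predictor(predictor)[["pair", "beta", "q_value", "significant"]]
    joined = ent.table.merge(eff, on="pair")
    joined["abs_beta"] = joined["beta"].abs()
    fit = fit_offset_sigmoid(
        joined["entropy"].to_numpy(), joined["abs_beta"].to_numpy(), seed=seed
    )
    lo_h = joined.nsmallest(n_extremes, "entropy").assign(kind="lowest_entropy")
    hi_h = joined.nlargest(n_extremes, "entropy").assign(kind="highest_entropy")
    hi_b = joined.nlargest(n_extremes, "abs_beta").assign(kind="largest_effect")
    extremes = pd.concat([lo_h, hi_h, hi_b], ignore_index=True)
    return EntropyEffectAnalysis(entropy=ent, fit=fit, table=joined, extremes=extremes)
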