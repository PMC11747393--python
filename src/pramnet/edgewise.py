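"""Edge-wise general linear models with permutation nulls and FDR control.

For each concept pair, the participant edge weights are regressed on a
predictor of interest plus nuisance covariates (gender, income bracket,
age) with ordinary least squares. Significance of the predictor's
coefficient is assessed against a permutation null — by default the tested
predictor column is randomly scrambled across participants while the
response and covariates stay fixed; a Freedman–Lane scheme (permuting the
residuals of the nuisance-only model) is available as an option. Two-sided
p-values use the add-one convention

    p = (1 + #{ |beta*| >= |beta_hat| }) / (n_perm + 1)

and are Benjamini–Hochberg corrected across the pairs, separately per
predictor.

When racial identity is the predictor of interest the news-bias column is
deliberately left out of the model: news bias is the hypothesized mediator
of group differences, and conditioning on it would absorb exactly the
indirect path the downstream mediation screen is meant to decompose. When
news bias is tested, racial identity joins the nuisance set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .data_model import Cohort, PairIndex, ValidationError
from .graphs import EdgeWeightMatrix

NUISANCE = ("gender", "income", "age")

#: predictor name -> covariates entering its model besides the nuisance set
_EXTRA_COVARIATES = {"race": (), "news_bias": ("race",)}


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is not full column rank."""


@dataclass(frozen=True)
class Design:
    """Design matrix for one predictor of interest, restricted to complete cases."""

    X: np.ndarray
    columns: tuple[str, ...]
    tested: int  # column index of the predictor of interest
    rows: np.ndarray  # boolean mask into the cohort


def build_design(cohort: Cohort, predictor: str) -> Design:
    """Assemble [intercept, predictor, covariates] over scored participants."""
    mask = cohort.scored_mask()
    demo = cohort.demographics.loc[mask]
    values = {
        "race": demo["race"].to_numpy(float),
        "gender": demo["gender"].to_numpy(float),
        "income": demo["income"].to_numpy(float),
        "age": demo["age"].to_numpy(float),
        "news_bias": cohort.news_bias[mask],
    }
    if predictor not in values:
        raise ValueError(f"unknown predictor {predictor!r}")
    extra = _EXTRA_COVARIATES.get(predictor, ())
    cols = ["intercept", predictor, *extra, *NUISANCE]
    X = np.column_stack(
        [np.ones(mask.sum())] + [values[c] for c in cols[1:]]
    )
    _check_rank(X, cols)
    return Design(X=X, columns=tuple(cols), tested=1, rows=mask)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivots
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in range(len(names)) if diag[i] < 1e-10 * diag.max()]
        raise RankDeficientError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear columns: {bad or 'unresolved'}"
        )


def fit_edge_glm(
    y: np.ndarray, X: np.ndarray, names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and standard errors for one edge.

    Raises :class:`RankDeficientError` naming the collinear columns when the
    design is singular.
    """
    y = np.asarray(y, float)
    if y.shape[0] != X.shape[0]:
        raise ValidationError(f"{y.shape[0]} responses vs {X.shape[0]} design rows")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    _check_rank(X, names)
    fit = sm.OLS(y, X).fit()
    return fit.params, fit.bse


def _fwl(X: np.ndarray, tested: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the non-tested columns, and the residualized x."""
    C = np.delete(X, tested, axis=1)
    Q, _ = np.linalg.qr(C)
    x = X[:, tested]
    xt = x - Q @ (Q.T @ x)
    return Q, xt


def _permutation_indices(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    idx = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(idx, axis=1)


def permutation_pvalue(
    y: np.ndarray,
    X: np.ndarray,
    tested: int,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    scheme: str = "simple",
) -> tuple[float, float]:
    """Two-sided permutation p-value for one coefficient; returns (p, beta_hat).

    ``scheme="simple"`` scrambles the tested predictor column, holding the
    response and covariates fixed; ``scheme="freedman-lane"`` scrambles the
    residuals of the nuisance-only model. Reproducible given the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(y, float)
    x = X[:, tested]
    if np.ptp(x) == 0:
        raise ValidationError("tested predictor column is constant")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = y.shape[0]
    Q, xt = _fwl(X, tested)
    yt = y - Q @ (Q.T @ y)  # residual of y on the non-tested columns
    xt_norm2 = xt @ xt
    beta_hat = (xt @ yt) / xt_norm2

    idx = _permutation_indices(rng, n_perm, n)
    if scheme == "simple":
        xp = x[idx]  # n_perm x n
        B = xp @ Q
        xtp = xp - B @ Q.T
        num = xtp @ yt
        den = np.einsum("ij,ij->i", xtp, xp)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_star = np.where(den > 0, num / den, 0.0)
    elif scheme == "freedman-lane":
        # under H0 the nuisance-only residuals of y are exchangeable; the
        # fitted nuisance part is orthogonal to xt so it drops from beta*
        rp = yt[idx]
        beta_star = (rp @ xt) / xt_norm2
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    exceed = np.count_nonzero(np.abs(beta_star) >= np.abs(beta_hat) - 1e-12)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return float(p), float(beta_hat)


def fdr_correct(pvals: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: returns (q_values, reject_flags)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass(frozen=True)
class EdgeInferenceResult:
    """Per-pair, per-predictor coefficients, permutation p, BH q, flags."""

    table: pd.DataFrame
    pair_index: PairIndex
    n_perm: int
    alpha: float
    seed: int
    scheme: str

    def for_predictor(self, predictor: str) -> pd.DataFrame:
        return self.table[self.table["predictor"] == predictor].reset_index(drop=True)

    def significant_pairs(self, predictor: str) -> list[int]:
        df = self.for_predictor(predictor)
        return sorted(df.loc[df["significant"], "pair"].astype(int))

    def n_significant(self, predictor: str) -> int:
        return len(self.significant_pairs(predictor))


def _edge_rng(seed: int, predictor: str, pair: int) -> np.random.Generator:
    # named substream per (seed, predictor, edge): results do not depend on
    # the order in which edges are evaluated
    tag = sum(ord(c) for c in predictor)
    return np.random.default_rng(np.random.SeedSequence((seed, tag, pair)))


def run_edgewise(
    cohort: Cohort,
    predictors: Sequence[str] = ("race", "news_bias"),
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "simple",
) -> EdgeInferenceResult:
    """Fit the edge-wise GLM and permutation test on every concept pair.

    BH correction is applied across pairs separately for each predictor of
    interest (family size = number of pairs).
    """
    weights = EdgeWeightMatrix.from_ratings(cohort.ratings)
    pi = cohort.pair_index
    rows = []
    for predictor in predictors:
        design = build_design(cohort, predictor)
        Y = weights.values[design.rows]
        names = design.columns
        for k in range(len(pi)):
            y = Y[:, k]
            coefs, ses = fit_edge_glm(y, design.X, names)
            p, _ = permutation_pvalue(
                y,
                design.X,
                design.tested,
                n_perm=n_perm,
                seed=_edge_rng(seed, predictor, k),
                scheme=scheme,
            )
            a, b = pi.labels(k)
            rows.append(
                {
                    "pair": k,
                    "concept_a": a,
                    "concept_b": b,
                    "predictor": predictor,
                    "beta": coefs[design.tested],
                    "se": ses[design.tested],
                    "mean_weight": float(y.mean()),
                    "p_value": p,
                }
            )
    table = pd.DataFrame(rows)
    table["q_value"] = np.nan
    table["significant"] = False
    for predictor in predictors:
        m = table["predictor"] == predictor
        q, rej = fdr_correct(table.loc[m, "p_value"].to_numpy(), alpha)
        table.loc[m, "q_value"] = q
        table.loc[m, "significant"] = rej
    return EdgeInferenceResult(
        table=table, pair_index=pi, n_perm=n_perm, alpha=alpha, seed=seed, scheme=scheme
    )
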