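"""Group -> news-bias -> edge-weight mediation screen.

For each group-differing concept pair, three nested OLS fits decompose the
total group effect ``c`` on the edge weight into a direct path ``c'`` and
an indirect path ``a * b`` through mean news bias:

    m ~ x + C          ->  a   (group -> mediator)
    y ~ x + C          ->  c   (total effect)
    y ~ x + m + C      ->  c', b

with C the nuisance covariates (gender, income, age). Because the three
models share the covariate set, ``c = c' + a*b`` holds exactly. The
indirect effect is tested by permuting the mediator across participants
(preserving the x–y relation while breaking both the a and b paths), with
a Sobel normal-approximation test reported as converging evidence. Edges
are classified full (direct effect loses FDR significance), partial (both
paths survive), or unmediated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .data_model import Cohort, PairIndex, ValidationError
from .edgewise import NUISANCE, _check_rank, _permutation_indices, fdr_correct
from .graphs import EdgeWeightMatrix

LABELS = ("not_race_differing", "unmediated", "partial", "full")


@dataclass(frozen=True)
class MediationPaths:
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    c_prime: float
    se_c_prime: float
    p_direct: float  # two-sided t-test p for c' in the full model

    @property
    def indirect(self) -> float:
        return self.a * self.b


def mediation_paths(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> MediationPaths:
    """Estimate the a/b/c/c' paths via three nested OLS fits."""
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    n = x.shape[0]
    if not (m.shape[0] == y.shape[0] == n):
        raise ValidationError("x, m, y must be row-aligned")
    if np.isnan(m).any():
        raise ValidationError("mediator contains missing values")
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    ones = np.ones((n, 1))
    Xa = np.hstack([ones, x[:, None], C])
    _check_rank(Xa, ["intercept", "x"] + [f"c{i}" for i in range(C.shape[1])])
    fit_a = sm.OLS(m, Xa).fit()
    fit_c = sm.OLS(y, Xa).fit()
    Xb = np.hstack([ones, x[:, None], m[:, None], C])
    _check_rank(Xb, ["intercept", "x", "m"] + [f"c{i}" for i in range(C.shape[1])])
    fit_b = sm.OLS(y, Xb).fit()
    return MediationPaths(
        a=float(fit_a.params[1]),
        se_a=float(fit_a.bse[1]),
        b=float(fit_b.params[2]),
        se_b=float(fit_b.bse[2]),
        c=float(fit_c.params[1]),
        se_c=float(fit_c.bse[1]),
        c_prime=float(fit_b.params[1]),
        se_c_prime=float(fit_b.bse[1]),
        p_direct=float(fit_b.pvalues[1]),
    )


def sobel_test(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Sobel z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2), two-sided normal p.

    At a = b = 0 the statistic is taken as 0 with p = 1 (limit convention).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    denom = np.sqrt(b * b * se_a * se_a + a * a * se_b * se_b)
    if denom == 0.0:
        return 0.0, 1.0
    z = a * b / denom
    return float(z), float(2.0 * norm.sf(abs(z)))


def mediation_permutation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation p-value for the indirect effect; returns (p, indirect_hat).

    The mediator is scrambled across participants and a*b recomputed on each
    permutation; two-sided with add-one smoothing.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if np.ptp(m) == 0:
        raise ValidationError("mediator is constant")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.shape[0]
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    ones = np.ones((n, 1))

    # a path: coefficient of x in m ~ x + C, via residualized x
    Qa, _ = np.linalg.qr(np.hstack([ones, C]))
    xt = x - Qa @ (Qa.T @ x)
    xt_norm2 = xt @ xt
    # b path: coefficient of m in y ~ x + m + C, via m residualized on [1, x, C]
    Qb, _ = np.linalg.qr(np.hstack([ones, x[:, None], C]))
    yt = y - Qb @ (Qb.T @ y)

    def ab(m_cols: np.ndarray) -> np.ndarray:
        # m_cols: n_draws x n
        a = (m_cols @ xt) / xt_norm2
        mt = m_cols - (m_cols @ Qb) @ Qb.T
        den = np.einsum("ij,ij->i", mt, m_cols)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(den > 0, (mt @ yt) / den, 0.0)
        return a * b

    indirect_hat = float(ab(m[None, :])[0])
    idx = _permutation_indices(rng, n_perm, n)
    indirect_star = ab(m[idx])
    exceed = np.count_nonzero(np.abs(indirect_star) >= abs(indirect_hat) - 1e-12)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return float(p), indirect_hat


def classify_mediation(
    q_indirect: float, q_direct: float, race_flag: bool, alpha: float = 0.05
) -> str:
    """Label an edge from FDR-adjusted indirect and direct q-values."""
    if not race_flag:
        return "not_race_differing"
    if q_indirect <= alpha and q_direct > alpha:
        return "full"
    if q_indirect <= alpha and q_direct <= alpha:
        return "partial"
    return "unmediated"


@dataclass(frozen=True)
class MediationResult:
    """Per-edge path estimates, tests and labels for the screened pairs."""

    table: pd.DataFrame
    pair_index: PairIndex
    n_perm: int
    alpha: float
    seed: int

    def label_counts(self) -> dict[str, int]:
        counts = self.table["label"].value_counts().to_dict()
        return {lab: int(counts.get(lab, 0)) for lab in LABELS}

    def labels_by_pair(self) -> dict[int, str]:
        return dict(zip(self.table["pair"].astype(int), self.table["label"]))


def _edge_rng(seed: int, pair: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, 104, pair)))


def run_mediation_screen(
    cohort: Cohort,
    race_differing_pairs,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    include_covariates: bool = True,
) -> MediationResult:
    """Mediation analysis over the group-differing edges.

    BH correction is applied separately to the indirect (permutation) and
    direct (t-test) p-value families over the screened edge set, and edges
    are classified full / partial / unmediated. An empty input set yields an
    empty table.
    """
    pairs = sorted(int(k) for k in race_differing_pairs)
    pi = cohort.pair_index
    cols = [
        "pair", "concept_a", "concept_b", "a", "se_a", "b", "se_b", "c", "se_c",
        "c_prime", "se_c_prime", "indirect", "sobel_z", "sobel_p",
        "p_indirect", "p_direct", "q_indirect", "q_direct", "label",
    ]
    if not pairs:
        return MediationResult(pd.DataFrame(columns=cols), pi, n_perm, alpha, seed)

    mask = cohort.scored_mask()
    demo = cohort.demographics.loc[mask]
    x = demo["race"].to_numpy(float)
    m = cohort.news_bias[mask]
    C = (
        demo[list(NUISANCE)].to_numpy(float)
        if include_covariates
        else None
    )
    weights = EdgeWeightMatrix.from_ratings(cohort.ratings).values[mask]

    rows = []
    for k in pairs:
        y = weights[:, k]
        paths = mediation_paths(x, m, y, C)
        z, sp = sobel_test(paths.a, paths.se_a, paths.b, paths.se_b)
        p_ind, _ = mediation_permutation(
            x, m, y, C, n_perm=n_perm, seed=_edge_rng(seed, k)
        )
        a_lab, b_lab = pi.labels(k)
        rows.append(
            {
                "pair": k, "concept_a": a_lab, "concept_b": b_lab,
                "a": paths.a, "se_a": paths.se_a, "b": paths.b, "se_b": paths.se_b,
                "c": paths.c, "se_c": paths.se_c,
                "c_prime": paths.c_prime, "se_c_prime": paths.se_c_prime,
                "indirect": paths.indirect, "sobel_z": z, "sobel_p": sp,
                "p_indirect": p_ind, "p_direct": paths.p_direct,
            }
        )
    table = pd.DataFrame(rows)
    q_ind, _ = fdr_correct(table["p_indirect"].to_numpy(), alpha)
    q_dir, _ = fdr_correct(np.clip(table["p_direct"].to_numpy(), 1e-300, 1.0), alpha)
    table["q_indirect"] = q_ind
    table["q_direct"] = q_dir
    table["label"] = [
        classify_mediation(qi, qd, True, alpha) for qi, qd in zip(q_ind, q_dir)
    ]
    return MediationResult(table[cols], pi, n_perm, alpha, seed)
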