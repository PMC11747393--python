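"""Synthetic cohort generator with planted group, mediator and news effects.

The generator emulates the statistical structure the downstream analyses
assume: two identity groups of equal size, a continuous mediator (partisan
news bias on the 1–5 scale) shifted between groups by an ``a`` path, and per
concept-pair latent ratings

    latent = baseline + direct * group + b * (mediator - E[mediator])
             + covariate terms + Normal(0, noise_sd)

rounded to the nearest integer and clipped to the 15-level −7..+7 scale.
Rounding and clipping shrink planted effects toward zero, so recovery
scenarios plant effects well inside the scale.

The mediator is quantized to the 1/3 grid reachable as a mean of three
integer source scores, so a simulated cohort written to the three CSV
tables and reloaded reproduces the identical analysis inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    BIAS_MAX,
    BIAS_MIN,
    RATING_MAX,
    RATING_MIN,
    BiasLookup,
    Cohort,
    ConceptSet,
    PairIndex,
    RatingMatrix,
    canonical_pair_index,
    write_cohort,
)

logger = logging.getLogger(__name__)

#: Synthetic outlets spanning the 5-point bias scale, used when a simulated
#: cohort is written to CSV so that reloading reproduces the same bias scores.
SYNTHETIC_OUTLETS: dict[str, int] = {
    "synthetic left wire": 1,
    "synthetic left-leaning post": 2,
    "synthetic center times": 3,
    "synthetic right-leaning herald": 4,
    "synthetic right wire": 5,
}
_SCORE_TO_OUTLET = {v: k for k, v in SYNTHETIC_OUTLETS.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification of a synthetic cohort.

    Per-edge quantities are keyed by canonical pair-column index. Effects are
    in rating-scale units (``direct_effects``), rating units per bias unit
    (``news_effects``), or bias units (``a_path``).
    """

    concepts: ConceptSet = field(default_factory=ConceptSet)
    n_per_group: int = 223
    seed: int = 0
    #: direct (not mediator-carried) group effect per edge, rating units
    direct_effects: Mapping[int, float] = field(default_factory=dict)
    #: mediator->rating slope per edge (the b path), rating units / bias unit
    news_effects: Mapping[int, float] = field(default_factory=dict)
    #: planted mediation class per edge: "partial" or "full"
    mediation_labels: Mapping[int, str] = field(default_factory=dict)
    #: group->mediator shift, bias units (group 1 mean minus group 0 mean)
    a_path: float = 0.0
    mediator_mean: float = 2.5
    mediator_sd: float = 0.4
    #: per-edge latent baseline mean rating (scalar or length-n_pairs array)
    baseline: float | np.ndarray = 0.0
    #: per-edge latent noise SD (scalar or length-n_pairs array)
    noise_sd: float | np.ndarray = 1.5
    #: covariate -> rating-units effect applied uniformly across edges
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    #: participants appended with only algorithm-driven sources (no bias score)
    n_unscorable: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        noise = np.asarray(self.noise_sd, dtype=float)
        if np.any(noise < 0):
            raise ValueError("noise_sd must be non-negative")
        for k, lab in self.mediation_labels.items():
            if lab not in ("partial", "full"):
                raise ValueError(f"mediation label {lab!r} for edge {k}")
            if lab == "partial" and k not in self.direct_effects:
                raise ValueError(f"partial mediation on edge {k} requires a direct effect")
            if lab == "full" and self.direct_effects.get(k, 0.0) != 0.0:
                raise ValueError(f"full mediation on edge {k} requires direct effect 0")
            if k not in self.news_effects:
                raise ValueError(f"mediated edge {k} requires a news (b-path) effect")

    @property
    def pair_index(self) -> PairIndex:
        return canonical_pair_index(self.concepts)

    def race_differing_edges(self) -> set[int]:
        """Edges with a planted group effect, direct or mediator-carried."""
        direct = {k for k, v in self.direct_effects.items() if v != 0.0}
        mediated = set(self.mediation_labels) if self.a_path != 0.0 else set()
        return direct | mediated

    def is_null(self) -> bool:
        return (
            not self.race_differing_edges()
            and not any(v != 0.0 for v in self.news_effects.values())
            and not any(v != 0.0 for v in self.covariate_effects.values())
        )


def _quantize_bias(m: np.ndarray) -> np.ndarray:
    """Snap mediator values to the grid of three-source integer-score means."""
    return np.round(np.clip(m, BIAS_MIN, BIAS_MAX) * 3.0) / 3.0


def _sources_for_bias(b: float) -> tuple[str, str, str]:
    s = int(round(b * 3))
    base, rem = divmod(s, 3)
    scores = [base + 1] * rem + [base] * (3 - rem)
    return tuple(_SCORE_TO_OUTLET[x] for x in scores)  # type: ignore[return-value]


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Draw a cohort from the generative model; bit-reproducible given seed."""
    if config.is_null() and np.all(np.asarray(config.noise_sd) == 0):
        warnings.warn("degenerate config: all effects and noise are zero", stacklevel=2)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pi = config.pair_index
    n_pairs = len(pi)
    n = 2 * config.n_per_group

    group = np.repeat([0, 1], config.n_per_group)
    gender = rng.integers(0, 2, size=n)
    income = rng.integers(0, 10, size=n)
    age = rng.integers(18, 76, size=n)

    m_latent = (
        config.mediator_mean
        + config.a_path * group
        + rng.normal(0.0, config.mediator_sd, size=n)
    )
    mediator = _quantize_bias(m_latent)

    baseline = np.broadcast_to(np.asarray(config.baseline, dtype=float), (n_pairs,))
    noise_sd = np.broadcast_to(np.asarray(config.noise_sd, dtype=float), (n_pairs,))
    direct = np.zeros(n_pairs)
    for k, v in config.direct_effects.items():
        direct[k] = v
    bpath = np.zeros(n_pairs)
    for k, v in config.news_effects.items():
        bpath[k] = v

    # population (pre-clipping) mediator mean; centering only moves intercepts
    m_center = config.mediator_mean + config.a_path * 0.5
    latent = (
        baseline[None, :]
        + np.outer(group, direct)
        + np.outer(mediator - m_center, bpath)
        + rng.normal(0.0, 1.0, size=(n, n_pairs)) * noise_sd[None, :]
    )
    for cov, eff in config.covariate_effects.items():
        if eff:
            vals = {"gender": gender, "income": income, "age": age}[cov]
            latent += np.outer(vals.astype(float), np.full(n_pairs, eff))
    ratings = np.clip(np.rint(latent), RATING_MIN, RATING_MAX).astype(np.int64)

    if config.n_unscorable:
        n_x = config.n_unscorable
        group = np.concatenate([group, rng.integers(0, 2, n_x)])
        gender = np.concatenate([gender, rng.integers(0, 2, n_x)])
        income = np.concatenate([income, rng.integers(0, 10, n_x)])
        age = np.concatenate([age, rng.integers(18, 76, n_x)])
        mediator = np.concatenate([mediator, np.full(n_x, np.nan)])
        extra = np.clip(
            np.rint(baseline[None, :] + rng.normal(0, 1, (n_x, n_pairs)) * noise_sd),
            RATING_MIN,
            RATING_MAX,
        ).astype(np.int64)
        ratings = np.vstack([ratings, extra])
        n += n_x

    pids = tuple(f"sim{idx:05d}" for idx in range(n))
    demo = pd.DataFrame(
        {
            "participant_id": pids,
            "race": group.astype(int),
            "gender": gender.astype(int),
            "income": income.astype(int),
            "age": age.astype(float),
        }
    )
    srcs = []
    for b in mediator:
        if np.isnan(b):
            srcs.append(("my social media feed", "video app algorithm", ""))
        else:
            srcs.append(_sources_for_bias(b))
    demo[["source1", "source2", "source3"]] = pd.DataFrame(srcs, index=demo.index)

    return Cohort(RatingMatrix(ratings, pids, pi), demo, mediator)


def synthetic_bias_lookup() -> BiasLookup:
    return BiasLookup(dict(SYNTHETIC_OUTLETS))


def write_simulated_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write ratings, demographics and the synthetic bias table as CSVs."""
    paths = write_cohort(cohort, out_dir)
    bias_path = Path(out_dir) / "bias.csv"
    pd.DataFrame(
        {"source": list(SYNTHETIC_OUTLETS), "bias": list(SYNTHETIC_OUTLETS.values())}
    ).to_csv(bias_path, index=False)
    paths["bias"] = bias_path
    return paths


# ---------------------------------------------------------------------------
# Named scenario presets
# ---------------------------------------------------------------------------

#: Structural layout RNG seed for the preset edge assignments. Fixed so the
#: *which-edges-carry-effects* layout is part of the scenario definition and
#: independent of the simulation seed that drives the noise draws.
_LAYOUT_SEED = 917

#: Planted counts for the reference scenario: 31 group-differing edges of
#: which 18 partially and 3 fully mediated, and 44 news-sensitive edges.
N_RACE_EDGES = 31
N_PARTIAL = 18
N_FULL = 3
N_NEWS_EDGES = 44


def _paper_like_layout(n_pairs: int = 120):
    rng = np.random.default_rng(_LAYOUT_SEED)
    order = rng.permutation(n_pairs)
    news_edges = np.sort(order[:N_NEWS_EDGES])
    mediated = rng.choice(news_edges, N_PARTIAL + N_FULL, replace=False)
    partial, full = mediated[:N_PARTIAL], mediated[N_PARTIAL:]
    non_news = np.sort(order[N_NEWS_EDGES:])
    race_only = rng.choice(non_news, N_RACE_EDGES - N_PARTIAL - N_FULL, replace=False)

    noise = np.empty(n_pairs)
    is_news = np.zeros(n_pairs, bool)
    is_news[news_edges] = True
    noise[is_news] = rng.uniform(1.8, 2.8, is_news.sum())
    noise[~is_news] = rng.uniform(0.7, 1.6, (~is_news).sum())
    baseline = rng.uniform(-3.5, 4.5, n_pairs)
    # a few strongly-bonded anchor pairs (joy-love style): extreme mean, tiny
    # spread, hence near-zero entropy and no news sensitivity
    anchors = rng.choice(non_news[~np.isin(non_news, race_only)], 5, replace=False)
    baseline[anchors] = 6.3
    noise[anchors] = 0.5
    return news_edges, partial, full, race_only, noise, baseline


def default_scenarios(n_per_group: int | None = None, seed: int = 0) -> dict[str, SimulationConfig]:
    """Named presets spanning null, group-only, mediated and reference designs.

    ``paper_like`` is the reference condition: 446 participants in two equal
    groups, a −0.48 bias-unit group shift on the mediator (SD 1.2 on the 1–5
    scale), 31 group-differing edges of which 18 are partially and 3 fully
    mediated, 44 news-sensitive edges whose slopes scale with the edge's
    latent noise, and heterogeneous per-edge noise giving a broad entropy
    spread. Direct effects are ±0.5 latent-noise SDs; mediated slopes are
    0.65 (partial) or 1.1 (full) latent SDs per bias unit, signed so the
    indirect path reinforces the direct one, and ±0.3 SDs on the
    news-only edges.
    """
    news_edges, partial, full, race_only, noise, baseline = _paper_like_layout()
    lay_rng = np.random.default_rng(_LAYOUT_SEED + 1)

    direct: dict[int, float] = {}
    news: dict[int, float] = {}
    labels: dict[int, str] = {}
    a_path = -0.48
    for k in partial:
        news[int(k)] = 0.65 * noise[k]
        direct[int(k)] = -0.5 * noise[k]  # same sign as a*b (a<0, b>0)
        labels[int(k)] = "partial"
    for k in full:
        news[int(k)] = 1.1 * noise[k]
        labels[int(k)] = "full"
    for k in news_edges:
        if int(k) not in news:
            # news-sensitive but not group-differing: slope kept small enough
            # that the induced indirect group effect stays undetectable
            news[int(k)] = float(lay_rng.choice([-0.3, 0.3])) * noise[k]
    for i, k in enumerate(race_only):
        direct[int(k)] = (0.5 if i % 2 == 0 else -0.5) * noise[k]

    paper_like = SimulationConfig(
        n_per_group=223,
        seed=seed,
        direct_effects=direct,
        news_effects=news,
        mediation_labels=labels,
        a_path=a_path,
        mediator_mean=2.52,  # group-0 mean; group 1 shifted by a_path
        mediator_sd=1.2,
        baseline=baseline,
        noise_sd=noise,
        covariate_effects={},
    )

    null = SimulationConfig(n_per_group=150, seed=seed, mediator_mean=2.5, mediator_sd=0.8)

    # diagnostic group-effect-only design: mediator present but independent of
    # group, so any full/partial label is a false positive of the screen
    race_only_cfg = SimulationConfig(
        n_per_group=223,
        seed=seed,
        direct_effects={int(k): (0.5 if i % 2 == 0 else -0.5) * 1.5
                        for i, k in enumerate(np.sort(np.concatenate([partial, full, race_only])))},
        a_path=0.0,
        mediator_mean=2.29,
        mediator_sd=1.2,
        noise_sd=1.5,
    )

    med_edges = np.sort(np.concatenate([partial, full]))[:10]
    fully_mediated = SimulationConfig(
        n_per_group=223,
        seed=seed,
        news_effects={int(k): 0.9 * 1.5 for k in med_edges},
        mediation_labels={int(k): "full" for k in med_edges},
        a_path=-0.6,
        mediator_mean=2.6,
        mediator_sd=1.0,
        noise_sd=1.5,
    )
    partially_mediated = SimulationConfig(
        n_per_group=223,
        seed=seed,
        direct_effects={int(k): -0.5 * 1.5 for k in med_edges},
        news_effects={int(k): 0.65 * 1.5 for k in med_edges},
        mediation_labels={int(k): "partial" for k in med_edges},
        a_path=-0.6,
        mediator_mean=2.6,
        mediator_sd=1.0,
        noise_sd=1.5,
    )

    scenarios = {
        "null": null,
        "race_only": race_only_cfg,
        "fully_mediated": fully_mediated,
        "partially_mediated": partially_mediated,
        "paper_like": paper_like,
    }
    if n_per_group is not None:
        scenarios = {k: replace(v, n_per_group=n_per_group) for k, v in scenarios.items()}
    return scenarios
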