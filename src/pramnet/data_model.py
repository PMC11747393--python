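"""Domain types and file I/O for pairwise concept-rating cohorts.

A study cohort consists of three tables:

* **ratings** — one integer (dis)similarity judgment in ``[-7, +7]`` per
  participant per unordered concept pair (``-7`` = opposites, ``0`` =
  unrelated, ``+7`` = strongly related);
* **demographics** — racial identity, gender, income bracket, age, and up
  to three self-reported news sources per participant;
* **bias lookup** — a user-supplied table mapping news-source names to a
  partisan-bias score on the 5-point scale Left (1) … Right (5).

A participant's news-bias score is the arithmetic mean of the bias scores
of their scorable sources; participants with no scorable source (e.g. only
algorithm-driven platforms) carry a missing score and are excluded from
analyses that require it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RATING_MIN: int = -7
RATING_MAX: int = 7
#: Number of discrete rating levels on the -7..+7 scale.
N_RATING_LEVELS: int = RATING_MAX - RATING_MIN + 1

#: The 16 socioenvironmental concepts of the default instrument.
DEFAULT_CONCEPTS: tuple[str, ...] = (
    "police",
    "firefighter",
    "your neighbors",
    "political conservatives",
    "political liberals",
    "healthcare",
    "voting",
    "immigration",
    "religion",
    "science",
    "anger",
    "fear",
    "joy",
    "love",
    "sadness",
    "trust",
)

BIAS_MIN: float = 1.0
BIAS_MAX: float = 5.0


class ValidationError(ValueError):
    """Raised when an input table violates the cohort data contract."""


@dataclass(frozen=True)
class ConceptSet:
    """Ordered set of concept labels defining the rating instrument."""

    labels: tuple[str, ...] = DEFAULT_CONCEPTS

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValidationError("a concept set needs at least 2 labels")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise ValidationError(f"duplicate concept labels: {dupes}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class PairIndex:
    """Canonical ordering of the n(n-1)/2 unordered concept pairs.

    Pairs are ordered lexicographically by ``(i, j)`` with ``i < j`` over the
    stated concept order, so the mapping from pair to column index is
    deterministic and stable across runs.
    """

    concepts: ConceptSet
    pairs: tuple[tuple[int, int], ...] = field(init=False)
    position: Mapping[tuple[int, int], int] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.concepts)
        pairs = tuple((i, j) for i in range(n) for j in range(i + 1, n))
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "position", {p: k for k, p in enumerate(pairs)})

    def __len__(self) -> int:
        return len(self.pairs)

    def labels(self, k: int) -> tuple[str, str]:
        i, j = self.pairs[k]
        return self.concepts.labels[i], self.concepts.labels[j]

    def pair_names(self) -> list[str]:
        return [f"{a}|{b}" for a, b in (self.labels(k) for k in range(len(self)))]

    def position_of(self, label_a: str, label_b: str) -> int:
        i = self.concepts.index(label_a)
        j = self.concepts.index(label_b)
        if i == j:
            raise ValidationError(f"self-pair {label_a!r}")
        if i > j:
            i, j = j, i
        return self.position[(i, j)]


def canonical_pair_index(concepts: ConceptSet | Sequence[str]) -> PairIndex:
    """Build the canonical pair index for a concept set.

    For the default 16-concept instrument this yields the 120 pairs on which
    every participant is rated.
    """
    if not isinstance(concepts, ConceptSet):
        concepts = ConceptSet(tuple(concepts))
    return PairIndex(concepts)


@dataclass(frozen=True)
class RatingMatrix:
    """Participants x pairs integer similarity ratings in ``[-7, +7]``."""

    values: np.ndarray
    participant_ids: tuple[str, ...]
    pair_index: PairIndex

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValidationError("rating matrix must be 2-D")
        if v.shape[0] != len(self.participant_ids):
            raise ValidationError(
                f"{v.shape[0]} rating rows but {len(self.participant_ids)} participant ids"
            )
        if v.shape[1] != len(self.pair_index):
            raise ValidationError(
                f"{v.shape[1]} rating columns but pair index has {len(self.pair_index)}"
            )
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(np.equal(np.mod(v, 1), 0)):
                bad = np.argwhere(np.mod(v, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer rating at participant row {bad[0]}, pair column {bad[1]}"
                )
            v = v.astype(np.int64)
        if v.size and (v.min() < RATING_MIN or v.max() > RATING_MAX):
            bad = np.argwhere((v < RATING_MIN) | (v > RATING_MAX))[0]
            pid = self.participant_ids[bad[0]]
            a, b = self.pair_index.labels(bad[1])
            raise ValidationError(
                f"rating {v[bad[0], bad[1]]} out of [-7, 7] for participant "
                f"{pid!r}, pair {a!r}|{b!r}"
            )
        object.__setattr__(self, "values", np.ascontiguousarray(v, dtype=np.int64))

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BiasLookup:
    """Mapping from normalized news-source name to bias score in {1..5}."""

    scores: Mapping[str, float]

    @staticmethod
    def normalize(name: str) -> str:
        return " ".join(name.strip().lower().split())

    def __post_init__(self) -> None:
        norm: dict[str, float] = {}
        for name, score in self.scores.items():
            key = self.normalize(name)
            if key in norm and norm[key] != float(score):
                raise ValidationError(f"conflicting bias scores for source {key!r}")
            s = float(score)
            if not (BIAS_MIN <= s <= BIAS_MAX):
                raise ValidationError(f"bias score {s} for {key!r} outside [1, 5]")
            norm[key] = s
        object.__setattr__(self, "scores", norm)

    def get(self, name: str) -> float | None:
        return self.scores.get(self.normalize(name))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiasLookup":
        df = pd.read_csv(path)
        _require_columns(df, ["source", "bias"], path)
        return cls(dict(zip(df["source"].astype(str), df["bias"].astype(float))))


def compute_news_bias(
    sources: Iterable[str],
    lookup: BiasLookup,
    *,
    require_all: bool = False,
) -> float:
    """Mean bias score of a participant's scorable news sources.

    Returns ``nan`` when no source can be scored (the participant is then
    excluded from news analyses), or — under ``require_all=True`` — when any
    listed source is missing from the lookup.
    """
    names = [s for s in sources if isinstance(s, str) and s.strip()]
    if not names:
        logger.debug("participant listed no news sources; bias marked missing")
        return math.nan
    scores = [lookup.get(s) for s in names]
    found = [s for s in scores if s is not None]
    if not found or (require_all and len(found) < len(names)):
        logger.debug("no scorable sources among %r; bias marked missing", names)
        return math.nan
    return float(np.mean(found))


DEMOGRAPHIC_COLUMNS = [
    "participant_id",
    "race",
    "gender",
    "income_bracket",
    "age",
    "source1",
    "source2",
    "source3",
]

#: Category strings coded 1 for the race indicator (Black / African American = 1).
RACE_POSITIVE = {"black", "black / african american", "african american"}
#: Category strings coded 1 for the gender indicator (Female = 1).
GENDER_POSITIVE = {"female", "woman", "f"}


@dataclass(frozen=True)
class Cohort:
    """Row-aligned ratings + demographics + per-participant news bias.

    ``demographics`` columns: ``race`` (1 = Black/African American),
    ``gender`` (1 = Female), ``income`` (ordinal bracket rank), ``age``
    (years), plus the raw source names. ``news_bias`` is the mean source
    bias in [1, 5], ``nan`` when unscorable.
    """

    ratings: RatingMatrix
    demographics: pd.DataFrame
    news_bias: np.ndarray

    def __post_init__(self) -> None:
        n = self.ratings.n_participants
        if len(self.demographics) != n or len(self.news_bias) != n:
            raise ValidationError("ratings, demographics and news_bias must be row-aligned")
        for col in ("race", "gender", "income", "age"):
            if col not in self.demographics.columns:
                raise ValidationError(f"demographics missing column {col!r}")
        object.__setattr__(
            self, "news_bias", np.asarray(self.news_bias, dtype=float)
        )

    @property
    def n_participants(self) -> int:
        return self.ratings.n_participants

    @property
    def pair_index(self) -> PairIndex:
        return self.ratings.pair_index

    @property
    def concepts(self) -> ConceptSet:
        return self.ratings.pair_index.concepts

    def scored_mask(self) -> np.ndarray:
        """Participants with a defined news-bias score and full demographics."""
        demo_ok = (
            self.demographics[["race", "gender", "income", "age"]].notna().all(axis=1)
        ).to_numpy()
        return demo_ok & ~np.isnan(self.news_bias)

    def n_scored(self) -> int:
        return int(self.scored_mask().sum())


# ---------------------------------------------------------------------------
# CSV ingestion / export
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _ratings_from_long(df: pd.DataFrame, pair_index: PairIndex, path) -> RatingMatrix:
    labels = set(pair_index.concepts.labels)
    for col in ("concept_a", "concept_b"):
        unknown = set(df[col].astype(str)) - labels
        if unknown:
            raise ValidationError(f"{path}: unknown concept labels {sorted(unknown)}")
    pids = sorted(df["participant_id"].astype(str).unique())
    pid_row = {p: r for r, p in enumerate(pids)}
    values = np.full((len(pids), len(pair_index)), np.iinfo(np.int64).min, dtype=np.int64)
    label_pos = {
        (a, b): k
        for k in range(len(pair_index))
        for a, b in (pair_index.labels(k), pair_index.labels(k)[::-1])
    }
    keys = list(zip(df["concept_a"].astype(str), df["concept_b"].astype(str)))
    try:
        cols = np.array([label_pos[k] for k in keys])
    except KeyError as exc:
        raise ValidationError(f"{path}: self-paired or unknown concept pair {exc}") from exc
    rows = df["participant_id"].astype(str).map(pid_row).to_numpy()
    ratings = df["rating"].to_numpy()
    if not np.all(np.equal(np.mod(ratings, 1), 0)):
        bad = int(np.argwhere(np.mod(ratings, 1) != 0)[0][0])
        raise ValidationError(f"{path}: non-integer rating in row {bad}")
    values[rows, cols] = ratings.astype(np.int64)
    if (values == np.iinfo(np.int64).min).any():
        r, c = np.argwhere(values == np.iinfo(np.int64).min)[0]
        a, b = pair_index.labels(c)
        raise ValidationError(
            f"{path}: participant {pids[r]!r} has no rating for pair {a!r}|{b!r}"
        )
    return RatingMatrix(values, tuple(pids), pair_index)


def _ratings_from_wide(df: pd.DataFrame, pair_index: PairIndex, path) -> RatingMatrix:
    names = pair_index.pair_names()
    _require_columns(df, ["participant_id", *names], path)
    df = df.sort_values("participant_id")
    return RatingMatrix(
        df[names].to_numpy(),
        tuple(df["participant_id"].astype(str)),
        pair_index,
    )


def load_ratings(
    path: str | Path, pair_index: PairIndex | None = None
) -> RatingMatrix:
    """Read a ratings CSV (long form canonical; wide form accepted)."""
    if pair_index is None:
        pair_index = canonical_pair_index(ConceptSet())
    df = pd.read_csv(path)
    if {"participant_id", "concept_a", "concept_b", "rating"} <= set(df.columns):
        return _ratings_from_long(df, pair_index, path)
    return _ratings_from_wide(df, pair_index, path)


def _code_indicator(series: pd.Series, positive: set[str], name: str) -> pd.Series:
    def code(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, (int, float, np.integer, np.floating)):
            if v in (0, 1):
                return int(v)
            raise ValidationError(f"{name} indicator must be 0/1 or a category string, got {v!r}")
        return int(str(v).strip().lower() in positive)

    return series.map(code)


def load_cohort(
    ratings_path: str | Path,
    demographics_path: str | Path,
    bias_path: str | Path,
    *,
    pair_index: PairIndex | None = None,
    require_three_sources: bool = False,
) -> Cohort:
    """Load and validate the three cohort tables into a row-aligned `Cohort`.

    Participants present in the ratings table but absent from demographics
    (or vice versa) raise a validation error naming the offending ids.
    Exclusion counts (unscorable news sources, missing demographics) are
    logged; those participants stay in the cohort and are dropped only by
    analyses that need the missing fields.
    """
    ratings = load_ratings(ratings_path, pair_index)
    demo = pd.read_csv(demographics_path)
    _require_columns(demo, DEMOGRAPHIC_COLUMNS[:5], demographics_path)
    demo["participant_id"] = demo["participant_id"].astype(str)
    rated = set(ratings.participant_ids)
    present = set(demo["participant_id"])
    if rated != present:
        raise ValidationError(
            f"participant mismatch between ratings and demographics: "
            f"only-rated={sorted(rated - present)[:5]}, "
            f"only-demographics={sorted(present - rated)[:5]}"
        )
    demo = demo.set_index("participant_id").loc[list(ratings.participant_ids)].reset_index()
    out = pd.DataFrame({"participant_id": demo["participant_id"]})
    out["race"] = _code_indicator(demo["race"], RACE_POSITIVE, "race")
    out["gender"] = _code_indicator(demo["gender"], GENDER_POSITIVE, "gender")
    out["income"] = pd.to_numeric(demo["income_bracket"], errors="raise")
    if (out["income"].dropna() < 0).any():
        raise ValidationError("income bracket ranks must be >= 0")
    out["age"] = pd.to_numeric(demo["age"], errors="raise")
    if (out["age"].dropna() <= 0).any():
        raise ValidationError("ages must be positive")
    for col in ("source1", "source2", "source3"):
        out[col] = demo[col] if col in demo.columns else np.nan

    lookup = BiasLookup.from_csv(bias_path)
    bias = np.array(
        [
            compute_news_bias(
                [row.source1, row.source2, row.source3],
                lookup,
                require_all=require_three_sources,
            )
            for row in out.itertuples()
        ]
    )
    n_unscorable = int(np.isnan(bias).sum())
    if n_unscorable:
        logger.info(
            "%d of %d participants have no scorable news sources; "
            "excluded from news-bias analyses",
            n_unscorable,
            len(out),
        )
    return Cohort(ratings, out, bias)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical three-CSV representation (long-form ratings).

    The bias table written contains one row per distinct source name seen in
    the demographics, scored from the cohort's news-bias values only when the
    cohort was simulated with the built-in synthetic outlets; for loaded
    cohorts pass the original bias table alongside instead.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pi = cohort.pair_index
    n_pairs = len(pi)
    pids = np.repeat(cohort.ratings.participant_ids, n_pairs)
    names = [pi.labels(k) for k in range(n_pairs)]
    a = np.tile([x for x, _ in names], cohort.n_participants)
    b = np.tile([y for _, y in names], cohort.n_participants)
    ratings_df = pd.DataFrame(
        {
            "participant_id": pids,
            "concept_a": a,
            "concept_b": b,
            "rating": cohort.ratings.values.ravel(),
        }
    )
    ratings_path = out_dir / "ratings.csv"
    ratings_df.to_csv(ratings_path, index=False)

    demo = cohort.demographics.copy()
    demo = demo.rename(columns={"income": "income_bracket"})
    cols = [c for c in DEMOGRAPHIC_COLUMNS if c in demo.columns]
    demo_path = out_dir / "demographics.csv"
    demo[cols].to_csv(demo_path, index=False)
    return {"ratings": ratings_path, "demographics": demo_path}
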