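"""Cleaning chain, sleep-disturbance filter, train/test split and the
numeric feature matrix.

The cleaning chain is order-faithful to the study's flow: (1) respondents
with multiple submissions are eliminated entirely, (2) respondents failing
the inclusion criteria (age >= 19, eligible enlisted rank, consent) or with
any missing required item are removed — no imputation — then (3) rows with
out-of-range open-question values (height, weight, smoking amount and
duration) are dropped.  After scoring, only respondents with a PSQI global
score strictly above 5 are retained, and the remaining table is randomly
split 80/20 (train size floored).

The clustering input contains the raw questionnaire responses of every
section — including the items of the four scored instruments — but never
the *derived* scores themselves: the PSQI/Berlin/NQ/GSRS scores serve as
external validation and are non-linear functions of the items that the
feature extractor is not given.  Setting
``include_scored_instrument_items=False`` switches to the stricter reading
in which the scored instruments' raw items are withheld as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .synthetic import COLUMNS, RANKS, SECTIONS

logger = logging.getLogger(__name__)

#: Sections whose raw items feed the clustering input by default.
DEFAULT_FEATURE_SECTIONS = ("demographics", "medical", "military", "sleep_env", "diet", "bss")

#: Sections belonging to the four externally-validated instruments.
SCORED_INSTRUMENT_SECTIONS = ("psqi", "berlin", "nq", "gsrs")

#: Item columns a complete response must answer (everything but id/label).
REQUIRED_COLUMNS = tuple(
    c.name for c in COLUMNS if c.section != "id" or c.name == "consent"
)

ELIGIBLE_RANKS = frozenset(RANKS)


@dataclass(frozen=True)
class OutlierBounds:
    """Strict plausibility bounds on the open-question fields."""

    height_min: float = 110.0
    height_max: float = 200.0
    weight_min: float = 40.0
    weight_max: float = 160.0
    packs_per_day_max: float = 5.0
    smoking_years_max: float = 20.0


# ---------------------------------------------------------------------------
# Cleaning stages
# ---------------------------------------------------------------------------


def deduplicate(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove every row of any respondent id that appears more than once.

    Multiple submissions make a respondent unreliable, so all their rows are
    eliminated, not just the surplus copies.
    """
    counts = table["respondent_id"].value_counts()
    bad = counts.index[counts > 1]
    keep = ~table["respondent_id"].isin(bad)
    return table.loc[keep].copy(), int((~keep).sum())


def apply_inclusion_and_completeness(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep eligible (age >= 19, eligible rank, consenting) complete rows."""
    age = pd.to_numeric(table["age"], errors="coerce")
    eligible = (
        (age >= 19)
        & table["rank"].isin(ELIGIBLE_RANKS)
        & table["consent"].astype(bool)
    )
    present = [c for c in REQUIRED_COLUMNS if c in table.columns]
    complete = table[present].notna().all(axis=1)
    kept = table.loc[eligible & complete].copy()
    counts = {
        "ineligible_removed": int((~eligible).sum()),
        "incomplete_removed": int((eligible & ~complete).sum()),
    }
    return kept, counts


def remove_outliers(
    table: pd.DataFrame, bounds: OutlierBounds = OutlierBounds()
) -> tuple[pd.DataFrame, int]:
    """Drop rows violating any plausibility bound (strict inequalities)."""
    if table.empty:
        return table.copy(), 0
    h = pd.to_numeric(table["height_cm"], errors="coerce")
    w = pd.to_numeric(table["weight_kg"], errors="coerce")
    p = pd.to_numeric(table["smoking_packs_per_day"], errors="coerce")
    y = pd.to_numeric(table["smoking_years"], errors="coerce")
    bad = (
        (h < bounds.height_min)
        | (h > bounds.height_max)
        | (w < bounds.weight_min)
        | (w > bounds.weight_max)
        | (p > bounds.packs_per_day_max)
        | (y > bounds.smoking_years_max)
    )
    return table.loc[~bad].copy(), int(bad.sum())


def filter_sleep_disturbed(scored: pd.DataFrame) -> pd.DataFrame:
    """Keep respondents with a PSQI global score strictly above 5."""
    return scored.loc[pd.to_numeric(scored["psqi_global"], errors="coerce") > 5].copy()


def clean(
    table: pd.DataFrame, bounds: OutlierBounds = OutlierBounds()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the pre-scoring cleaning chain, logging per-stage counts."""
    counts: dict[str, int] = {"input_rows": len(table)}
    table, counts["duplicates_removed"] = deduplicate(table)
    table, inc = apply_inclusion_and_completeness(table)
    counts.update(inc)
    table, counts["outliers_removed"] = remove_outliers(table, bounds)
    counts["remaining"] = len(table)
    assert counts["input_rows"] == counts["remaining"] + counts["duplicates_removed"] + \
        counts["ineligible_removed"] + counts["incomplete_removed"] + counts["outliers_removed"]
    for stage, n in counts.items():
        logger.info("cleaning stage %s: %d", stage, n)
    return table, counts


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitResult:
    train_ids: tuple
    test_ids: tuple
    fraction: float
    seed: int


def split(table: pd.DataFrame, fraction: float = 0.8, seed: int = 0) -> SplitResult:
    """Uniformly random partition; train size = floor(fraction * n)."""
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must lie in (0, 1]")
    ids = np.asarray(table["respondent_id"], dtype=object)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(fraction * len(ids)))
    return SplitResult(
        train_ids=tuple(ids[order[:n_train]]),
        test_ids=tuple(ids[order[n_train:]]),
        fraction=fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Encoded, standardised input matrix with its fitted scaler state."""

    X: np.ndarray
    columns: tuple  # encoded column names
    row_ids: tuple
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray

    @property
    def d(self) -> int:
        return self.X.shape[1]


def default_schema(include_scored_instrument_items: bool = True):
    """Per-column encoding plan: ``(name, encoding, levels)`` triples.

    Nominal items are one-hot expanded over their declared level set;
    numeric, ordinal and flag items are standardised as single columns.
    """
    sections = list(DEFAULT_FEATURE_SECTIONS)
    if include_scored_instrument_items:
        sections += list(SCORED_INSTRUMENT_SECTIONS)
    schema = []
    for spec in COLUMNS:
        if spec.section not in sections:
            continue
        if spec.kind == "nominal":
            schema.append((spec.name, "onehot", tuple(spec.levels)))
        else:
            schema.append((spec.name, "numeric", ()))
    return schema


def _encode(table: pd.DataFrame, schema) -> tuple[np.ndarray, tuple]:
    blocks, names = [], []
    for name, encoding, levels in schema:
        col = table[name]
        if encoding == "numeric":
            blocks.append(pd.to_numeric(col, errors="coerce").to_numpy(float)[:, None])
            names.append(name)
        elif encoding == "onehot":
            values = col.to_numpy(object)
            unseen = set(values) - set(levels)
            if unseen:
                logger.warning(
                    "column %s: unseen levels %s mapped to all-zero block", name, sorted(unseen)
                )
            block = np.stack([(values == lv).astype(float) for lv in levels], axis=1)
            blocks.append(block)
            names.extend(f"{name}={lv}" for lv in levels)
        else:
            raise ConfigurationError(f"unknown encoding '{encoding}' for column {name}")
    return np.hstack(blocks), tuple(names)


def build_feature_matrix(
    scored: pd.DataFrame,
    split_result: SplitResult,
    schema=None,
    include_scored_instrument_items: bool = True,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Encode and standardise the clustering input for both partitions.

    The location/scale of every encoded column is fitted on the training
    rows only and applied unchanged to the test rows (no leakage).
    """
    if schema is None:
        schema = default_schema(include_scored_instrument_items)
    indexed = scored.set_index("respondent_id", drop=False)
    train = indexed.loc[list(split_result.train_ids)]
    test = indexed.loc[list(split_result.test_ids)]

    X_train, names = _encode(train, schema)
    if np.isnan(X_train).any():
        raise ConfigurationError("feature matrix contains missing entries; clean the table first")
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)
    scale[scale == 0.0] = 1.0  # constant columns pass through centred

    def finalize(X, ids):
        return FeatureMatrix(
            X=(X - mean) / scale,
            columns=names,
            row_ids=tuple(ids),
            scaler_mean=mean.copy(),
            scaler_scale=scale.copy(),
        )

    fm_train = finalize(X_train, split_result.train_ids)
    if len(test):
        X_test, _ = _encode(test, schema)
        fm_test = finalize(X_test, split_result.test_ids)
    else:
        fm_test = finalize(np.empty((0, X_train.shape[1])), ())
    return fm_train, fm_test
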