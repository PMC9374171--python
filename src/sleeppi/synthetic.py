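"""Synthetic survey-population generator.

The study this package models analysed an anonymous electronic survey of
army service members (six sections: demographics, medical history, military
duty, sleep, diet/nutrition, gastrointestinal status), but the raw responses
were never deposited.  This module generates item-level survey tables with a
configurable latent three-cluster structure so every downstream stage —
instrument scoring, the cleaning chain, feature extraction, clustering and
external validation — can be exercised and tested end to end.

Generation is *score-first*: per-cluster instrument totals (GSRS, PSQI
global, the four nutrition-quotient factor scores) are drawn from truncated
normals whose location is calibrated so the truncated mean equals the
configured target, and item vectors are then sampled under the constraint
that the scoring module reproduces that total exactly.  Cluster-informative
signal is also placed in the *unscored* sections (dietary habits, sleeping
environment, stool form, medical-history flags, military duty) because those
are the columns that feed the clustering input matrix.

A single ``separation`` scalar interpolates every cluster profile toward the
population grand mean (0 = clusters indistinguishable, 1 = configured
profiles), so recovery tests can sweep difficulty.

The raw-item distributions are stand-ins: the study reports cluster-level
score summaries, not item distributions, so anything below the instrument
totals is this module's own modelling choice.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# Data dictionary
# ---------------------------------------------------------------------------

#: Section order; "trailing-section" incompleteness blanks a suffix of this.
SECTIONS = (
    "id",
    "demographics",
    "medical",
    "military",
    "psqi",
    "berlin",
    "sleep_env",
    "diet",
    "nq",
    "gsrs",
    "bss",
)


@dataclass(frozen=True)
class ColumnSpec:
    """One entry of the machine-readable data dictionary."""

    name: str
    section: str
    kind: str  # id | label | flag | numeric | ordinal | nominal
    levels: tuple = ()


def _ordinal(name, section, lo, hi):
    return ColumnSpec(name, section, "ordinal", tuple(range(lo, hi + 1)))


RANKS = ("private", "private_first_class", "corporal", "sergeant")
EDUCATION = ("middle_school", "high_school", "university")
SMOKING = ("never", "past", "active")
BRANCHES = ("combat", "support", "administration")

PSQI_DISTURBANCE_ITEMS = tuple(f"psqi_q5{c}" for c in "bcdefghij")
BERLIN_CAT1_ITEMS = tuple(f"berlin_c1_{i}" for i in range(1, 6))
BERLIN_CAT2_ITEMS = tuple(f"berlin_c2_{i}" for i in range(1, 5))
DIET_ITEMS = tuple(f"diet_q{i:02d}" for i in range(1, 26))
NQ_ITEMS = tuple(f"nq_q{i:02d}" for i in range(1, 22))
GSRS_ITEMS = tuple(f"gsrs_q{i:02d}" for i in range(1, 16))

COLUMNS: tuple[ColumnSpec, ...] = (
    ColumnSpec("respondent_id", "id", "id"),
    ColumnSpec("true_cluster", "id", "label"),
    ColumnSpec("consent", "id", "flag"),
    # demographics -----------------------------------------------------------
    ColumnSpec("age", "demographics", "numeric"),
    ColumnSpec("height_cm", "demographics", "numeric"),
    ColumnSpec("weight_kg", "demographics", "numeric"),
    ColumnSpec("rank", "demographics", "nominal", RANKS),
    ColumnSpec("education", "demographics", "nominal", EDUCATION),
    ColumnSpec("smoking_status", "demographics", "nominal", SMOKING),
    ColumnSpec("smoking_packs_per_day", "demographics", "numeric"),
    ColumnSpec("smoking_years", "demographics", "numeric"),
    _ordinal("alcohol_freq", "demographics", 0, 3),
    _ordinal("coffee_freq", "demographics", 0, 5),
    _ordinal("energy_drink_freq", "demographics", 0, 5),
    _ordinal("exercise_freq", "demographics", 0, 3),
    _ordinal("physical_grade", "demographics", 1, 5),
    # medical history --------------------------------------------------------
    ColumnSpec("hist_sleep_disorder", "medical", "flag"),
    ColumnSpec("hist_gi_disorder", "medical", "flag"),
    ColumnSpec("hist_hypertension", "medical", "flag"),
    ColumnSpec("hist_general_disease", "medical", "flag"),
    _ordinal("stress", "medical", 1, 5),
    # military duty ----------------------------------------------------------
    ColumnSpec("duty_branch", "military", "nominal", BRANCHES),
    _ordinal("night_shift_dutyoff_freq", "military", 0, 5),
    _ordinal("night_shift_no_dutyoff_freq", "military", 0, 5),
    _ordinal("night_shift_sleep_impact", "military", 1, 5),
    _ordinal("duty_stress", "military", 1, 5),
    # PSQI (the two clock-time items are pre-combined into time in bed) ------
    ColumnSpec("psqi_latency_min", "psqi", "numeric"),
    ColumnSpec("psqi_sleep_hours", "psqi", "numeric"),
    ColumnSpec("psqi_bed_hours", "psqi", "numeric"),
    _ordinal("psqi_q5a", "psqi", 0, 3),
    *[_ordinal(n, "psqi", 0, 3) for n in PSQI_DISTURBANCE_ITEMS],
    _ordinal("psqi_quality", "psqi", 0, 3),
    _ordinal("psqi_medication", "psqi", 0, 3),
    _ordinal("psqi_daysleepy", "psqi", 0, 3),
    _ordinal("psqi_enthusiasm", "psqi", 0, 3),
    # Berlin -----------------------------------------------------------------
    *[ColumnSpec(n, "berlin", "flag") for n in BERLIN_CAT1_ITEMS],
    *[ColumnSpec(n, "berlin", "flag") for n in BERLIN_CAT2_ITEMS],
    ColumnSpec("berlin_c2_drive", "berlin", "flag"),
    # sleeping environment ---------------------------------------------------
    _ordinal("env_noise", "sleep_env", 1, 5),
    _ordinal("env_light", "sleep_env", 1, 5),
    _ordinal("env_temperature", "sleep_env", 1, 5),
    _ordinal("env_crowding", "sleep_env", 1, 5),
    # dietary habits ---------------------------------------------------------
    *[_ordinal(n, "diet", 1, 5) for n in DIET_ITEMS],
    # nutrition quotient -----------------------------------------------------
    *[_ordinal(n, "nq", 1, 5) for n in NQ_ITEMS],
    # GSRS -------------------------------------------------------------------
    *[_ordinal(n, "gsrs", 1, 7) for n in GSRS_ITEMS],
    # Bristol stool scale ----------------------------------------------------
    _ordinal("bss", "bss", 1, 7),
)

COLUMN_NAMES = tuple(c.name for c in COLUMNS)
_BY_SECTION = {s: tuple(c.name for c in COLUMNS if c.section == s) for s in SECTIONS}


def data_dictionary() -> pd.DataFrame:
    """The column dictionary (name, section, type, level set) as a table."""
    return pd.DataFrame(
        {
            "column": [c.name for c in COLUMNS],
            "section": [c.section for c in COLUMNS],
            "type": [c.kind for c in COLUMNS],
            "levels": ["|".join(map(str, c.levels)) for c in COLUMNS],
        }
    )


# ---------------------------------------------------------------------------
# Cluster profiles and configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterProfile:
    """Target distributions for one latent cluster.

    Score targets (GSRS total, PSQI global, NQ factors) are the quantities the
    scoring module must reproduce in expectation; everything else shapes the
    unscored sections that feed the clustering input.
    """

    name: str
    gsrs: tuple[float, float]          # mean, SD of the 0-90 total
    psqi: tuple[float, float]          # mean, SD of the 0-21 global
    berlin_high_p: float               # P(high OSA risk)
    nq_balance: tuple[float, float]    # factor score, 0-70
    nq_diversity: tuple[float, float]  # 0-25
    nq_moderation: tuple[float, float]  # 0-25
    nq_behavior: tuple[float, float]   # 0-20
    age: tuple[float, float]
    height: tuple[float, float]
    weight: tuple[float, float]
    smoking_p: tuple[float, float, float]  # never, past, active
    hist_p: tuple[float, float, float, float]  # sleep, GI, hypertension, general
    stress_mean: float
    night_shift_means: tuple[float, float]
    night_impact_mean: float
    severity: float                    # position on the latent unwellness axis


# Defaults follow the published per-cluster summaries (training partition):
# cluster A = mild sleep disturbance / good GI status, B = severe GI symptoms,
# C = intermediate.  The clusters sit at ordered positions on one latent
# "unwellness" axis (see `severity` and the generator below); quantities the
# study does not report (BSS, sleeping environment, dietary-item levels) are
# stand-ins aligned with that narrative.
DEFAULT_PROFILES: tuple[ClusterProfile, ...] = (
    ClusterProfile(
        name="A",
        gsrs=(2.18, 2.15), psqi=(8.33, 2.20), berlin_high_p=166 / 1396,
        nq_balance=(35.44, 14.33), nq_diversity=(12.67, 4.21),
        nq_moderation=(8.65, 4.18), nq_behavior=(11.38, 3.46),
        age=(20.8, 1.2), height=(174.6, 5.6), weight=(72.2, 9.2),
        smoking_p=(0.53, 0.06, 0.41),
        hist_p=(0.064, 0.042, 0.047, 0.053),
        stress_mean=3.46, night_shift_means=(2.0, 2.4),
        night_impact_mean=4.07,
        severity=0.0,
    ),
    ClusterProfile(
        name="B",
        gsrs=(17.94, 7.38), psqi=(11.57, 3.31), berlin_high_p=35 / 98,
        nq_balance=(33.25, 15.37), nq_diversity=(11.95, 4.54),
        nq_moderation=(12.90, 5.85), nq_behavior=(9.67, 3.74),
        age=(21.2, 1.6), height=(175.2, 6.0), weight=(75.1, 11.1),
        smoking_p=(0.54, 0.04, 0.42),
        hist_p=(0.337, 0.316, 0.122, 0.133),
        stress_mean=3.41, night_shift_means=(2.3, 2.7),
        night_impact_mean=4.43,
        severity=3.8,
    ),
    ClusterProfile(
        name="C",
        gsrs=(6.39, 4.09), psqi=(9.96, 2.81), berlin_high_p=178 / 569,
        nq_balance=(33.24, 16.73), nq_diversity=(12.83, 4.55),
        nq_moderation=(11.12, 4.91), nq_behavior=(9.90, 3.66),
        age=(21.1, 1.4), height=(174.8, 5.6), weight=(73.8, 11.1),
        smoking_p=(0.43, 0.08, 0.49),
        hist_p=(0.174, 0.144, 0.060, 0.074),
        stress_mean=3.40, night_shift_means=(2.0, 2.4),
        night_impact_mean=4.25,
        severity=1.8,
    ),
)

#: Training-partition cluster sizes 1,396 / 98 / 569, normalised.
DEFAULT_WEIGHTS = (1396 / 2063, 98 / 2063, 569 / 2063)


@dataclass(frozen=True)
class ArtifactRates:
    """Rates of deliberately injected data-quality defects."""

    duplicate_rate: float = 0.007
    incomplete_rate: float = 0.028
    outlier_rate: float = 0.004


@dataclass(frozen=True)
class SyntheticConfig:
    n_respondents: int = 4869
    cluster_weights: tuple[float, ...] = DEFAULT_WEIGHTS
    profiles: tuple[ClusterProfile, ...] = DEFAULT_PROFILES
    separation: float = 1.0
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_respondents < 0:
            raise ConfigurationError("n_respondents must be >= 0")
        w = np.asarray(self.cluster_weights, dtype=float)
        if (w < 0).any():
            raise ConfigurationError("cluster_weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("cluster_weights must sum to 1 within 1e-9")
        if len(self.profiles) != len(w):
            raise ConfigurationError("cluster_weights length must match profiles")
        for fname in ("duplicate_rate", "incomplete_rate", "outlier_rate"):
            r = getattr(self.artifact_rates, fname)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{fname} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _calibrated_loc(target: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal whose *truncated* mean equals target."""

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    span = hi - lo
    return optimize.brentq(
        lambda loc: trunc_mean(loc) - target, lo - 3 * sd - span, hi + 3 * sd + span
    )


def _trunc_normal(rng, mean, sd, lo, hi, size):
    loc = _calibrated_loc(round(mean, 6), round(sd, 6), lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _trunc_normal_corr(rng, mean, sd, lo, hi, latent, corr):
    """Calibrated truncated normal partially driven by a standard-normal latent.

    The marginal is the same calibrated truncated normal as
    :func:`_trunc_normal` (so cluster score targets are preserved exactly),
    but the draw is the quantile transform of ``corr * latent`` plus
    independent noise, which correlates the score with the shared severity
    latent.
    """
    u = corr * latent + math.sqrt(max(1.0 - corr**2, 0.0)) * rng.normal(size=latent.size)
    loc = _calibrated_loc(round(mean, 6), round(sd, 6), lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.ppf(
        np.clip(stats.norm.cdf(u), 1e-12, 1 - 1e-12), a, b, loc=loc, scale=sd
    )


def _likert(rng, mean, sd, lo, hi, size):
    """Clipped, rounded normal draw on an integer Likert range."""
    return np.clip(np.rint(rng.normal(mean, sd, size)), lo, hi).astype(int)


def _allocate(rng, total: int, n_items: int, cap: int) -> np.ndarray:
    """Uniform bounded composition: split `total` over items, each <= cap.

    Sampled by choosing `total` of the n_items*cap unit slots without
    replacement, which yields a random composition respecting the caps.
    """
    total = int(np.clip(total, 0, n_items * cap))
    if total == 0:
        return np.zeros(n_items, dtype=int)
    slots = rng.choice(n_items * cap, size=total, replace=False)
    return np.bincount(slots // cap, minlength=n_items)


def _interpolate(value, grand, separation):
    return grand + separation * (np.asarray(value, dtype=float) - grand)


def _blend_profiles(profiles, weights, separation):
    """Pull every profile toward the weight-averaged grand profile."""
    if separation == 1.0:
        return profiles
    w = np.asarray(weights, dtype=float)

    def grand(attr, idx=None):
        vals = [getattr(p, attr) if idx is None else getattr(p, attr)[idx] for p in profiles]
        return float(np.average(np.asarray(vals, dtype=float), axis=0, weights=w)) \
            if np.ndim(vals[0]) == 0 else np.average(np.asarray(vals, dtype=float), axis=0, weights=w)

    blended = []
    for p in profiles:
        kw = {}
        for attr in (
            "gsrs", "psqi", "nq_balance", "nq_diversity", "nq_moderation",
            "nq_behavior", "age", "height", "weight",
        ):
            mean, sd = getattr(p, attr)
            kw[attr] = (float(_interpolate(mean, grand(attr, 0), separation)), sd)
        for attr in ("berlin_high_p", "stress_mean", "night_impact_mean", "severity"):
            kw[attr] = float(_interpolate(getattr(p, attr), grand(attr), separation))
        for attr in ("smoking_p", "hist_p", "night_shift_means"):
            kw[attr] = tuple(_interpolate(getattr(p, attr), grand(attr), separation))
        blended.append(replace(p, **kw))
    return tuple(blended)


# ---------------------------------------------------------------------------
# Item-level realisation of the scored instruments
# ---------------------------------------------------------------------------


def _allocate_proportional(rng, total: int, n_items: int, cap: int, noise: float) -> np.ndarray:
    """Composition of `total` proportional to capacity with mild jitter.

    Unlike the uniform composition, this keeps the parts positively coupled
    to the total — the way severity spreads across the components of a real
    instrument — instead of anti-correlated given it.
    """
    total = int(np.clip(total, 0, n_items * cap))
    ideal = np.clip(total / n_items + rng.normal(0.0, noise, n_items), 0, cap)
    parts = np.floor(ideal).astype(int)
    # largest-remainder repair to the exact total, respecting caps
    while parts.sum() < total:
        room = parts < cap
        frac = np.where(room, ideal - parts, -np.inf)
        parts[int(np.argmax(frac))] += 1
    while parts.sum() > total:
        frac = np.where(parts > 0, ideal - parts, np.inf)
        parts[int(np.argmin(frac))] -= 1
    return parts


def _realise_psqi(rng, global_scores: np.ndarray, out: dict) -> None:
    """Sample the 17 PSQI working items so the component sum equals target."""
    n = global_scores.size
    lat_min = np.empty(n)
    sleep_h = np.empty(n)
    bed_h = np.empty(n)
    q5a = np.empty(n, dtype=int)
    disturb = np.empty((n, 9), dtype=int)
    quality = np.empty(n, dtype=int)
    medication = np.empty(n, dtype=int)
    daysleepy = np.empty(n, dtype=int)
    enthusiasm = np.empty(n, dtype=int)

    lat_lo = (0, 16, 31, 61)
    lat_hi = (15, 30, 60, 120)
    dur_lo = (7.05, 6.0, 5.0, 3.5)
    dur_hi = (8.5, 7.0, 5.95, 4.9)
    eff_lo = (0.86, 0.755, 0.655, 0.45)
    eff_hi = (0.97, 0.845, 0.745, 0.63)

    for i in range(n):
        comps = _allocate_proportional(rng, int(global_scores[i]), 7, 3, noise=0.55)
        c1, c2, c3, c4, c5, c6, c7 = comps
        quality[i] = c1
        # latency component: raw = band(minutes) + "can't sleep in 30 min"
        # frequency, re-banded 0 / 1-2 / 3-4 / 5-6 -> 0..3
        raw_choices = {0: (0,), 1: (1, 2), 2: (3, 4), 3: (5, 6)}[c2]
        raw = int(rng.choice(raw_choices))
        band = int(rng.integers(max(0, raw - 3), min(3, raw) + 1))
        q5a[i] = raw - band
        lat_min[i] = rng.uniform(lat_lo[band], lat_hi[band])
        sleep_h[i] = rng.uniform(dur_lo[c3], dur_hi[c3])
        bed_h[i] = sleep_h[i] / rng.uniform(eff_lo[c4], eff_hi[c4])
        dsum = (0, rng.integers(1, 6), 10 + rng.integers(0, 4), 19 + rng.integers(0, 4))[c5]
        disturb[i] = _allocate_proportional(rng, int(dsum), 9, 3, noise=0.45)
        medication[i] = c6
        dt = (0, rng.integers(1, 3), rng.integers(3, 5), rng.integers(5, 7))[c7]
        pair = _allocate(rng, int(dt), 2, 3)
        daysleepy[i], enthusiasm[i] = pair

    out["psqi_latency_min"] = np.round(lat_min, 0)
    out["psqi_sleep_hours"] = np.round(sleep_h, 2)
    out["psqi_bed_hours"] = np.round(bed_h, 4)
    out["psqi_q5a"] = q5a
    for j, name in enumerate(PSQI_DISTURBANCE_ITEMS):
        out[name] = disturb[:, j]
    out["psqi_quality"] = quality
    out["psqi_medication"] = medication
    out["psqi_daysleepy"] = daysleepy
    out["psqi_enthusiasm"] = enthusiasm


def _realise_berlin(rng, high: np.ndarray, cat3: np.ndarray, out: dict) -> None:
    """Category-1/2 items consistent with the intended risk label.

    High-risk rows get >= 2 positives in both symptom categories; low-risk
    rows get at most one positive category, and none at all when category 3
    (blood pressure / BMI) is already positive, so the realised risk equals
    the intended label exactly.
    """
    n = high.size
    c1 = np.zeros((n, 5), dtype=bool)
    c2 = np.zeros((n, 4), dtype=bool)
    for i in range(n):
        if high[i]:
            k1 = int(rng.integers(2, 5))
            k2 = int(rng.integers(2, 4))
            c1[i, rng.choice(5, k1, replace=False)] = True
            c2[i, rng.choice(4, k2, replace=False)] = True
        elif not cat3[i]:
            u = rng.random()
            if u < 0.30:  # exactly one positive symptom category
                c1[i, rng.choice(5, 2, replace=False)] = True
            elif u < 0.45:
                c2[i, rng.choice(4, 2, replace=False)] = True
            elif u < 0.80:  # sub-threshold single positives
                c1[i, rng.integers(5)] = rng.random() < 0.7
                c2[i, rng.integers(4)] = rng.random() < 0.4
    for j, name in enumerate(BERLIN_CAT1_ITEMS):
        out[name] = c1[:, j]
    for j, name in enumerate(BERLIN_CAT2_ITEMS):
        out[name] = c2[:, j]
    out["berlin_c2_drive"] = (rng.random(n) < 0.1) & c2.any(axis=1)


#: (step in points per level, number of items) per NQ factor.
_NQ_FACTOR_SHAPE = {
    "nq_balance": (2.5, 7),
    "nq_diversity": (1.25, 5),
    "nq_moderation": (1.25, 5),
    "nq_behavior": (1.25, 4),
}


def _realise_levels_from_total(rng, totals, n_items, cap):
    """Item levels (1-based) whose 0-based sum equals each rounded total."""
    levels = np.empty((totals.size, n_items), dtype=int)
    for i, t in enumerate(np.rint(totals).astype(int)):
        levels[i] = _allocate(rng, t, n_items, cap) + 1
    return levels


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """Generate an artifact-free survey table of ``n_respondents`` rows.

    Latent cluster labels are drawn from ``cluster_weights`` and carried in
    the side column ``true_cluster`` (never used by the pipeline).  Instrument
    scores computed downstream reproduce each cluster's configured targets in
    expectation.  Fully reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    profiles = _blend_profiles(config.profiles, config.cluster_weights, config.separation)

    labels = rng.choice(len(profiles), size=n, p=np.asarray(config.cluster_weights, float))
    out: dict[str, np.ndarray] = {
        "respondent_id": np.array([f"R{i:06d}" for i in range(n)], dtype=object),
        "true_cluster": np.array([profiles[c].name for c in labels], dtype=object),
        "consent": np.ones(n, dtype=bool),
    }
    # allocate empty columns, filled per cluster below
    for spec in COLUMNS[3:]:
        dtype = object if spec.kind == "nominal" else float
        out[spec.name] = np.empty(n, dtype=dtype) if dtype is object else np.zeros(n, dtype=float)

    for ci, prof in enumerate(profiles):
        m = labels == ci
        if not m.any():
            continue
        for name, values in _generate_cluster_block(rng, prof, int(m.sum())).items():
            out[name][m] = values

    df = pd.DataFrame({name: out[name] for name in COLUMN_NAMES})
    # cast ordinal/flag columns to clean integer / boolean dtypes
    for spec in COLUMNS:
        if spec.kind == "ordinal":
            df[spec.name] = df[spec.name].astype(int)
        elif spec.kind == "flag":
            df[spec.name] = df[spec.name].astype(bool)
    return df


#: Per-cluster correlation of each instrument total with the severity latent;
#: signs follow the published ordering of the cluster means.
_SCORE_SEVERITY_CORR = {
    "gsrs": 0.3,
    "psqi": 0.25,
    "nq_moderation": 0.18,
    "nq_balance": -0.1,
    "nq_behavior": -0.15,
    "nq_diversity": 0.0,
}


def _generate_cluster_block(rng, prof: ClusterProfile, n: int) -> dict:
    out: dict[str, np.ndarray] = {}
    # The population is organised along one latent "unwellness" axis: each
    # cluster is a position on it (prof.severity) plus tight within-cluster
    # noise.  Lifestyle items load on the axis linearly; a second, hinge
    # block (environment complaints, meal irregularity) responds only in the
    # severe range, so the manifold bends — the non-linearity a deep
    # autoencoder exploits and a linear projection shortens.
    s = prof.severity + 0.2 * rng.normal(size=n)
    s_hat = (s - prof.severity) / 0.2  # unit within-cluster residual
    hinge = np.maximum(s - 2.3, 0.0)

    # demographics ----------------------------------------------------------
    out["age"] = np.round(_trunc_normal(rng, *prof.age, 19.0, 45.0, n), 0)
    out["height_cm"] = np.round(_trunc_normal(rng, *prof.height, 150.0, 199.0, n), 1)
    out["weight_kg"] = np.round(_trunc_normal(rng, *prof.weight, 45.0, 140.0, n), 1)
    out["rank"] = rng.choice(RANKS, size=n, p=(0.05, 0.42, 0.40, 0.13))
    out["education"] = rng.choice(EDUCATION, size=n, p=(0.01, 0.93, 0.06))
    smoking = rng.choice(SMOKING, size=n, p=np.asarray(prof.smoking_p) / sum(prof.smoking_p))
    out["smoking_status"] = smoking
    packs = np.clip(rng.normal(0.5, 0.3, n), 0.05, 2.0)
    years = np.clip(rng.normal(2.5, 1.5, n), 0.1, 8.0)
    ever = smoking != "never"
    out["smoking_packs_per_day"] = np.round(np.where(smoking == "active", packs, 0.0), 2)
    out["smoking_years"] = np.round(np.where(ever, years, 0.0), 1)
    # caffeine consumption moves as one correlated block (shared latent)
    caffeine = rng.normal(0.0, 1.0, n)
    out["coffee_freq"] = np.clip(
        np.rint(1.6 + 0.55 * caffeine + rng.normal(0, 0.9, n)), 0, 5
    ).astype(int)
    out["energy_drink_freq"] = np.clip(
        np.rint(1.0 + 0.5 * caffeine + rng.normal(0, 0.9, n)), 0, 5
    ).astype(int)
    out["alcohol_freq"] = np.clip(
        np.rint(1.35 + 0.05 * s + rng.normal(0, 0.95, n)), 0, 3
    ).astype(int)
    out["exercise_freq"] = np.clip(
        np.rint(1.85 - 0.1 * s + rng.normal(0, 1.05, n)), 0, 3
    ).astype(int)
    out["physical_grade"] = np.clip(
        np.rint(1.95 + 0.1 * s + 0.4 * hinge + rng.normal(0, 0.75, n)), 1, 5
    ).astype(int)
    # medical history (published per-cluster rates, mildly severity-coupled)
    for name, p, load in zip(
        ("hist_sleep_disorder", "hist_gi_disorder", "hist_hypertension", "hist_general_disease"),
        prof.hist_p,
        (0.4, 0.7, 0.2, 0.5),
    ):
        out[name] = rng.random(n) < np.clip(p * (1.0 + load * s_hat * 0.3), 0.0, 0.95)
    out["stress"] = np.clip(
        np.rint(prof.stress_mean + 0.1 * s_hat + rng.normal(0, 1.35, n)), 1, 5
    ).astype(int)
    # military ----------------------------------------------------------------
    out["duty_branch"] = rng.choice(BRANCHES, size=n, p=(0.5, 0.3, 0.2))
    shift = rng.normal(0.0, 1.0, n)  # night-shift exposure block
    out["night_shift_dutyoff_freq"] = np.clip(
        np.rint(prof.night_shift_means[0] + 0.8 * shift + rng.normal(0, 1.0, n)), 0, 5
    ).astype(int)
    out["night_shift_no_dutyoff_freq"] = np.clip(
        np.rint(prof.night_shift_means[1] + 0.85 * shift + rng.normal(0, 1.0, n)), 0, 5
    ).astype(int)
    out["night_shift_sleep_impact"] = np.clip(
        np.rint(prof.night_impact_mean + 0.15 * s_hat + rng.normal(0, 0.85, n)), 1, 5
    ).astype(int)
    out["duty_stress"] = np.clip(
        np.rint(3.25 + 0.42 * s + 0.6 * hinge + rng.normal(0, 0.95, n)), 1, 5
    ).astype(int)
    # scored instruments: calibrated marginals, correlated with severity ------
    psqi_global = np.rint(
        _trunc_normal_corr(rng, *prof.psqi, 0.0, 21.0, s_hat, _SCORE_SEVERITY_CORR["psqi"])
    )
    _realise_psqi(rng, psqi_global, out)
    bmi = out["weight_kg"] / (out["height_cm"] / 100.0) ** 2
    cat3 = out["hist_hypertension"] | (bmi > 30.0)
    high = rng.random(n) < prof.berlin_high_p
    _realise_berlin(rng, high, cat3, out)
    # sleeping environment: hinge block — complaints emerge in the severe range
    env = rng.normal(0.0, 1.0, n)
    for name in ("env_noise", "env_light", "env_temperature", "env_crowding"):
        out[name] = np.clip(
            np.rint(2.35 + 0.17 * s + 1.3 * hinge + 0.25 * env + rng.normal(0, 0.85, n)),
            1, 5,
        ).astype(int)
    # dietary habits: moderation/frequency blocks load linearly on severity
    # (they differentiate the mild and intermediate clusters); meal
    # regularity is a hinge block that collapses only in the severe range
    for j, name in enumerate(DIET_ITEMS):
        if j < 8:
            base = 3.2 - 0.1 * s - 1.2 * hinge
        elif j < 17:
            base = 3.7 - 1.12 * s
        else:
            base = 2.4 + 0.98 * s
        out[name] = np.clip(
            np.rint(base + rng.normal(0, 0.95, n)), 1, 5
        ).astype(int)
    for attr in ("nq_balance", "nq_diversity", "nq_moderation", "nq_behavior"):
        step, n_items = _NQ_FACTOR_SHAPE[attr]
        mean, sd = getattr(prof, attr)
        hi = step * n_items * 4
        target_units = _trunc_normal_corr(
            rng, mean, sd, 0.0, hi, s_hat, _SCORE_SEVERITY_CORR[attr]
        ) / step
        levels = _realise_levels_from_total(rng, target_units, n_items, 4)
        start = {"nq_balance": 0, "nq_diversity": 7, "nq_moderation": 12, "nq_behavior": 17}[attr]
        for j in range(n_items):
            out[NQ_ITEMS[start + j]] = levels[:, j]
    gsrs_total = _trunc_normal_corr(
        rng, *prof.gsrs, 0.0, 90.0, s_hat, _SCORE_SEVERITY_CORR["gsrs"]
    )
    gsrs_levels = _realise_levels_from_total(rng, gsrs_total, 15, 6)
    for j, name in enumerate(GSRS_ITEMS):
        out[name] = gsrs_levels[:, j]
    out["bss"] = np.clip(
        np.rint(3.2 + 0.77 * s + 0.7 * hinge + rng.normal(0, 0.9, n)), 1, 7
    ).astype(int)
    return out


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

#: Preprocessing bounds the injected outliers are guaranteed to violate.
OUTLIER_FIELDS = ("height_cm", "weight_kg", "smoking_packs_per_day", "smoking_years")

#: Trailing sections eligible as the blanking cut point for incomplete rows.
_INCOMPLETE_CUTS = ("diet", "nq", "gsrs", "bss")


def inject_artifacts(
    table: pd.DataFrame,
    rates: ArtifactRates | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject duplicates, incomplete rows and out-of-range outliers.

    Returns the augmented table and a manifest (``respondent_id``,
    ``artifact``) of the altered rows.  The three artifact groups are drawn
    from disjoint row sets so the cleaning chain removes each group at
    exactly one stage.  Duplicated respondents keep their id but re-draw a
    few Likert answers; incomplete rows have a trailing block of sections
    blanked; outlier rows get one of the open-question fields (height,
    weight, smoking amount or duration) overwritten with an out-of-bound
    value.
    """
    rates = rates or ArtifactRates()
    for fname in ("duplicate_rate", "incomplete_rate", "outlier_rate"):
        r = getattr(rates, fname)
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"{fname} must lie in [0, 1]")
    if table["respondent_id"].duplicated().any():
        raise ConfigurationError("input table must have unique respondent_id")

    rng = np.random.default_rng(seed)
    n = len(table)
    n_dup = rng.binomial(n, rates.duplicate_rate)
    n_inc = rng.binomial(n, rates.incomplete_rate)
    n_out = rng.binomial(n, rates.outlier_rate)
    order = rng.permutation(n)
    dup_rows = order[:n_dup]
    inc_rows = order[n_dup:n_dup + n_inc]
    out_rows = order[n_dup + n_inc:n_dup + n_inc + n_out]

    df = table.copy()
    manifest_rows = []

    # incomplete: blank a trailing block of sections
    incomplete_cols = {
        cut: [c for s in SECTIONS[SECTIONS.index(cut):] for c in _BY_SECTION[s]]
        for cut in _INCOMPLETE_CUTS
    }
    for pos in inc_rows:
        cut = _INCOMPLETE_CUTS[rng.integers(len(_INCOMPLETE_CUTS))]
        cols = incomplete_cols[cut]
        df.loc[df.index[pos], cols] = np.nan
        manifest_rows.append((table["respondent_id"].iloc[pos], "incomplete"))

    # outliers: overwrite one bounded field with an out-of-range value
    outlier_draws = {
        "height_cm": lambda: rng.choice([rng.uniform(80, 109), rng.uniform(201, 240)]),
        "weight_kg": lambda: rng.choice([rng.uniform(20, 39), rng.uniform(161, 220)]),
        "smoking_packs_per_day": lambda: rng.uniform(5.5, 12),
        "smoking_years": lambda: rng.uniform(21, 40),
    }
    for pos in out_rows:
        fld = OUTLIER_FIELDS[rng.integers(len(OUTLIER_FIELDS))]
        df.loc[df.index[pos], fld] = round(float(outlier_draws[fld]()), 1)
        manifest_rows.append((table["respondent_id"].iloc[pos], "outlier"))

    # duplicates: append a re-sampled copy with the same id
    likert_cols = [c.name for c in COLUMNS if c.kind == "ordinal"]
    dup_block = df.iloc[dup_rows].copy()
    for col in rng.choice(likert_cols, size=min(8, len(likert_cols)), replace=False):
        spec = next(c for c in COLUMNS if c.name == col)
        dup_block[col] = rng.choice(spec.levels, size=len(dup_block))
    for rid in table["respondent_id"].iloc[dup_rows]:
        manifest_rows.append((rid, "duplicate"))

    df = pd.concat([df, dup_block], ignore_index=True)
    manifest = pd.DataFrame(manifest_rows, columns=["respondent_id", "artifact"])
    return df, manifest


def generate_survey(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population plus injected artifacts; the usual pipeline entry point."""
    clean = generate_population(config)
    # derive the artifact seed from the config seed; keep both below 2**31
    return inject_artifacts(clean, config.artifact_rates, seed=(config.seed + 1) % (2**31))


def write_survey(
    table: pd.DataFrame, path, manifest: pd.DataFrame | None = None, manifest_path=None
) -> None:
    """Persist a survey table (and optional manifest) as delimited text."""
    table.to_csv(path, index=False)
    if manifest is not None and manifest_path is not None:
        manifest.to_csv(manifest_path, index=False)
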