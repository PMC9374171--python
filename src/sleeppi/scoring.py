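"""Instrument scoring and design-stage sample-size arithmetic.

Implements every derived score the analysis consumes:

* PSQI — 19 items folded into seven components (each 0-3), a global score
  0-21, and the sleep-disturbance flag (global > 5).
* Berlin questionnaire — three category positives and the high/low OSA-risk
  label (high = at least two positive categories).
* Nutrition quotient (NQ) — four factor scores, a global score and the
  "good" (>= 58) / "monitoring" grade.  The published factor weighting is
  not reproduced in the source study, so the default weight table here is a
  stand-in with the correct structure; it is supplied as data and can be
  replaced wholesale.
* GSRS — 15-item discomfort total.  The aggregation convention is
  configurable (``sum0`` zero-based sum, ``sum1`` one-based sum, ``mean``);
  the zero-based sum is the default, the only convention whose 0-90 range is
  consistent with the reported per-cluster means.
* Bristol stool scale — passthrough 1-7.

Component banding tables are module-level data, not control flow, so
variants can be tested by substitution.  Missing items raise
:class:`~sleeppi.errors.ScoringError`; there is no imputation anywhere —
incomplete respondents are excluded upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ScoringError
from .synthetic import (
    BERLIN_CAT1_ITEMS,
    BERLIN_CAT2_ITEMS,
    GSRS_ITEMS,
    NQ_ITEMS,
    PSQI_DISTURBANCE_ITEMS,
)

# ---------------------------------------------------------------------------
# PSQI
# ---------------------------------------------------------------------------

#: Banding tables: list of (upper_bound_inclusive, band). Scanned in order.
PSQI_BANDS = {
    # minutes of sleep latency
    "latency_minutes": [(15, 0), (30, 1), (60, 2), (math.inf, 3)],
    # re-banding of band(minutes) + frequency item
    "latency_sum": [(0, 0), (2, 1), (4, 2), (6, 3)],
    # hours of actual sleep: > t0 -> 0, >= t1 -> 1, >= t2 -> 2, else 3
    "duration_hours": (7.0, 6.0, 5.0),
    # habitual sleep efficiency percent: >= t0 -> 0, >= t1 -> 1, >= t2 -> 2
    "efficiency_pct": (85.0, 75.0, 65.0),
    # sum of the nine disturbance-frequency items
    "disturbance_sum": [(0, 0), (9, 1), (18, 2), (27, 3)],
    # sum of the two daytime-dysfunction items
    "daytime_sum": [(0, 0), (2, 1), (4, 2), (6, 3)],
}

PSQI_ITEMS = (
    "psqi_latency_min",
    "psqi_sleep_hours",
    "psqi_bed_hours",
    "psqi_q5a",
    *PSQI_DISTURBANCE_ITEMS,
    "psqi_quality",
    "psqi_medication",
    "psqi_daysleepy",
    "psqi_enthusiasm",
)


def _band_upper(value, bands):
    for ub, band in bands:
        if value <= ub:
            return band
    return bands[-1][1]


def _require(items: Mapping, names: Sequence[str], instrument: str):
    vals = {}
    for name in names:
        if name not in items:
            raise ScoringError(f"{instrument}: missing item '{name}'")
        v = items[name]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ScoringError(f"{instrument}: missing item '{name}'")
        vals[name] = v
    return vals


def score_psqi(items: Mapping, bands: Mapping = PSQI_BANDS):
    """Score one respondent's PSQI.

    Returns ``(components, global_score, disturbed)`` where ``components``
    is a 7-tuple of integers in 0-3 (quality, latency, duration, efficiency,
    disturbances, medication, daytime dysfunction), ``global_score`` is
    their sum, and ``disturbed`` flags a global score strictly above 5.
    """
    v = _require(items, PSQI_ITEMS, "PSQI")
    c1 = int(v["psqi_quality"])
    lat_band = _band_upper(float(v["psqi_latency_min"]), bands["latency_minutes"])
    c2 = _band_upper(lat_band + int(v["psqi_q5a"]), bands["latency_sum"])
    hours = float(v["psqi_sleep_hours"])
    t0, t1, t2 = bands["duration_hours"]
    if hours > t0:
        c3 = 0
    elif hours >= t1:
        c3 = 1
    elif hours >= t2:
        c3 = 2
    else:
        c3 = 3
    bed = float(v["psqi_bed_hours"])
    if bed <= 0:
        raise ScoringError("PSQI: non-positive time in bed")
    eff = 100.0 * hours / bed
    e0, e1, e2 = bands["efficiency_pct"]
    c4 = 0 if eff >= e0 else 1 if eff >= e1 else 2 if eff >= e2 else 3
    dist_sum = sum(int(v[name]) for name in PSQI_DISTURBANCE_ITEMS)
    c5 = _band_upper(dist_sum, bands["disturbance_sum"])
    c6 = int(v["psqi_medication"])
    c7 = _band_upper(int(v["psqi_daysleepy"]) + int(v["psqi_enthusiasm"]), bands["daytime_sum"])
    comps = (c1, c2, c3, c4, c5, c6, c7)
    for c in comps:
        if not 0 <= c <= 3:
            raise ScoringError(f"PSQI: component out of range in {comps}")
    total = int(sum(comps))
    return comps, total, total > 5


# ---------------------------------------------------------------------------
# Berlin questionnaire
# ---------------------------------------------------------------------------


def score_berlin(items: Mapping, bmi: float, bp_history: bool):
    """Berlin OSA screen: category flags and the high/low risk label.

    Categories 1 and 2 are positive with at least two positive symptom
    responses; category 3 is positive with a blood-pressure history or
    BMI > 30 kg/m^2.  Risk is high with at least two positive categories.
    The drowsy-driving sub-question is carried but does not count toward
    the category-2 threshold.
    """
    v = _require(items, BERLIN_CAT1_ITEMS + BERLIN_CAT2_ITEMS, "Berlin")
    cat1 = sum(bool(v[n]) for n in BERLIN_CAT1_ITEMS) >= 2
    cat2 = sum(bool(v[n]) for n in BERLIN_CAT2_ITEMS) >= 2
    cat3 = bool(bp_history) or float(bmi) > 30.0
    risk = "high" if (cat1 + cat2 + cat3) >= 2 else "low"
    return cat1, cat2, cat3, risk


# ---------------------------------------------------------------------------
# GSRS
# ---------------------------------------------------------------------------


def score_gsrs(items: Mapping, convention: str = "sum0") -> float:
    """GSRS aggregate over the 15 seven-point discomfort items.

    ``sum0`` (default): total of (level - 1), range 0-90; ``sum1``: total of
    raw levels, range 15-105; ``mean``: mean raw level, range 1-7.
    """
    v = _require(items, GSRS_ITEMS, "GSRS")
    levels = []
    for name in GSRS_ITEMS:
        lv = int(v[name])
        if not 1 <= lv <= 7:
            raise ScoringError(f"GSRS: item '{name}' level {lv} outside 1-7")
        levels.append(lv)
    if convention == "sum0":
        return float(sum(lv - 1 for lv in levels))
    if convention == "sum1":
        return float(sum(levels))
    if convention == "mean":
        return float(np.mean(levels))
    raise ConfigurationError(f"unknown GSRS convention '{convention}'")


# ---------------------------------------------------------------------------
# Nutrition quotient
# ---------------------------------------------------------------------------

NQ_GOOD_THRESHOLD = 58.0


def _default_nq_weights():
    """Stand-in weight table with the published structure (21 items, four
    factors, global score on a 0-100 scale graded at 58)."""
    factors = {
        "balance": (NQ_ITEMS[0:7], [0.0, 2.5, 5.0, 7.5, 10.0]),
        "diversity": (NQ_ITEMS[7:12], [0.0, 1.25, 2.5, 3.75, 5.0]),
        "moderation": (NQ_ITEMS[12:17], [0.0, 1.25, 2.5, 3.75, 5.0]),
        "behavior": (NQ_ITEMS[17:21], [0.0, 1.25, 2.5, 3.75, 5.0]),
    }
    item_points = {it: pts for items, pts in factors.values() for it in items}
    item_factor = {it: f for f, (items, _) in factors.items() for it in items}
    # max attainable factor total is 140 points; scale the global to 0-100
    factor_weights = {f: 100.0 / 140.0 for f in factors}
    return {
        "item_factor": item_factor,
        "item_points": item_points,
        "factor_weights": factor_weights,
    }


DEFAULT_NQ_WEIGHTS = _default_nq_weights()


def score_nq(items: Mapping, weights: Mapping = DEFAULT_NQ_WEIGHTS):
    """NQ factor scores, global score and grade from a weight table.

    ``weights`` maps items to factors (``item_factor``), items to per-level
    point lists indexed by ``level - 1`` (``item_points``) and factors to
    their contribution to the global score (``factor_weights``).  Returns
    ``(global, factor_scores, grade)`` with grade ``good`` iff global >= 58.
    """
    item_factor = weights["item_factor"]
    item_points = weights["item_points"]
    factor_weights = weights["factor_weights"]
    mapped = list(item_factor)
    for it in mapped:
        if it not in item_points:
            raise ConfigurationError(f"NQ weights: item '{it}' has no point table")
    v = _require(items, mapped, "NQ")
    factor_scores = {f: 0.0 for f in factor_weights}
    for it in mapped:
        level = int(v[it])
        pts = item_points[it]
        if not 1 <= level <= len(pts):
            raise ScoringError(f"NQ: item '{it}' level {level} outside 1-{len(pts)}")
        factor_scores[item_factor[it]] += float(pts[level - 1])
    nq_global = float(sum(factor_weights[f] * factor_scores[f] for f in factor_weights))
    grade = "good" if nq_global >= NQ_GOOD_THRESHOLD else "monitoring"
    return nq_global, factor_scores, grade


# ---------------------------------------------------------------------------
# Whole-table scoring
# ---------------------------------------------------------------------------

SCORE_COLUMNS = (
    "psqi_global",
    "psqi_disturbed",
    "berlin_cat1",
    "berlin_cat2",
    "berlin_cat3",
    "berlin_risk",
    "nq_global",
    "nq_balance",
    "nq_diversity",
    "nq_moderation",
    "nq_behavior",
    "nq_grade",
    "gsrs_total",
)


def score_table(
    table: pd.DataFrame,
    gsrs_convention: str = "sum0",
    nq_weights: Mapping = DEFAULT_NQ_WEIGHTS,
    psqi_bands: Mapping = PSQI_BANDS,
    skip_incomplete: bool = True,
) -> pd.DataFrame:
    """Append every derived instrument score to a survey table.

    Rows failing any instrument (missing/out-of-range items) get NaN scores
    when ``skip_incomplete`` is true (they are dropped by the completeness
    filter upstream of any score consumer); otherwise the error propagates.
    """
    df = table.copy()
    n = len(df)
    cols = {name: np.full(n, np.nan, dtype=object) for name in SCORE_COLUMNS}
    comps = np.full((n, 7), np.nan)
    records = df.to_dict("records")
    for i, row in enumerate(records):
        try:
            c, total, flag = score_psqi(row, psqi_bands)
            bmi = float(row["weight_kg"]) / (float(row["height_cm"]) / 100.0) ** 2
            cat1, cat2, cat3, risk = score_berlin(row, bmi, row["hist_hypertension"])
            nq_g, nq_f, nq_grade = score_nq(row, nq_weights)
            gsrs = score_gsrs(row, gsrs_convention)
        except (ScoringError, ValueError, TypeError):
            if not skip_incomplete:
                raise
            continue
        comps[i] = c
        cols["psqi_global"][i] = total
        cols["psqi_disturbed"][i] = flag
        cols["berlin_cat1"][i] = cat1
        cols["berlin_cat2"][i] = cat2
        cols["berlin_cat3"][i] = cat3
        cols["berlin_risk"][i] = risk
        cols["nq_global"][i] = nq_g
        for f in ("balance", "diversity", "moderation", "behavior"):
            cols[f"nq_{f}"][i] = nq_f[f]
        cols["nq_grade"][i] = nq_grade
        cols["gsrs_total"][i] = gsrs
    for j in range(7):
        df[f"psqi_c{j + 1}"] = comps[:, j]
    flag_cols = ("psqi_disturbed", "berlin_cat1", "berlin_cat2", "berlin_cat3")
    for name in SCORE_COLUMNS:
        values = cols[name]
        if name in ("berlin_risk", "nq_grade"):
            df[name] = values
        elif name in flag_cols:
            df[name] = pd.array(list(values), dtype="boolean")
        else:
            df[name] = pd.to_numeric(pd.Series(values, index=df.index), errors="coerce")
    return df


# ---------------------------------------------------------------------------
# Sample-size design calculations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSizeParams:
    """Finite-population sample-size inputs.

    N: population size; e: margin of error (proportion); confidence: level
    in (0, 1), mapped to the standard-normal quantile z; p: anticipated
    proportion (0.5 is the conservative default); response_rate: expected
    fraction of invitations yielding a complete response.
    """

    N: float
    e: float
    confidence: float = 0.95
    p: float = 0.5
    response_rate: float = 1.0

    def validate(self):
        if not 0 < self.e < 1:
            raise ConfigurationError("e (margin of error) must lie in (0, 1)")
        if not 0 < self.p < 1:
            raise ConfigurationError("p (anticipated proportion) must lie in (0, 1)")
        if self.N <= 0:
            raise ConfigurationError("N (population size) must be positive")
        if not 0 < self.confidence < 1:
            raise ConfigurationError("confidence must lie in (0, 1)")
        if not 0 < self.response_rate <= 1:
            raise ConfigurationError("response_rate must lie in (0, 1]")


def sample_size(params: SampleSizeParams) -> int:
    """Required completed surveys under the finite-population correction.

    n0 = z^2 p (1 - p) / e^2, deflated by 1 + n0/N and rounded up.
    """
    params.validate()
    z = stats.norm.ppf(0.5 + params.confidence / 2.0)
    n0 = z**2 * params.p * (1.0 - params.p) / params.e**2
    return int(math.ceil(n0 / (1.0 + n0 / params.N)))


def required_invitations(completes: int, response_rate: float) -> int:
    """Invitations needed for `completes` responses at the given rate."""
    if not 0 < response_rate <= 1:
        raise ConfigurationError("response_rate must lie in (0, 1]")
    return int(math.ceil(completes / response_rate))
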