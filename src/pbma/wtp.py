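"""Contingent-valuation (willingness-to-pay) aggregation.

Survey respondents state, per program component, the maximum increase in
annual taxation (GBP/person/year) they would accept to have the component
provided.  Only complete cases — respondents who valued every component —
are retained, mirroring stated-preference practice.  The sample mean per
component scales up to a societal aggregate value (mean x population, in
GBP millions/year), which feeds two criteria:

* societal benefit: the aggregates are min-max mapped across the component
  set onto the bounded -2..+2 scoring scale;
* cost-benefit: the net benefit (aggregate value minus annual cost) is
  divided by a dispersion scale and clamped to [-2, +2].

Both mappings are pluggable strategies; reports record which was used,
since no single convention exists for projecting monetary values onto a
bounded panel-scoring scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

RESPONSE_COLUMNS = {"respondent_id", "component", "wtp_gbp_per_year"}


@dataclass(frozen=True)
class SocietalValue:
    component: str
    mean_wtp: float  # GBP / person / year
    aggregate_value_gbp_m: float  # GBP millions / year
    benefit_score: float | None = None
    cost_benefit_score: float | None = None


def complete_cases(responses: pd.DataFrame) -> pd.DataFrame:
    """Keep only respondents who valued every component in the survey."""
    missing = RESPONSE_COLUMNS - set(responses.columns)
    if missing:
        raise ValidationError(f"response table missing columns: {sorted(missing)}")
    if (responses["wtp_gbp_per_year"] < 0).any():
        raise ValidationError("negative willingness-to-pay amount")
    n_components = responses["component"].nunique()
    counts = responses.groupby("respondent_id")["component"].nunique()
    keep = counts[counts == n_components].index
    return responses[responses["respondent_id"].isin(keep)]


def aggregate_wtp(
    responses: pd.DataFrame,
    population: int,
    trim: float = 0.0,
) -> pd.DataFrame:
    """Mean WTP and societal aggregate value per component.

    ``trim`` (0 <= trim < 0.5) requests a symmetric trimmed mean to blunt
    extreme stated amounts; 0 is the plain mean used by default.
    Returns a frame indexed by component with columns ``mean_wtp`` and
    ``aggregate_value_gbp_m`` (= mean x population / 1e6).
    """
    if population <= 0:
        raise ValidationError("population must be positive")
    if not 0 <= trim < 0.5:
        raise ValidationError("trim fraction must be in [0, 0.5)")
    complete = complete_cases(responses)
    if complete.empty:
        raise InsufficientDataError("no respondent valued every component")

    def _mean(values: pd.Series) -> float:
        if trim == 0:
            return float(values.mean())
        return float(stats.trim_mean(values.to_numpy(), trim))

    mean_wtp = complete.groupby("component", sort=False)["wtp_gbp_per_year"].apply(_mean)
    out = pd.DataFrame(
        {
            "mean_wtp": mean_wtp,
            "aggregate_value_gbp_m": mean_wtp * population / 1e6,
        }
    )
    out.index.name = "component"
    return out


def wtp_to_benefit_score(aggregate_values: Mapping[str, float]) -> dict[str, float]:
    """Min-max map of aggregate values onto [-2, +2] across components.

    The component with the lowest aggregate value scores -2, the highest
    +2; a degenerate range (single component, or all equal) scores 0.
    """
    if not aggregate_values:
        raise ValidationError("no aggregate values to score")
    items = list(aggregate_values.items())
    vals = np.array([v for _, v in items], dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return {k: 0.0 for k, _ in items}
    scores = -2.0 + 4.0 * (vals - lo) / (hi - lo)
    return {k: float(s) for (k, _), s in zip(items, scores)}


def cost_benefit_score(cost_gbp_m: float, aggregate_value_gbp_m: float, scale_gbp_m: float) -> float:
    """Clamped linear score of net societal benefit.

    score = clamp((value - cost) / scale, -2, +2): break-even scores 0,
    and a net benefit of +/- 2 x scale saturates the scale ends.
    """
    if scale_gbp_m <= 0:
        raise ValidationError("scale must be positive")
    return float(np.clip((aggregate_value_gbp_m - cost_gbp_m) / scale_gbp_m, -2.0, 2.0))


def default_cost_benefit_scale(
    costs_gbp_m: Mapping[str, float],
    aggregate_values_gbp_m: Mapping[str, float],
) -> float:
    """Half the interquartile range of |value - cost| across components.

    Chosen so that typical net benefits spread across the usable score
    range rather than piling up at the clamp.  Falls back to the largest
    absolute net benefit (or 1.0 if all are zero) when the IQR degenerates.
    """
    gaps = np.array(
        [abs(aggregate_values_gbp_m[c] - costs_gbp_m[c]) for c in costs_gbp_m],
        dtype=float,
    )
    iqr = float(np.percentile(gaps, 75) - np.percentile(gaps, 25))
    if iqr > 0:
        return iqr / 2.0
    fallback = float(gaps.max()) if gaps.size and gaps.max() > 0 else 1.0
    return fallback


def societal_values(
    responses: pd.DataFrame,
    population: int,
    costs_gbp_m: Mapping[str, float] | None = None,
    trim: float = 0.0,
    scale_gbp_m: float | None = None,
) -> pd.DataFrame:
    """Full survey-to-scores pipeline for every component.

    Aggregates WTP, maps aggregates to benefit scores, and — when per-
    component annual costs are supplied — computes cost-benefit scores.
    """
    agg = aggregate_wtp(responses, population, trim=trim)
    benefit = wtp_to_benefit_score(agg["aggregate_value_gbp_m"].to_dict())
    agg["benefit_score"] = agg.index.map(benefit)
    if costs_gbp_m is not None:
        missing = set(agg.index) - set(costs_gbp_m)
        if missing:
            raise ValidationError(f"no cost supplied for components: {sorted(missing)}")
        values = agg["aggregate_value_gbp_m"].to_dict()
        if scale_gbp_m is None:
            scale_gbp_m = default_cost_benefit_scale(
                {c: costs_gbp_m[c] for c in agg.index}, values
            )
        agg["cost_benefit_score"] = [
            cost_benefit_score(costs_gbp_m[c], values[c], scale_gbp_m) for c in agg.index
        ]
    return agg
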