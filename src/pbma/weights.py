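"""Criterion weight elicitation by 100-point allocation.

Each panelist distributes exactly 100 points across the decision criteria
(and, within each criterion, across its subcriteria).  The panel weight of
an item is the arithmetic mean of the points it received — the mean
preserves the 100-point simplex, so main weights always total 100.  The
overall weight of a subcriterion is its main-criterion weight multiplied
by its within-criterion weight: e.g. a criterion weighted 22.8% whose
subcriterion takes 26% of it gives an overall weight of 22.8 x 0.26 = 5.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

#: tolerance on weight sums imposed by :class:`CriterionTree`
SUM_TOL = 0.2


@dataclass(frozen=True)
class PointAllocation:
    """One panelist's distribution of 100 points over a set of items."""

    panelist_id: str
    points: Mapping[str, float]

    def total(self) -> float:
        return float(sum(self.points.values()))


@dataclass(frozen=True)
class Subcriterion:
    name: str
    within_weight_pct: float

    def overall_weight_pct(self, main_weight_pct: float) -> float:
        return main_weight_pct * self.within_weight_pct / 100.0


@dataclass(frozen=True)
class Criterion:
    name: str
    weight_pct: float
    subcriteria: tuple[Subcriterion, ...] = field(default_factory=tuple)


class CriterionTree:
    """Two-level weighting structure: main criteria with nested subcriteria.

    Criteria keep their input order; nothing is re-sorted by weight.  On
    construction the tree checks that main weights total 100 (+/- 0.2) and
    that within-criterion weights total 100 (+/- 0.2) for every criterion.
    """

    def __init__(self, criteria: Sequence[Criterion]):
        if not criteria:
            raise ValidationError("criterion tree must contain at least one criterion")
        names = [c.name for c in criteria]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate criterion names")
        total = sum(c.weight_pct for c in criteria)
        if abs(total - 100.0) > SUM_TOL:
            raise ValidationError(
                f"main criterion weights sum to {total:.3f}, expected 100 +/- {SUM_TOL}"
            )
        for c in criteria:
            if c.subcriteria:
                sub_total = sum(s.within_weight_pct for s in c.subcriteria)
                if abs(sub_total - 100.0) > SUM_TOL:
                    raise ValidationError(
                        f"within-criterion weights of {c.name!r} sum to "
                        f"{sub_total:.3f}, expected 100 +/- {SUM_TOL}"
                    )
        self.criteria: tuple[Criterion, ...] = tuple(criteria)

    # -- access ---------------------------------------------------------

    @property
    def criterion_names(self) -> list[str]:
        return [c.name for c in self.criteria]

    def main_weights(self) -> dict[str, float]:
        """Main-criterion percentage weights, in input order."""
        return {c.name: c.weight_pct for c in self.criteria}

    def criterion(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise ValidationError(f"unknown criterion {name!r}")

    def overall_subweights(self) -> dict[tuple[str, str], float]:
        """Overall percentage weight of every (criterion, subcriterion).

        overall = main x within / 100, unrounded.  Subcriterion names are
        only unique within their criterion, hence the pair key.  The values
        total 100 (up to the tolerance already enforced on the inputs).
        """
        out: dict[tuple[str, str], float] = {}
        for c in self.criteria:
            subs = c.subcriteria or (Subcriterion(c.name, 100.0),)
            for s in subs:
                out[(c.name, s.name)] = s.overall_weight_pct(c.weight_pct)
        return out

    # -- (de)serialisation ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.criteria:
            subs = c.subcriteria or (Subcriterion(c.name, 100.0),)
            for s in subs:
                rows.append(
                    {
                        "criterion": c.name,
                        "weight_pct": c.weight_pct,
                        "subcriterion": s.name,
                        "within_weight_pct": s.within_weight_pct,
                        "overall_weight_pct": s.overall_weight_pct(c.weight_pct),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CriterionTree":
        required = {"criterion", "weight_pct", "subcriterion", "within_weight_pct"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"criterion table missing columns: {sorted(missing)}")
        criteria = []
        for name in frame["criterion"].drop_duplicates():
            block = frame[frame["criterion"] == name]
            weight = float(block["weight_pct"].iloc[0])
            subs = tuple(
                Subcriterion(str(r.subcriterion), float(r.within_weight_pct))
                for r in block.itertuples()
            )
            criteria.append(Criterion(str(name), weight, subs))
        return cls(criteria)

    @classmethod
    def from_csv(cls, path) -> "CriterionTree":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, CriterionTree) and self.criteria == other.criteria

    def __repr__(self) -> str:
        return f"CriterionTree({len(self.criteria)} criteria)"


# -- elicitation ----------------------------------------------------------


def validate_allocation(
    points: Mapping[str, float],
    tolerance: float = 0.0,
    panelist_id: str = "?",
) -> PointAllocation:
    """Check a raw ballot and normalise it to total exactly 100 points.

    A ballot whose total is within ``tolerance`` of 100 is rescaled
    proportionally; anything further off is rejected.  The default strict
    tolerance mirrors electronic voting that enforces the constraint.
    """
    if not points:
        raise ValidationError(f"panelist {panelist_id}: empty allocation")
    vals = np.asarray(list(points.values()), dtype=float)
    if np.any(vals < 0):
        raise ValidationError(f"panelist {panelist_id}: negative points")
    total = vals.sum()
    if total == 0:
        raise ValidationError(f"panelist {panelist_id}: all points are zero")
    if abs(total - 100.0) > tolerance:
        raise ValidationError(
            f"panelist {panelist_id}: points sum to {total:g}, "
            f"outside 100 +/- {tolerance:g}"
        )
    scale = 100.0 / total
    return PointAllocation(
        panelist_id=panelist_id,
        points={k: float(v) * scale for k, v in points.items()},
    )


def aggregate_allocations(
    allocations: Iterable[PointAllocation],
    method: str = "mean",
) -> dict[str, float]:
    """Aggregate panel point allocations into percentage weights.

    The panel weight of each item is the mean of the points it received;
    ``method='median'`` is available for sensitivity analysis (the median
    does not preserve the 100-point total in general).
    """
    allocations = list(allocations)
    if not allocations:
        raise InsufficientDataError("no point allocations to aggregate")
    item_sets = {frozenset(a.points) for a in allocations}
    if len(item_sets) != 1:
        raise ValidationError("allocations do not cover the same item set")
    items = list(allocations[0].points)
    matrix = np.array([[a.points[i] for i in items] for a in allocations], dtype=float)
    if method == "mean":
        agg = matrix.mean(axis=0)
    elif method == "median":
        agg = np.median(matrix, axis=0)
    else:
        raise ValidationError(f"unknown aggregation method {method!r}")
    return dict(zip(items, agg.tolist()))


def build_tree(
    main_allocations: Iterable[PointAllocation],
    sub_allocations: Mapping[str, Iterable[PointAllocation]],
    method: str = "mean",
) -> CriterionTree:
    """Elicit a full two-level :class:`CriterionTree` from panel ballots.

    ``sub_allocations`` maps each criterion name to the panel's 100-point
    ballots over that criterion's subcriteria; criteria without an entry
    become single-subcriterion criteria carrying their own name.
    """
    main = aggregate_allocations(main_allocations, method=method)
    criteria = []
    for name, weight in main.items():
        if name in sub_allocations:
            within = aggregate_allocations(sub_allocations[name], method=method)
            subs = tuple(Subcriterion(s, w) for s, w in within.items())
        else:
            subs = (Subcriterion(name, 100.0),)
        criteria.append(Criterion(name, weight, subs))
    return CriterionTree(criteria)


def allocations_from_frame(frame: pd.DataFrame) -> list[PointAllocation]:
    """Read ballots from a tidy table (panelist_id, item, points)."""
    required = {"panelist_id", "item", "points"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"allocation table missing columns: {sorted(missing)}")
    out = []
    for pid, block in frame.groupby("panelist_id", sort=False):
        out.append(
            PointAllocation(str(pid), dict(zip(block["item"], block["points"].astype(float))))
        )
    return out
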