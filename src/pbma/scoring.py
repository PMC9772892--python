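"""Panel scoring of program components on the -2..+2 criterion scale.

Each panelist scores every component on every subcriterion with an integer
in {-2,-1,0,+1,+2}; the panel score is the median (half-integers arise for
even panels).  Subcriterion medians roll up to a criterion score as the
within-criterion weighted mean, and criterion scores roll up to the final
weighted score as the main-weight weighted mean.  Because both stages are
linear, the two-level roll-up equals a single pass over subcriteria with
their overall weights — a distributivity identity the test suite checks
against a brute-force oracle.

External evidence on a 1..5 Likert scale (e.g. a survey of members of
Parliament, or a patient-and-public involvement group) maps onto the score
scale by the affine shift rating - 3, and is carried through aggregation
exactly like a panel median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .weights import CriterionTree

logger = logging.getLogger(__name__)

VALID_VOTES = {-2, -1, 0, 1, 2}


def median_score(votes: Iterable[float]) -> float:
    """Median of integer panel votes; even counts give half-integers."""
    votes = list(votes)
    if not votes:
        raise InsufficientDataError("no votes to take a median of")
    for v in votes:
        if v not in VALID_VOTES:
            raise ValidationError(f"vote {v!r} outside the -2..+2 integer scale")
    return float(np.median(np.asarray(votes, dtype=float)))


def likert_to_score(median_rating: float) -> float:
    """Map a 1..5 Likert median onto the -2..+2 scale (rating - 3)."""
    if not 1.0 <= median_rating <= 5.0:
        raise ValidationError(f"Likert rating {median_rating} outside [1, 5]")
    return float(median_rating) - 3.0


@dataclass(frozen=True)
class LikertSummary:
    """Median 5-point rating of one component from an external source."""

    source: str
    component: str
    median_rating: float

    def score(self) -> float:
        return likert_to_score(self.median_rating)


def criterion_score(
    sub_scores: Mapping[str, float],
    tree: CriterionTree,
    criterion: str,
) -> float:
    """Within-criterion weighted mean of subcriterion scores."""
    crit = tree.criterion(criterion)
    subs = crit.subcriteria or ()
    if not subs:
        # single-subcriterion criterion represented by its own name
        return float(sub_scores[criterion])
    missing = [s.name for s in subs if s.name not in sub_scores]
    if missing:
        raise ValidationError(
            f"criterion {criterion!r}: missing subcriterion scores {missing}"
        )
    return sum(s.within_weight_pct / 100.0 * float(sub_scores[s.name]) for s in subs)


def final_weighted_score(
    criterion_scores: Mapping[str, float],
    tree: CriterionTree,
) -> float:
    """Main-weight weighted mean of the criterion-level scores."""
    missing = [c for c in tree.criterion_names if c not in criterion_scores]
    if missing:
        raise ValidationError(f"missing criterion scores: {missing}")
    return sum(
        c.weight_pct / 100.0 * float(criterion_scores[c.name]) for c in tree.criteria
    )


@dataclass
class ScoreMatrix:
    """Panel scores at all three aggregation levels.

    sub_scores:       components x (criterion, subcriterion) medians
    criterion_scores: components x criteria weighted means
    final_scores:     per-component final weighted score
    """

    sub_scores: pd.DataFrame
    criterion_scores: pd.DataFrame
    final_scores: pd.Series

    def __post_init__(self):
        for frame in (self.sub_scores, self.criterion_scores):
            vals = frame.to_numpy(dtype=float)
            if np.any(vals < -2 - 1e-9) or np.any(vals > 2 + 1e-9):
                raise ValidationError("score outside the [-2, +2] range")


def score_matrix_from_ballots(
    ballots: pd.DataFrame,
    tree: CriterionTree,
    external_scores: Mapping[tuple[str, str, str], float] | None = None,
    expected_panel: int | None = None,
) -> ScoreMatrix:
    """Aggregate a tidy ballot table into a full :class:`ScoreMatrix`.

    ``ballots`` columns: panelist_id, component, criterion, subcriterion,
    score.  ``external_scores`` supplies evidence-derived subcriterion
    scores keyed by (component, criterion, subcriterion) — e.g. societal
    benefit from a willingness-to-pay survey — which override any panel
    votes on that cell.  A short panel (fewer ballots than
    ``expected_panel``) is logged, not rejected: analyses proceed on the
    ballots that arrived.
    """
    required = {"panelist_id", "component", "criterion", "subcriterion", "score"}
    missing = required - set(ballots.columns)
    if missing:
        raise ValidationError(f"ballot table missing columns: {sorted(missing)}")
    if ballots.empty:
        raise InsufficientDataError("no score ballots")
    if expected_panel is not None:
        n_seen = ballots["panelist_id"].nunique()
        if n_seen < expected_panel:
            logger.warning(
                "only %d of %d expected panelists returned ballots", n_seen, expected_panel
            )

    external = dict(external_scores or {})
    components = list(ballots["component"].drop_duplicates())
    columns = list(tree.overall_subweights())

    med = (
        ballots.groupby(["component", "criterion", "subcriterion"])["score"]
        .apply(lambda v: median_score(v.tolist()))
        .to_dict()
    )
    med.update({k: float(v) for k, v in external.items()})

    sub = pd.DataFrame(index=components, columns=pd.MultiIndex.from_tuples(columns), dtype=float)
    for comp in components:
        for crit, subc in columns:
            key = (comp, crit, subc)
            if key not in med:
                raise ValidationError(f"no score for {key}")
            sub.loc[comp, (crit, subc)] = med[key]

    crit_frame = pd.DataFrame(index=components, columns=tree.criterion_names, dtype=float)
    for comp in components:
        for crit in tree.criterion_names:
            sub_scores = {s: sub.loc[comp, (crit, s)] for c, s in columns if c == crit}
            crit_frame.loc[comp, crit] = criterion_score(sub_scores, tree, crit)

    final = crit_frame.apply(lambda row: final_weighted_score(row.to_dict(), tree), axis=1)
    final.name = "final_score"
    return ScoreMatrix(sub_scores=sub, criterion_scores=crit_frame, final_scores=final)


def final_scores_from_criterion_table(
    criterion_scores: pd.DataFrame,
    tree: CriterionTree,
) -> pd.Series:
    """Final weighted scores from an already-aggregated component x criterion table."""
    out = criterion_scores.apply(
        lambda row: final_weighted_score(row.to_dict(), tree), axis=1
    )
    out.name = "final_score"
    return out
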