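"""Marginal analysis: cost-neutral portfolio selection and the panel vote.

Candidate changes at the margin come in three kinds: *investments* (new
services), *disinvestments* (current services that could be scaled back
or stopped) and *efficiency* components (same service volume at lower
cost).  Efficiency components are assumed implemented, so their released
resource augments the investable budget.  A portfolio is feasible when
the money released by the selected disinvestments plus the efficiency
release covers the cost of the selected investments (no overspend).

Each panelist submits one feasible portfolio; a component is "funded" on
a ballot when it is a selected investment, or a current service NOT
selected for disinvestment.  Components with at least a threshold number
of funding votes (6 of 9 in the bundled case study) are recommended:
Invest / No investment for new services, Continue / Disinvest for
current ones.

Components are nondivisible by default: evidence and scores were elicited
for whole programs, so funding part of one would invalidate its score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SizeError, ValidationError

logger = logging.getLogger(__name__)

#: maximum non-efficiency components for exhaustive enumeration (2^n scan)
MAX_ENUMERATION = 25

KINDS = {"investment", "disinvestment", "efficiency"}
DECISIONS = ("Invest", "No investment", "Continue", "Disinvest")


@dataclass(frozen=True)
class ProgramComponent:
    """A discrete candidate service change with an annual cost in GBP millions."""

    id: str
    name: str
    kind: str  # investment | disinvestment | efficiency
    cost_gbp_m: float  # for efficiency components: GBP millions released
    currently_provided: bool
    final_score: float = float("nan")
    divisible: bool = False
    exclusion_group: str | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"component {self.id}: unknown kind {self.kind!r}")
        if self.cost_gbp_m < 0:
            raise ValidationError(f"component {self.id}: negative cost")
        if self.kind == "investment" and self.currently_provided:
            raise ValidationError(
                f"component {self.id}: an investment cannot already be provided"
            )
        if self.kind == "disinvestment" and not self.currently_provided:
            raise ValidationError(
                f"component {self.id}: a disinvestment must be currently provided"
            )
        if self.divisible:
            warnings.warn(
                f"component {self.id} marked divisible: scores were elicited for "
                "whole programs, so partial funding may invalidate them",
                stacklevel=2,
            )


class Registry:
    """The set of components under consideration, keyed by id."""

    def __init__(self, components: Sequence[ProgramComponent]):
        ids = [c.id for c in components]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate component ids in registry")
        self._components = {c.id: c for c in components}

    def __getitem__(self, component_id: str) -> ProgramComponent:
        try:
            return self._components[component_id]
        except KeyError:
            raise ValidationError(f"unknown component id {component_id!r}") from None

    def __iter__(self):
        return iter(self._components.values())

    def __len__(self) -> int:
        return len(self._components)

    def __contains__(self, component_id: str) -> bool:
        return component_id in self._components

    @property
    def investments(self) -> list[ProgramComponent]:
        return [c for c in self if c.kind == "investment"]

    @property
    def disinvestments(self) -> list[ProgramComponent]:
        return [c for c in self if c.kind == "disinvestment"]

    @property
    def efficiency_components(self) -> list[ProgramComponent]:
        return [c for c in self if c.kind == "efficiency"]

    def efficiency_release(self) -> float:
        """Total GBP millions released by the (auto-applied) efficiency components."""
        return sum(c.cost_gbp_m for c in self.efficiency_components)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Registry":
        required = {"component_id", "name", "kind", "cost_gbp_m", "currently_provided"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"registry table missing columns: {sorted(missing)}")
        components = []
        for row in frame.to_dict("records"):
            components.append(
                ProgramComponent(
                    id=str(row["component_id"]),
                    name=str(row["name"]),
                    kind=str(row["kind"]),
                    cost_gbp_m=float(row["cost_gbp_m"]),
                    currently_provided=_as_bool(row["currently_provided"]),
                    final_score=float(row.get("final_score", float("nan"))),
                    exclusion_group=(
                        str(row["exclusion_group"])
                        if row.get("exclusion_group") not in (None, "", float("nan"))
                        and pd.notna(row.get("exclusion_group"))
                        else None
                    ),
                )
            )
        return cls(components)

    @classmethod
    def from_csv(cls, path) -> "Registry":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component_id": [c.id for c in self],
                "name": [c.name for c in self],
                "kind": [c.kind for c in self],
                "cost_gbp_m": [c.cost_gbp_m for c in self],
                "currently_provided": [c.currently_provided for c in self],
                "final_score": [c.final_score for c in self],
            }
        )


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        return value.strip().lower() in {"true", "yes", "1"}
    return bool(value)


@dataclass(frozen=True)
class Portfolio:
    """One selection of changes: investments to fund, current services to stop."""

    selected_investments: frozenset[str] = frozenset()
    selected_disinvestments: frozenset[str] = frozenset()
    efficiency_release_gbp_m: float = 0.0

    def funds(self, component: ProgramComponent) -> bool:
        """Does this portfolio fund the component?

        An investment is funded when selected; a current service is funded
        when retained, i.e. NOT selected for disinvestment.
        """
        if component.kind == "investment":
            return component.id in self.selected_investments
        if component.kind == "disinvestment":
            return component.id not in self.selected_disinvestments
        return True  # efficiency components are always implemented


def portfolio_feasible(
    portfolio: Portfolio, registry: Registry
) -> tuple[bool, float]:
    """Cost-neutrality check: (feasible, residual budget in GBP millions).

    residual = released by disinvestments + efficiency release - invested;
    the portfolio is feasible iff the residual is nonnegative.
    """
    invested = 0.0
    for cid in portfolio.selected_investments:
        component = registry[cid]
        if component.kind != "investment":
            raise ValidationError(f"{cid!r} selected as investment but is {component.kind}")
        invested += component.cost_gbp_m
    released = 0.0
    for cid in portfolio.selected_disinvestments:
        component = registry[cid]
        if component.kind != "disinvestment":
            raise ValidationError(
                f"{cid!r} selected as disinvestment but is {component.kind}"
            )
        released += component.cost_gbp_m
    residual = released + portfolio.efficiency_release_gbp_m - invested
    return residual >= 0, residual


def _violates_exclusion(registry: Registry, selected: frozenset[str]) -> bool:
    groups: dict[str, int] = {}
    for cid in selected:
        group = registry[cid].exclusion_group
        if group is not None:
            groups[group] = groups.get(group, 0) + 1
            if groups[group] > 1:
                return True
    return False


def enumerate_feasible(
    registry: Registry,
    efficiency_release_gbp_m: float = 0.0,
    pareto_only: bool = False,
) -> list[tuple[Portfolio, float]]:
    """Exhaustive scan of all 2^n portfolios; returns the feasible ones.

    Each result pairs a portfolio with its residual budget.  Portfolios
    selecting more than one member of an exclusion group (mutually
    exclusive alternatives, e.g. overlapping orthodontic eligibility
    tiers) are dropped.  With ``pareto_only`` the list is filtered to
    portfolios undominated on (total final score of the funded set,
    residual budget).
    """
    investments = registry.investments
    disinvestments = registry.disinvestments
    n = len(investments) + len(disinvestments)
    if n > MAX_ENUMERATION:
        raise SizeError(
            f"{n} components is too many for exhaustive enumeration "
            f"(limit {MAX_ENUMERATION}); split the registry or pre-filter candidates"
        )
    results = []
    inv_ids = [c.id for c in investments]
    dis_ids = [c.id for c in disinvestments]
    for r_inv in range(len(inv_ids) + 1):
        for inv_subset in combinations(inv_ids, r_inv):
            for r_dis in range(len(dis_ids) + 1):
                for dis_subset in combinations(dis_ids, r_dis):
                    portfolio = Portfolio(
                        frozenset(inv_subset),
                        frozenset(dis_subset),
                        efficiency_release_gbp_m,
                    )
                    selected = portfolio.selected_investments | portfolio.selected_disinvestments
                    if _violates_exclusion(registry, selected):
                        continue
                    feasible, residual = portfolio_feasible(portfolio, registry)
                    if feasible:
                        results.append((portfolio, residual))
    if pareto_only:
        results = _pareto_filter(results, registry)
    return results


def _funded_score(portfolio: Portfolio, registry: Registry) -> float:
    return sum(
        c.final_score
        for c in registry
        if c.kind != "efficiency" and portfolio.funds(c)
    )


def _pareto_filter(
    results: list[tuple[Portfolio, float]], registry: Registry
) -> list[tuple[Portfolio, float]]:
    scored = [(p, r, _funded_score(p, registry)) for p, r in results]
    kept = []
    for p, r, s in scored:
        dominated = any(
            (s2 >= s and r2 >= r) and (s2 > s or r2 > r) for _, r2, s2 in scored
        )
        if not dominated:
            kept.append((p, r))
    return kept


@dataclass(frozen=True)
class Ballotbox:
    """Funding votes per component, out of ``n_voters`` returned ballots."""

    votes_for_funding: Mapping[str, int]
    n_voters: int

    def __post_init__(self):
        for cid, votes in self.votes_for_funding.items():
            if not 0 <= votes <= self.n_voters:
                raise ValidationError(
                    f"component {cid}: {votes} votes out of {self.n_voters} voters"
                )


def tally_votes(ballots: Iterable[Portfolio], registry: Registry) -> Ballotbox:
    """Count, per component, how many submitted portfolios fund it.

    Infeasible ballots are counted but logged — the vote stands, the
    overspend is the submitter's to answer for.
    """
    ballots = list(ballots)
    counted = {c.id: 0 for c in registry if c.kind != "efficiency"}
    for i, ballot in enumerate(ballots):
        feasible, residual = portfolio_feasible(ballot, registry)
        if not feasible:
            logger.warning("ballot %d is infeasible (residual %.1f GBP m)", i, residual)
        for component in registry:
            if component.kind != "efficiency" and ballot.funds(component):
                counted[component.id] += 1
    return Ballotbox(votes_for_funding=counted, n_voters=len(ballots))


@dataclass(frozen=True)
class Recommendation:
    """Final funding decision per component plus the unspent budget."""

    decisions: Mapping[str, str]  # component id -> Invest/No investment/Continue/Disinvest
    residual_budget_gbp_m: float = field(default=float("nan"))


def apply_decision_rule(
    box: Ballotbox, registry: Registry, threshold: int = 6
) -> Recommendation:
    """Threshold rule: components with >= ``threshold`` funding votes are funded.

    Funded new services -> Invest, otherwise No investment; funded current
    services -> Continue, otherwise Disinvest.  A tie at exactly the
    threshold counts as funded (the rule is "threshold or more").
    """
    if threshold < -(-box.n_voters // 2):  # ceil(n/2)
        warnings.warn(
            f"threshold {threshold} is below a majority of {box.n_voters} voters",
            stacklevel=2,
        )
    decisions = {}
    for component in registry:
        if component.kind == "efficiency":
            continue
        if component.id not in box.votes_for_funding:
            raise ValidationError(f"component {component.id} missing from the ballot box")
        funded = box.votes_for_funding[component.id] >= threshold
        if component.currently_provided:
            decisions[component.id] = "Continue" if funded else "Disinvest"
        else:
            decisions[component.id] = "Invest" if funded else "No investment"
    return Recommendation(decisions=decisions)


def residual_after_recommendation(
    recommendation: Recommendation,
    registry: Registry,
    efficiency_release_gbp_m: float = 0.0,
) -> float:
    """Unspent budget once the recommended changes are enacted (GBP millions)."""
    released = sum(
        registry[cid].cost_gbp_m
        for cid, decision in recommendation.decisions.items()
        if decision == "Disinvest"
    )
    invested = sum(
        registry[cid].cost_gbp_m
        for cid, decision in recommendation.decisions.items()
        if decision == "Invest"
    )
    return released + efficiency_release_gbp_m - invested
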