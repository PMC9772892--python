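"""Pipeline orchestration, fixture I/O and report rendering.

A run consumes a directory of CSV inputs (a *fixture*) and produces a
report bundle: program-budget table, elicited criterion weights, the
score matrix, the recommendation table and a sensitivity annex, plus a
JSON manifest recording input hashes, configuration and strategy names
so identical inputs give identical outputs.

CSV dialect: UTF-8, comma-separated, "." decimal, mandatory header row;
monetary columns are suffixed ``_gbp`` or ``_gbp_m``.  All persisted
intermediate tables are full precision — rounding (weights 1 dp, scores
2 dp, budget shares below 1% shown as "<1") happens only in the
human-readable rendering.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__, case_study
from .budget import budget_table, breakdown_gds_spend, ClaimsRecord, extrapolate_national_spend, returns_from_frame
from .errors import ValidationError
from .marginal import Portfolio, Registry, apply_decision_rule, residual_after_recommendation, tally_votes
from .scoring import ScoreMatrix, score_matrix_from_ballots
from .sensitivity import SensitivitySpec, threshold_sweep, weight_sensitivity
from .weights import CriterionTree, allocations_from_frame, build_tree
from .wtp import societal_values

logger = logging.getLogger("pbma")
if not logger.handlers:  # stage-tagged lines to standard error
    _handler = logging.StreamHandler(sys.stderr)
    _handler.setFormatter(logging.Formatter("pbma [%(levelname)s] %(message)s"))
    logger.addHandler(_handler)

FIXTURE_FILES = {
    "main_allocations": "main_allocations.csv",
    "sub_allocations": "sub_allocations.csv",
    "score_ballots": "score_ballots.csv",
    "wtp_responses": "wtp_responses.csv",
    "regional_returns": "regional_returns.csv",
    "claims": "claims.csv",
    "registry": "component_registry.csv",
    "vote_ballots": "vote_ballots.csv",
}


class PipelineConfig(BaseModel):
    """Paths and parameters for one full pipeline run."""

    fixture_dir: Path
    national_population: int = Field(56_000_000, gt=0)
    correction_factor: float = Field(1.0, gt=0)
    efficiency_release_gbp_m: float = Field(0.0, ge=0)
    vote_threshold: int = Field(6, ge=1)
    wtp_trim: float = Field(0.0, ge=0, lt=0.5)
    benefit_mapping: str = "minmax"  # aggregate WTP -> -2..+2
    cost_benefit_mapping: str = "net_benefit_linear"
    societal_benefit_cell: tuple[str, str] | None = (
        "Benefit",
        "Societal benefit (WTP survey)",
    )
    cost_benefit_cell: tuple[str, str] | None = (
        "Cost-benefit",
        "Total cost less societal benefit",
    )
    sensitivity_draws: int = Field(1000, ge=1)
    sensitivity_concentration: float = Field(100.0, gt=0)
    seed: int = 0

    def path(self, key: str) -> Path:
        return Path(self.fixture_dir) / FIXTURE_FILES[key]


@dataclass
class ReportBundle:
    """All tables produced by one run, plus the run manifest."""

    budget: pd.DataFrame
    gds_breakdown: pd.DataFrame | None
    tree: CriterionTree
    societal: pd.DataFrame
    scores: ScoreMatrix
    recommendations: pd.DataFrame
    residual_budget_gbp_m: float
    sensitivity: pd.DataFrame
    thresholds: pd.DataFrame
    manifest: dict

    def write(self, out_dir, formats: tuple[str, ...] = ("csv",)) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "budget_table": self.budget,
            "criterion_weights": self.tree.to_frame(),
            "societal_values": self.societal,
            "criterion_scores": self.scores.criterion_scores,
            "final_scores": self.scores.final_scores.to_frame(),
            "recommendations": self.recommendations,
            "sensitivity": self.sensitivity.drop(columns=["rank_probs"]),
            "threshold_sweep": self.thresholds,
        }
        if self.gds_breakdown is not None:
            tables["gds_breakdown"] = self.gds_breakdown
        if "csv" in formats:
            for name, frame in tables.items():
                frame.to_csv(out / f"{name}.csv")
        if "txt" in formats:
            with open(out / "report.txt", "w", encoding="utf-8") as fh:
                fh.write(render_text(self))
        if "json" in formats:
            with open(out / "tables.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {name: json.loads(frame.to_json(orient="split")) for name, frame in tables.items()},
                    fh,
                    indent=1,
                    sort_keys=True,
                )
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in order on one fixture directory.

    budget -> weight elicitation -> WTP aggregation -> panel scoring ->
    marginal analysis (vote tally + decision rule) -> sensitivity.
    Stage failures propagate with the stage name prefixed.
    """
    hashes = {}
    for key, fname in FIXTURE_FILES.items():
        p = config.path(key)
        if p.exists():
            hashes[fname] = _sha256(p)
        elif key != "claims":  # claims breakdown is optional
            raise ValidationError(f"missing input file: {p}")

    try:
        _stage("program_budget")
        returns = returns_from_frame(pd.read_csv(config.path("regional_returns")))
        national = extrapolate_national_spend(returns, config.national_population)
        budget = budget_table(national)
        budget.attrs["extrapolation"] = (
            "unweighted per-capita mean over responding regions x national population; "
            "applied identically to NHS and local-authority lines"
        )
        gds = None
        if config.path("claims").exists():
            claims_frame = pd.read_csv(config.path("claims"))
            claims = [
                ClaimsRecord(str(r["treatment_type"]), int(r["item_count"]), float(r["mean_fee"]))
                for r in claims_frame.to_dict("records")
            ]
            spend = breakdown_gds_spend(claims, config.correction_factor)
            gds = budget_table(spend).rename(columns={"service_line": "treatment_type"})

        _stage("weight_elicitation")
        main = allocations_from_frame(pd.read_csv(config.path("main_allocations")))
        sub_frame = pd.read_csv(config.path("sub_allocations"))
        subs = {
            str(crit): allocations_from_frame(block)
            for crit, block in sub_frame.groupby("criterion", sort=False)
        }
        tree = build_tree(main, subs)

        _stage("marginal_analysis: registry")
        registry = Registry.from_frame(pd.read_csv(config.path("registry")))
        costs = {c.id: c.cost_gbp_m for c in registry if c.kind != "efficiency"}

        _stage("wtp_survey")
        responses = pd.read_csv(config.path("wtp_responses"))
        societal = societal_values(
            responses,
            population=config.national_population,
            costs_gbp_m=costs,
            trim=config.wtp_trim,
        )
        societal.attrs["aggregation"] = (
            "complete-case mean WTP scaled to population (GBP M/year); "
            f"benefit mapping: {config.benefit_mapping}; "
            f"cost-benefit mapping: {config.cost_benefit_mapping}"
        )

        _stage("panel_scoring")
        ballots = pd.read_csv(config.path("score_ballots"))
        external = {}
        if config.societal_benefit_cell is not None:
            crit, sub = config.societal_benefit_cell
            for comp, score in societal["benefit_score"].items():
                external[(comp, crit, sub)] = float(score)
        if config.cost_benefit_cell is not None and "cost_benefit_score" in societal:
            crit, sub = config.cost_benefit_cell
            for comp, score in societal["cost_benefit_score"].items():
                external[(comp, crit, sub)] = float(score)
        scores = score_matrix_from_ballots(ballots, tree, external_scores=external)

        _stage("marginal_analysis: votes")
        votes_frame = pd.read_csv(config.path("vote_ballots"))
        ballots_by_panelist = _portfolios_from_frame(votes_frame, registry, config)
        box = tally_votes(ballots_by_panelist, registry)
        recommendation = apply_decision_rule(box, registry, threshold=config.vote_threshold)
        residual = residual_after_recommendation(
            recommendation, registry, config.efficiency_release_gbp_m
        )
        rec_table = recommendation_table(registry, box, recommendation, scores.final_scores)

        _stage("sensitivity")
        spec = SensitivitySpec(
            n_draws=config.sensitivity_draws,
            concentration=config.sensitivity_concentration,
            seed=config.seed,
        )
        sens = weight_sensitivity(tree, scores.criterion_scores, spec)
        sweep = threshold_sweep(box, registry, operating_threshold=config.vote_threshold)
    except Exception as exc:
        raise type(exc)(f"pipeline: {exc}") if isinstance(exc, ValidationError) else exc

    manifest = {
        "package_version": __version__,
        "input_sha256": hashes,
        "config": json.loads(config.model_dump_json()),
        "strategies": {
            "weight_aggregation": "mean",
            "score_aggregation": "median -> within-weighted mean -> main-weighted mean",
            "wtp_benefit_mapping": config.benefit_mapping,
            "cost_benefit_mapping": config.cost_benefit_mapping,
        },
        "notes": [
            "per-capita extrapolation applied identically to all lines",
            "WTP 'aggregation' interpreted as population scale-up of the sample mean",
        ],
    }
    return ReportBundle(
        budget=budget,
        gds_breakdown=gds,
        tree=tree,
        societal=societal,
        scores=scores,
        recommendations=rec_table,
        residual_budget_gbp_m=residual,
        sensitivity=sens,
        thresholds=sweep,
        manifest=manifest,
    )


def _portfolios_from_frame(
    frame: pd.DataFrame, registry: Registry, config: PipelineConfig
) -> list[Portfolio]:
    required = {"panelist_id", "component_id", "funded"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"vote ballot table missing columns: {sorted(missing)}")
    out = []
    for _, block in frame.groupby("panelist_id", sort=False):
        funded = {
            str(r["component_id"]): _truthy(r["funded"]) for r in block.to_dict("records")
        }
        invest = frozenset(
            c.id for c in registry.investments if funded.get(c.id, False)
        )
        disinvest = frozenset(
            c.id for c in registry.disinvestments if not funded.get(c.id, True)
        )
        out.append(Portfolio(invest, disinvest, config.efficiency_release_gbp_m))
    return out


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "yes", "1"}
    return bool(value)


def recommendation_table(
    registry: Registry,
    box,
    recommendation,
    final_scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Recommendation report: cost, score, votes and decision per component."""
    rows = []
    for c in registry:
        if c.kind == "efficiency":
            continue
        score = c.final_score
        if final_scores is not None and c.id in final_scores.index:
            score = float(final_scores[c.id])
        rows.append(
            {
                "component_id": c.id,
                "name": c.name,
                "currently_provided": c.currently_provided,
                "cost_gbp_m": c.cost_gbp_m,
                "final_score": score,
                "votes_for_funding": box.votes_for_funding[c.id],
                "decision": recommendation.decisions[c.id],
            }
        )
    return pd.DataFrame(rows).set_index("component_id")


def case_study_bundle(
    efficiency_release_gbp_m: float = 0.0,
    vote_threshold: int = case_study.VOTE_THRESHOLD,
    sensitivity_spec: SensitivitySpec | None = None,
) -> dict:
    """Re-derive the bundled case study's decision tables from its inputs.

    Returns the criterion tree, recomputed final scores, the
    recommendation table and the residual budget; the WTP and budget
    stages are not reproducible for the case study because the underlying
    survey responses and regional returns were never published.
    """
    from .scoring import final_scores_from_criterion_table

    tree = case_study.load_criterion_tree()
    criterion_scores = case_study.load_criterion_scores()
    finals = final_scores_from_criterion_table(criterion_scores, tree)
    registry = case_study.load_registry()
    box = case_study.load_ballotbox()
    recommendation = apply_decision_rule(box, registry, threshold=vote_threshold)
    residual = residual_after_recommendation(
        recommendation, registry, efficiency_release_gbp_m
    )
    spec = sensitivity_spec or SensitivitySpec()
    return {
        "tree": tree,
        "criterion_scores": criterion_scores,
        "final_scores": finals,
        "recommendations": recommendation_table(registry, box, recommendation, finals),
        "residual_budget_gbp_m": residual,
        "sensitivity": weight_sensitivity(tree, criterion_scores, spec),
        "thresholds": threshold_sweep(box, registry, operating_threshold=vote_threshold),
    }


# -- rendering ------------------------------------------------------------


def render_text(bundle: ReportBundle) -> str:
    """Human-readable report: weights at 1 dp, scores at 2 dp, '<1' shares."""
    parts = []
    budget = bundle.budget.copy()
    budget["spend_gbp"] = budget["spend_gbp"].map(lambda v: f"{v:,.0f}")
    budget["share_pct"] = budget["share_display"]
    parts.append("PROGRAM BUDGET\n" + budget.drop(columns="share_display").to_string(index=False))
    weights = bundle.tree.to_frame().copy()
    for col in ("weight_pct", "within_weight_pct", "overall_weight_pct"):
        weights[col] = weights[col].map(lambda v: f"{v:.1f}")
    parts.append("CRITERION WEIGHTS\n" + weights.to_string(index=False))
    finals = bundle.scores.final_scores.map(lambda v: f"{v:.2f}")
    parts.append("FINAL WEIGHTED SCORES\n" + finals.to_string())
    recs = bundle.recommendations.copy()
    recs["final_score"] = recs["final_score"].map(lambda v: f"{v:.2f}")
    parts.append("RECOMMENDATIONS\n" + recs.to_string())
    parts.append(f"RESIDUAL BUDGET: GBP {bundle.residual_budget_gbp_m:.0f}M")
    return "\n\n".join(parts) + "\n"
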