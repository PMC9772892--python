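"""Seeded synthetic panels, ballots, surveys and budget returns.

Everything downstream of data collection is testable without any real
returns: this module draws panel point allocations, integer score
ballots, a zero-inflated willingness-to-pay survey, regional spend
templates and a component registry with the statistical structure the
analysis assumes.

Defaults emulate the bundled case study's conditions: 10 panelists
allocating 100 points over 11 criteria (and 1-6 subcriteria each),
integer -2..+2 scores for 14 components x 24 subcriteria, 339 survey
respondents stating GBP/year amounts per component, and 16 commissioning
regions of which 9 respond.

A single integer seed drives a hierarchy of independent substreams (one
per generator), so any one artifact can be regenerated without drawing
the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import case_study
from .budget import RegionalReturn
from .errors import ConfigurationError
from .marginal import Portfolio, ProgramComponent, Registry
from .weights import PointAllocation

# substream labels: each generator owns one spawn key off the root seed
_STREAMS = {
    "allocations": 0,
    "sub_allocations": 1,
    "scores": 2,
    "wtp": 3,
    "regions": 4,
    "registry": 5,
    "votes": 6,
}

#: default per-capita spend (GBP/head/year) by service line — a realistic
#: national dental budget shape: ~GBP 64/head total, dominated by primary care
DEFAULT_SPEND_PER_CAPITA = {
    "general_dental_practice": 35.2,
    "oral_surgery": 10.2,
    "orthodontics": 7.0,
    "special_care_dentistry": 2.6,
    "out_of_hours": 1.3,
    "restorative_dentistry": 1.3,
    "paediatric_dentistry": 0.6,
    "sedation": 0.3,
    "small_specialties": 0.3,
    "community_and_hospital": 5.8,
    "local_authority": 0.4,
}


def _normalise(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def _default_true_weights() -> dict[str, float]:
    # case-study weights, renormalised (recorded values carry 1-dp rounding)
    return _normalise(case_study.load_criterion_tree().main_weights())


def _default_true_subweights() -> dict[str, dict[str, float]]:
    tree = case_study.load_criterion_tree()
    return {
        c.name: _normalise({s.name: s.within_weight_pct for s in c.subcriteria})
        for c in tree.criteria
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    ``true_weights`` is a probability vector over criteria (sums to 1);
    ``true_scores`` is an optional component x (criterion, subcriterion)
    table of latent scores in [-2, +2] — when omitted, a deterministic
    integer grid covering all five score levels is used.
    """

    n_panelists: int = 10
    n_components: int = 14
    n_respondents: int = 339
    true_weights: dict[str, float] = field(default_factory=_default_true_weights)
    true_subweights: dict[str, dict[str, float]] = field(
        default_factory=_default_true_subweights
    )
    true_scores: pd.DataFrame | None = None
    score_noise_sd: float = 0.5
    wtp_zero_prob: float = 0.25
    wtp_log_mean: float = 3.0  # log-GBP: median stated amount ~ GBP 20/year
    wtp_log_sd: float = 1.0
    spend_per_capita_gbp: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPEND_PER_CAPITA)
    )
    spend_noise_cv: float = 0.1
    region_population: int = 3_500_000
    seed: int = 0

    def __post_init__(self):
        for name in ("n_panelists", "n_components", "n_respondents"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        w = np.asarray(list(self.true_weights.values()), dtype=float)
        if np.any(w < 0) or np.any(w > 1):
            raise ConfigurationError("true_weights entries must be probabilities")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"true_weights sum to {w.sum()!r}, expected 1")
        for crit, subs in self.true_subweights.items():
            s = np.asarray(list(subs.values()), dtype=float)
            if np.any(s < 0) or abs(s.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"true_subweights[{crit!r}] is not a probability vector")
        if not 0.0 <= self.wtp_zero_prob <= 1.0:
            raise ConfigurationError("wtp_zero_prob must be in [0, 1]")
        if self.wtp_log_sd < 0 or self.score_noise_sd < 0 or self.spend_noise_cv < 0:
            raise ConfigurationError("noise parameters must be nonnegative")
        if self.region_population < 1:
            raise ConfigurationError("region_population must be >= 1")
        if self.true_scores is not None:
            vals = self.true_scores.to_numpy(dtype=float)
            if np.any(vals < -2) or np.any(vals > 2):
                raise ConfigurationError("true_scores must lie in [-2, +2]")

    # -- derived structure -------------------------------------------------

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one substream of the root seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    def component_ids(self) -> list[str]:
        return [f"component_{i + 1:02d}" for i in range(self.n_components)]

    def subcriterion_pairs(self) -> list[tuple[str, str]]:
        return [
            (crit, sub)
            for crit, subs in self.true_subweights.items()
            for sub in subs
        ]

    def resolve_true_scores(self) -> pd.DataFrame:
        """Latent score table; the default grid cycles through -2..+2."""
        if self.true_scores is not None:
            return self.true_scores
        pairs = self.subcriterion_pairs()
        data = [
            [((i + j) % 5) - 2 for j in range(len(pairs))]
            for i in range(self.n_components)
        ]
        return pd.DataFrame(
            data,
            index=self.component_ids(),
            columns=pd.MultiIndex.from_tuples(pairs),
            dtype=float,
        )


# -- generators -----------------------------------------------------------


def _multinomial_allocations(
    rng: np.random.Generator,
    n_panelists: int,
    items: Sequence[str],
    probabilities: Sequence[float],
    prefix: str = "panelist",
) -> list[PointAllocation]:
    draws = rng.multinomial(100, list(probabilities), size=n_panelists)
    return [
        PointAllocation(
            panelist_id=f"{prefix}_{i + 1:02d}",
            points=dict(zip(items, row.astype(float).tolist())),
        )
        for i, row in enumerate(draws)
    ]


def generate_panel_allocations(config: SyntheticConfig) -> list[PointAllocation]:
    """Main-criterion 100-point ballots: multinomial(100, true_weights).

    The multinomial guarantees every ballot is a nonnegative integer
    vector totalling exactly 100, the constraint the elicitation enforces.
    """
    rng = config.rng("allocations")
    items = list(config.true_weights)
    return _multinomial_allocations(
        rng, config.n_panelists, items, list(config.true_weights.values())
    )


def generate_subcriterion_allocations(
    config: SyntheticConfig,
) -> dict[str, list[PointAllocation]]:
    """Per-criterion 100-point ballots over that criterion's subcriteria."""
    rng = config.rng("sub_allocations")
    out = {}
    for crit, subs in config.true_subweights.items():
        out[crit] = _multinomial_allocations(
            rng, config.n_panelists, list(subs), list(subs.values())
        )
    return out


def _round_half_away(values: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(values) + 0.5), values)


def generate_score_ballots(config: SyntheticConfig) -> pd.DataFrame:
    """Integer -2..+2 ballots: true score + Gaussian noise, rounded, clamped.

    Returns a tidy frame (panelist_id, component, criterion, subcriterion,
    score).  Rounding is half-away-from-zero; at zero noise and integer
    true scores every ballot reproduces the truth exactly.
    """
    rng = config.rng("scores")
    truth = config.resolve_true_scores()
    pairs = list(truth.columns)
    records = []
    for p in range(config.n_panelists):
        noise = rng.normal(0.0, config.score_noise_sd, size=truth.shape)
        noisy = np.clip(_round_half_away(truth.to_numpy() + noise), -2, 2)
        for i, comp in enumerate(truth.index):
            for j, (crit, sub) in enumerate(pairs):
                records.append(
                    {
                        "panelist_id": f"panelist_{p + 1:02d}",
                        "component": comp,
                        "criterion": crit,
                        "subcriterion": sub,
                        "score": int(noisy[i, j]),
                    }
                )
    return pd.DataFrame.from_records(records)


def generate_wtp_survey(config: SyntheticConfig) -> pd.DataFrame:
    """Zero-inflated log-normal stated WTP per respondent x component.

    Each response is 0 with probability ``wtp_zero_prob`` (a genuine
    zero valuation), otherwise exp(N(wtp_log_mean, wtp_log_sd)) GBP/year.
    Returns a tidy frame (respondent_id, component, wtp_gbp_per_year).
    """
    rng = config.rng("wtp")
    components = config.component_ids()
    n = config.n_respondents * len(components)
    zeros = rng.random(n) < config.wtp_zero_prob
    amounts = np.exp(rng.normal(config.wtp_log_mean, config.wtp_log_sd, size=n))
    wtp = np.where(zeros, 0.0, amounts)
    respondent = np.repeat(
        [f"respondent_{i + 1:04d}" for i in range(config.n_respondents)], len(components)
    )
    return pd.DataFrame(
        {
            "respondent_id": respondent,
            "component": np.tile(components, config.n_respondents),
            "wtp_gbp_per_year": wtp,
        }
    )


def generate_regional_returns(
    config: SyntheticConfig,
    n_regions: int = 16,
    respond_fraction: float = 9 / 16,
) -> list[RegionalReturn]:
    """Spend templates from the responding subset of regions.

    Each responding region reports population x per-capita line mean,
    perturbed by multiplicative Gaussian noise with coefficient of
    variation ``spend_noise_cv`` (floored at zero spend).
    """
    if not 0 < respond_fraction <= 1:
        raise ConfigurationError("respond_fraction must be in (0, 1]")
    rng = config.rng("regions")
    n_responding = max(1, int(round(respond_fraction * n_regions)))
    responders = sorted(rng.choice(n_regions, size=n_responding, replace=False).tolist())
    lines = list(config.spend_per_capita_gbp)
    out = []
    for r in responders:
        noise = rng.normal(1.0, config.spend_noise_cv, size=len(lines))
        spends = {
            line: max(0.0, config.region_population * config.spend_per_capita_gbp[line] * f)
            for line, f in zip(lines, noise)
        }
        out.append(
            RegionalReturn(
                region_id=f"region_{r + 1:02d}",
                population=config.region_population,
                spend_by_line=spends,
            )
        )
    return out


def generate_component_registry(config: SyntheticConfig) -> Registry:
    """A synthetic registry: half new investments, half current services.

    Annual costs are log-normal (median ~GBP 50M, a realistic spread for
    national program components); final scores are left NaN — they come
    from the scoring stage.
    """
    rng = config.rng("registry")
    ids = config.component_ids()
    n_invest = math.ceil(config.n_components / 2)
    costs = np.exp(rng.normal(np.log(50.0), 1.0, size=config.n_components))
    components = []
    for i, cid in enumerate(ids):
        invest = i < n_invest
        components.append(
            ProgramComponent(
                id=cid,
                name=cid.replace("_", " "),
                kind="investment" if invest else "disinvestment",
                cost_gbp_m=float(round(costs[i], 1)),
                currently_provided=not invest,
            )
        )
    return Registry(components)


def true_final_scores(config: SyntheticConfig) -> pd.Series:
    """Final weighted score implied by the latent truth (single pass:
    sum of overall subcriterion weight x true score)."""
    truth = config.resolve_true_scores()
    out = {}
    for comp in truth.index:
        total = 0.0
        for (crit, sub) in truth.columns:
            overall = config.true_weights[crit] * config.true_subweights[crit][sub]
            total += overall * truth.loc[comp, (crit, sub)]
        out[comp] = total
    return pd.Series(out, name="final_score")


def greedy_portfolio(
    registry: Registry,
    scores: Mapping[str, float],
    efficiency_release_gbp_m: float = 0.0,
) -> Portfolio:
    """A plausible individual ballot: stop negative-scoring current
    services, then fund the best-scoring new services that fit the
    released budget (whole components only, best score first)."""
    disinvest = frozenset(
        c.id for c in registry.disinvestments if scores.get(c.id, 0.0) < 0
    )
    budget = efficiency_release_gbp_m + sum(
        registry[cid].cost_gbp_m for cid in disinvest
    )
    invest = set()
    candidates = sorted(
        (c for c in registry.investments if scores.get(c.id, 0.0) > 0),
        key=lambda c: scores[c.id],
        reverse=True,
    )
    for c in candidates:
        if c.cost_gbp_m <= budget:
            invest.add(c.id)
            budget -= c.cost_gbp_m
    return Portfolio(frozenset(invest), disinvest, efficiency_release_gbp_m)


def generate_vote_ballots(
    config: SyntheticConfig,
    registry: Registry,
    final_scores: Mapping[str, float],
    score_jitter_sd: float = 0.0,
    efficiency_release_gbp_m: float = 0.0,
) -> list[Portfolio]:
    """One feasible portfolio per panelist, greedy on (jittered) scores.

    With ``score_jitter_sd`` = 0 every panelist submits the identical
    portfolio implied by the final scores, so downstream decisions are
    unanimous and exactly recoverable.
    """
    rng = config.rng("votes")
    ballots = []
    for _ in range(config.n_panelists):
        jittered = {
            cid: s + (rng.normal(0.0, score_jitter_sd) if score_jitter_sd > 0 else 0.0)
            for cid, s in final_scores.items()
        }
        ballots.append(greedy_portfolio(registry, jittered, efficiency_release_gbp_m))
    return ballots


# -- fixture emission ------------------------------------------------------

#: deterministic synthetic claims table for the primary-care breakdown
SYNTHETIC_CLAIMS = [
    ("examination", 38_000_000, 12.0),
    ("restorations", 16_000_000, 25.0),
    ("scale_and_polish", 14_000_000, 13.0),
    ("dentures", 1_900_000, 95.0),
    ("crowns", 1_300_000, 95.0),
    ("radiographs", 12_000_000, 10.0),
    ("extractions", 3_100_000, 30.0),
    ("fluoride_varnish", 6_300_000, 10.0),
]


def write_fixture(
    config: SyntheticConfig,
    out_dir,
    n_regions: int = 16,
    respond_fraction: float = 9 / 16,
    efficiency_release_gbp_m: float = 0.0,
    vote_jitter_sd: float | None = None,
) -> dict[str, "Path"]:
    """Emit a complete fixture directory in the schemas the pipeline reads.

    ``vote_jitter_sd`` defaults to ``score_noise_sd``; at zero the panel
    is unanimous and the generator's implied decisions are exactly
    recoverable downstream.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    main = generate_panel_allocations(config)
    paths["main_allocations"] = out / "main_allocations.csv"
    pd.DataFrame(
        [
            {"panelist_id": a.panelist_id, "item": item, "points": pts}
            for a in main
            for item, pts in a.points.items()
        ]
    ).to_csv(paths["main_allocations"], index=False)

    subs = generate_subcriterion_allocations(config)
    paths["sub_allocations"] = out / "sub_allocations.csv"
    pd.DataFrame(
        [
            {"criterion": crit, "panelist_id": a.panelist_id, "item": item, "points": pts}
            for crit, allocs in subs.items()
            for a in allocs
            for item, pts in a.points.items()
        ]
    ).to_csv(paths["sub_allocations"], index=False)

    paths["score_ballots"] = out / "score_ballots.csv"
    generate_score_ballots(config).to_csv(paths["score_ballots"], index=False)

    paths["wtp_responses"] = out / "wtp_responses.csv"
    generate_wtp_survey(config).to_csv(paths["wtp_responses"], index=False)

    returns = generate_regional_returns(config, n_regions, respond_fraction)
    lines = list(config.spend_per_capita_gbp)
    paths["regional_returns"] = out / "regional_returns.csv"
    pd.DataFrame(
        [
            {"region_id": r.region_id, "population": r.population,
             **{line: r.spend_by_line[line] for line in lines}}
            for r in returns
        ]
    ).to_csv(paths["regional_returns"], index=False)

    paths["claims"] = out / "claims.csv"
    pd.DataFrame(
        SYNTHETIC_CLAIMS, columns=["treatment_type", "item_count", "mean_fee"]
    ).to_csv(paths["claims"], index=False)

    registry = generate_component_registry(config)
    paths["registry"] = out / "component_registry.csv"
    registry.to_frame().to_csv(paths["registry"], index=False)

    finals = true_final_scores(config)
    jitter = config.score_noise_sd if vote_jitter_sd is None else vote_jitter_sd
    ballots = generate_vote_ballots(
        config, registry, finals.to_dict(), jitter, efficiency_release_gbp_m
    )
    paths["vote_ballots"] = out / "vote_ballots.csv"
    pd.DataFrame(
        [
            {
                "panelist_id": f"panelist_{i + 1:02d}",
                "component_id": c.id,
                "funded": ballot.funds(c),
            }
            for i, ballot in enumerate(ballots)
            for c in registry
            if c.kind != "efficiency"
        ]
    ).to_csv(paths["vote_ballots"], index=False)
    return paths
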