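"""Bundled case study: a national NHS dental priority-setting exercise.

The package ships the published decision inputs of a whole-country PBMA
for NHS dentistry in England (2015-2016 budget year): the panel-elicited
criterion weights (11 main criteria, 24 subcriteria), the panel's
criterion-level scores for 14 candidate program components, and the
component registry with annual costs (GBP millions), funding votes from
the 9 returned ballots, and the recorded decisions.  These small tables
serve as the worked example and as reference data for the test suite.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .marginal import Ballotbox, Registry
from .weights import CriterionTree

N_VOTERS = 9  # 10 panelists, one of whom never returned a final ballot
VOTE_THRESHOLD = 6


def _read(name: str) -> pd.DataFrame:
    with resources.files("pbma.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_criterion_tree() -> CriterionTree:
    """The elicited two-level criterion weighting structure."""
    frame = _read("criteria_weights.csv")
    return CriterionTree.from_frame(frame)


def recorded_overall_subweights() -> dict[tuple[str, str], float]:
    """Overall subcriterion weights as recorded in the exercise (1 dp)."""
    frame = _read("criteria_weights.csv")
    return {
        (str(r["criterion"]), str(r["subcriterion"])): float(
            r["recorded_overall_weight_pct"]
        )
        for r in frame.to_dict("records")
    }


def load_criterion_scores() -> pd.DataFrame:
    """Component x criterion score table (criterion-level panel medians,
    weighted within criterion), indexed by component id."""
    frame = _read("component_criterion_scores.csv").set_index("component_id")
    return frame.drop(columns=["recorded_final_score"])


def recorded_final_scores() -> pd.Series:
    """Final weighted scores as recorded in the exercise (2 dp)."""
    frame = _read("component_criterion_scores.csv").set_index("component_id")
    return frame["recorded_final_score"]


def load_registry() -> Registry:
    """The 14 non-efficiency program components with costs and final scores."""
    return Registry.from_frame(_read("component_registry.csv"))


def load_ballotbox() -> Ballotbox:
    """Funding votes per component from the 9 returned final ballots."""
    frame = _read("component_registry.csv")
    votes = {
        str(r["component_id"]): int(r["votes_for_funding"])
        for r in frame.to_dict("records")
    }
    return Ballotbox(votes_for_funding=votes, n_voters=N_VOTERS)


def recorded_decisions() -> dict[str, str]:
    """The recorded funding decision per component."""
    frame = _read("component_registry.csv")
    return {
        str(r["component_id"]): str(r["recorded_decision"])
        for r in frame.to_dict("records")
    }
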