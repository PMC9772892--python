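"""Sensitivity analysis over the decision pipeline.

The elicited weights and the vote threshold are both judgment calls, so
two checks are provided:

* probabilistic weight sensitivity — main-criterion weights are resampled
  from a Dirichlet centred on the elicited weights (which preserves the
  100-point simplex by construction), final scores and ranks recomputed
  per draw, and per-component distributions summarised;
* a deterministic threshold sweep — the decision rule applied at every
  possible threshold, flagging components whose decision flips within
  one vote of the operating threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .marginal import Ballotbox, Recommendation, Registry, apply_decision_rule
from .weights import CriterionTree

_PERCENTILES = (2.5, 97.5)


@dataclass(frozen=True)
class SensitivitySpec:
    """Monte-Carlo settings for weight sensitivity.

    ``concentration`` scales the Dirichlet: alpha = concentration x
    (weight/100).  Large values mean tight resampling around the elicited
    weights; ``None`` (or infinity) degenerates to the point estimate.
    """

    n_draws: int = 1000
    concentration: float | None = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")
        if self.concentration is not None and self.concentration <= 0:
            raise ValidationError("concentration must be positive")


def _nearest_rank(sorted_values: np.ndarray, pct: float) -> float:
    n = len(sorted_values)
    k = max(1, int(np.ceil(pct / 100.0 * n)))
    return float(sorted_values[k - 1])


def weight_sensitivity(
    tree: CriterionTree,
    criterion_scores: pd.DataFrame,
    spec: SensitivitySpec,
) -> pd.DataFrame:
    """Distribution of final scores and ranks under weight uncertainty.

    ``criterion_scores`` is a component x criterion table.  Returns a
    frame indexed by component with the point estimate, the Monte-Carlo
    mean, nearest-rank 2.5/97.5 percentiles, P(final score > 0) and
    P(rank 1); a ``rank_probs`` column holds the full rank distribution.
    """
    missing = set(tree.criterion_names) - set(criterion_scores.columns)
    if missing:
        raise ValidationError(f"criterion score table missing criteria: {sorted(missing)}")
    scores = criterion_scores[tree.criterion_names].to_numpy(dtype=float)
    weights = np.array([c.weight_pct for c in tree.criteria]) / 100.0
    components = list(criterion_scores.index)
    point = scores @ weights

    rng = np.random.default_rng(spec.seed)
    if spec.concentration is None or np.isinf(spec.concentration):
        draws = np.tile(weights, (spec.n_draws, 1))
    else:
        draws = rng.dirichlet(spec.concentration * weights, size=spec.n_draws)
    finals = draws @ scores.T  # n_draws x n_components
    # rank 1 = highest final score in that draw
    order = (-finals).argsort(axis=1).argsort(axis=1) + 1

    rows = []
    for j, comp in enumerate(components):
        samples = np.sort(finals[:, j])
        rank_counts = np.bincount(order[:, j], minlength=len(components) + 1)[1:]
        rows.append(
            {
                "component": comp,
                "point_estimate": point[j],
                "mean": float(finals[:, j].mean()),
                "p2.5": _nearest_rank(samples, _PERCENTILES[0]),
                "p97.5": _nearest_rank(samples, _PERCENTILES[1]),
                "prob_positive": float((finals[:, j] > 0).mean()),
                "prob_rank_1": float(rank_counts[0] / spec.n_draws),
                "rank_probs": (rank_counts / spec.n_draws).tolist(),
            }
        )
    return pd.DataFrame(rows).set_index("component")


def threshold_sweep(
    box: Ballotbox,
    registry: Registry,
    operating_threshold: int = 6,
) -> pd.DataFrame:
    """Decisions at every threshold 1..n_voters, with near-flip flags.

    A component is flagged when its decision at ``operating_threshold``
    differs from its decision at an adjacent threshold (one vote either
    way) — those are the recommendations that hang on a single ballot.
    """
    import warnings as _warnings

    recs: dict[int, Recommendation] = {}
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # sub-majority thresholds are the point here
        for threshold in range(1, box.n_voters + 1):
            recs[threshold] = apply_decision_rule(box, registry, threshold=threshold)

    components = [c.id for c in registry if c.kind != "efficiency"]
    table = pd.DataFrame(
        {t: [recs[t].decisions[c] for c in components] for t in recs},
        index=components,
    )
    table.index.name = "component"
    at_op = table[operating_threshold]
    flips = pd.Series(False, index=table.index)
    for neighbour in (operating_threshold - 1, operating_threshold + 1):
        if neighbour in table.columns:
            flips |= table[neighbour] != at_op
    table["flips_within_one_vote"] = flips
    return table
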