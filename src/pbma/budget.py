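"""Program-budget compilation: where does the money currently go?

National spend per service line is extrapolated from the subset of
regions that returned a spend template: the unweighted mean per-capita
spend across responding regions, multiplied by the national population.
Primary-care (general dental service) spend, which commissioners cannot
break down from block contracts, is instead decomposed from claims data:
items of each treatment type x mean fee x a correction factor that
accounts for multiple items settled under one fee payment.

Monetary amounts in this module are plain GBP per annum; conversion to
GBP millions happens at the component-registry boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import InsufficientDataError, ValidationError


@dataclass(frozen=True)
class RegionalReturn:
    """One region's completed spend template."""

    region_id: str
    population: int
    spend_by_line: Mapping[str, float]  # service line -> GBP per annum

    def __post_init__(self):
        if self.population <= 0:
            raise ValidationError(f"region {self.region_id}: population must be positive")
        for line, spend in self.spend_by_line.items():
            if spend < 0:
                raise ValidationError(f"region {self.region_id}: negative spend on {line!r}")


@dataclass(frozen=True)
class ClaimsRecord:
    """Annual claims volume and mean fee for one treatment type."""

    treatment_type: str
    item_count: int
    mean_fee: float  # GBP per item

    def __post_init__(self):
        if self.item_count < 0:
            raise ValidationError(f"{self.treatment_type}: negative item count")
        if self.mean_fee < 0:
            raise ValidationError(f"{self.treatment_type}: negative mean fee")


def extrapolate_national_spend(
    returns: Iterable[RegionalReturn],
    national_population: int,
) -> dict[str, float]:
    """National spend per line = mean per-capita spend of responders x population."""
    returns = list(returns)
    if not returns:
        raise InsufficientDataError("no regional returns to extrapolate from")
    if national_population <= 0:
        raise ValidationError("national population must be positive")
    lines = list(returns[0].spend_by_line)
    for r in returns:
        if set(r.spend_by_line) != set(lines):
            raise ValidationError(
                f"region {r.region_id} reports a different set of service lines"
            )
    out = {}
    for line in lines:
        per_capita = [r.spend_by_line[line] / r.population for r in returns]
        out[line] = sum(per_capita) / len(per_capita) * national_population
    return out


def breakdown_gds_spend(
    claims: Iterable[ClaimsRecord],
    correction_factor: float,
) -> dict[str, float]:
    """Spend per treatment type = items x mean fee x correction factor."""
    if correction_factor <= 0:
        raise ValidationError("correction factor must be positive")
    return {
        c.treatment_type: c.item_count * c.mean_fee * correction_factor for c in claims
    }


def budget_shares(spends: Mapping[str, float]) -> dict[str, float]:
    """Percentage share of each line in the total; shares sum to exactly 100."""
    total = sum(spends.values())
    if total <= 0:
        raise ValidationError("total spend must be positive to compute shares")
    return {line: 100.0 * spend / total for line, spend in spends.items()}


def format_share(share: float) -> str:
    """Display rule for budget tables: shares below 1% print as '<1'."""
    if share < 0:
        raise ValidationError("negative share")
    if 0 < share < 1:
        return "<1"
    return str(int(round(share)))


def budget_table(spends: Mapping[str, float]) -> pd.DataFrame:
    """Spend, exact share and display share per line, in input order."""
    shares = budget_shares(spends)
    return pd.DataFrame(
        {
            "service_line": list(spends),
            "spend_gbp": [spends[k] for k in spends],
            "share_pct": [shares[k] for k in spends],
            "share_display": [format_share(shares[k]) for k in spends],
        }
    )


def returns_from_frame(frame: pd.DataFrame) -> list[RegionalReturn]:
    """Read regional returns from a wide table (region_id, population, <one column per line>)."""
    required = {"region_id", "population"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"regional return table missing columns: {sorted(missing)}")
    lines = [c for c in frame.columns if c not in required]
    return [
        RegionalReturn(
            region_id=str(row["region_id"]),
            population=int(row["population"]),
            spend_by_line={line: float(row[line]) for line in lines},
        )
        for row in frame.to_dict("records")
    ]
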