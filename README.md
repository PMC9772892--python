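# pbma

Program budgeting marginal analysis (PBMA) for health-service priority
setting, built around a complete national worked example from NHS
dentistry in England.

Health systems rarely reallocate budgets explicitly: historical spending
patterns persist, and new services are added without asking what should
be given up. PBMA is the health-economics framework that forces the
trade-off into the open. This package implements the full quantitative
pipeline for commissioners, health economists and researchers running a
PBMA exercise:

1. **Program budget** — map where the money currently goes, extrapolating
   national spend per service line from the per-capita means of the
   regions that return spend templates, and decomposing block primary-care
   contracts from claims counts × mean fees × a correction factor.
2. **Criteria and weights** — each panelist allocates exactly 100 points
   across the decision criteria (and within each criterion across its
   subcriteria); the panel weight is the arithmetic mean, which keeps the
   weights on the 100-point simplex. The overall weight of subcriterion
   *s* under criterion *c* is `w_c × w_{s|c} / 100`.
3. **Scoring** — panelists score every candidate program component on
   every subcriterion with an integer in {−2,…,+2}; the panel score is
   the median. External evidence on a 1–5 Likert scale enters as
   `rating − 3`. Aggregation is linear throughout:

   ```
   final(j) = Σ_c (w_c/100) · Σ_{s∈c} (w_{s|c}/100) · score(j, s)
   ```

4. **Societal values** — a contingent-valuation survey gives each
   respondent's maximum willingness to pay (WTP, £/person/year) per
   component; complete-case sample means scale up to aggregate societal
   values (£M/year), which feed the "societal benefit" subcriterion
   (min–max mapped to −2..+2) and the cost–benefit criterion
   (clamped net benefit `(value − cost)/scale`).
5. **Marginal analysis** — the decision stage. A portfolio of changes is
   feasible when disinvestment releases plus efficiency savings cover new
   investment (cost neutrality). Panelists each submit a feasible
   portfolio; a component with at least a threshold number of funding
   votes (6 of 9 in the case study) is recommended: Invest / No
   investment for new services, Continue / Disinvest for current ones.
6. **Sensitivity** — Dirichlet resampling of the elicited weights
   (rank probabilities, score intervals) and a deterministic sweep of the
   vote threshold.

A seeded synthetic-data module generates panels, ballots, WTP surveys,
regional returns and component registries with the structure the
analysis assumes, so the whole pipeline is testable end to end without
any confidential returns.

## Worked example

The package bundles the decision tables of a whole-country PBMA for NHS
dentistry (2015–2016 budget): 11 weighted criteria with 24 subcriteria,
criterion-level scores for 14 candidate components, costs, and the
panel's 9 returned final ballots. `pbma report` re-derives the decisions
from those inputs:

```text
$ pbma report
                                              name  ... votes_for_funding       decision
component_id                                        ...
moderate_orthodontics  Moderate-need orthodontics   ...                 3      Disinvest
adult_orthodontics     Adult orthodontics           ...                 3      Disinvest
routine_scaling        Routine scale and polish     ...                 2      Disinvest
molar_endodontics      Molar root canal treatment   ...                 6       Continue
...
care_homes             Expanded dental services in care homes   8         Invest
dph_input              Dental public health input ...           7         Invest
helpline_link          Direct booking link from the national NHS helpline  6  Invest
residual budget: GBP 74M
```

Reading the output: every current service kept by at least 6 of the 9
voters continues; the three kept by fewer are disinvested (releasing
44 + 11 + 174 = £229M), and the four new services with ≥6 votes are
funded (costing 135 + 13 + 5 + 2 = £155M), leaving £74M unspent. With
the oral-surgery efficiency release supplied
(`pbma report --efficiency-release 60`) the unspent budget is £134M.
Two candidate investments (preventive sessions at £659M and CBT at
£824M) exceed the £592M total that disinvesting *everything* would
release — exhaustive enumeration confirms no cost-neutral portfolio can
ever fund them.

The same pipeline runs on synthetic or user-supplied CSV fixtures:

```bash
pbma simulate --out fixture/ --seed 1      # seeded synthetic inputs
pbma run fixture/ --out report/ --seed 1   # budget → weights → scores → decisions
```

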