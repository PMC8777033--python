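# cofseof

Strain-design for **metabolite co-production** in genome-scale metabolic
models. Given a constraint-based model (SBML or BiGG JSON) and a growth
medium, `cofseof` finds single reaction knockouts/amplifications that
increase the secretion of *pairs* of metabolites simultaneously, and
exhaustively searches mixed intervention sets of up to three reactions for
a chosen product set.

Intended for metabolic engineers and systems biologists who work with
COBRA-style models and want co-production targets (e.g. a biofuel plus an
organic acid) rather than single-product designs.

## Method

For each product, an **enforced-objective flux scan** pins the product
exchange flux at 10%…100% of its theoretical maximum v_max,prdt while
biomass remains the FBA objective:

    max c_bio·v   s.t.  S v = 0,  v_l ≤ v ≤ v_u,  v_prdt = x · v_max,prdt

Reactions whose |flux| rises monotonically with x are amplification
candidates, falls are knockout candidates; flat, oscillatory and
sign-flipping trajectories are discarded, and exchange/transport reactions
are excluded from the search space. Candidate sets are intersected across
products: a common (reaction, action) is a co-production target. Each
target is validated on the mutant model by FVA — it passes when every
product's maximum flux rises > 5% over wild type (absolute floor for
non-secreted products) and the mutant keeps ≥ 25% of wild-type growth —
and ranked by

    Score_i = (v_prdt_i,mut − v_prdt_i,wt) / (v_bio,wt − v_bio,mut),
    overall = Σ_i Score_i

the production gain per unit of growth sacrificed, summed over products.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The packaged network `toynet_b` routes glucose-derived precursor A either
to biomass or through the coupled branch `R5: A -> P + Q` (capacity 12),
which secretes two products at once:

```sh
cofseof pairs --model toynet_b.json --out report.tsv
# evaluated 2 interventions, 1 passing pairs -> report.tsv
```

`report.tsv` (provenance header omitted):

```text
product_a  wt_flux_a  product_b  wt_flux_b  intervention  signature  mut_flux_a  mut_flux_b  mut_biomass  score_a  score_b  overall_score  passed
EX_P_e     0          EX_Q_e     0          R5            A          12          12          8            1        1        2              True
```

Amplifying R5 to its theoretical maximum (12) makes the mutant secrete 12
mmol/gDW/h of each product (wild type secretes neither) while biomass drops
from 20 to 8 — above the 25% retention floor — scoring 12/(20−8) = 1 per
product, overall 2. The knockout candidate shared by the pair (the biomass
branch `R2`) is evaluated too but fails the growth floor, so it is excluded
from the default report (`--all` keeps failing rows).

The same library drives single-product scans and the higher-order search:

```sh
cofseof scan   --model toynet_b.json --product EX_P_e --out scan.tsv
cofseof combos --model toynet_b.json --products EX_P_e,EX_Q_e --max-size 3 --out combos.tsv
```

Genome-scale models can be fetched by BiGG id when a network connection is
available (`cofseof fetch-model iML1515`) and used with the packaged
`aerobic`/`anaerobic` media presets (glucose −10 mmol/gDW/h; O₂ −2 or 0).

As a library:

```python
import cofseof as cf

model = cf.toynet_b()
records = cf.pairwise_coproduction(model)
best = records[0]
best.intervention.reaction_ids   # ('R5',)
best.overall_score               # 2.0
cf.passing_pairs(records)        # [('EX_P_e', 'EX_Q_e')]
```

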