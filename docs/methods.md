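# Methods

## Model and problem setting

A genome-scale metabolic model is a stoichiometric matrix **S** (m
metabolites × n reactions) with per-reaction flux bounds v_l ≤ v ≤ v_u
(mmol/gDW/h) and a linear objective c, the biomass reaction carrying the
nonzero weight. Flux balance analysis (FBA) solves

    max cᵀv   s.t.  S v = 0,  v_l ≤ v ≤ v_u

and flux variability analysis (FVA) fixes the objective at a fraction of
its optimum and then minimises/maximises each flux of interest, two LPs per
reaction. `cofseof` delegates both to cobrapy (GLPK backend, one solver
instance reused across an FVA batch) and builds the strain-design layers on
top.

The package identifies reaction-level engineering strategies — knockouts
(both bounds to 0) and amplifications (both bounds pinned at the reaction's
theoretical-maximum flux, emulating strong constitutive overexpression) —
that increase the secretion of *several* products at once while keeping the
strain growing.

## Enforced-objective flux scanning

For one product: compute the maximum biomass flux v_max,bio and the maximum
product exchange flux v_max,prdt by FBA; then pin the product exchange
(lower = upper bound) at x·v_max,prdt for an increasing ladder of fractions
x and re-solve biomass-optimal FBA at each step. Biomass stays the
objective throughout — production is *enforced*, never optimised. Reactions
whose absolute flux rises monotonically along the ladder are amplification
candidates; monotone falls are knockout candidates; flat (range ≤ ε_flat),
oscillating, and sign-flipping trajectories are discarded (a sign flip is
neither amplification nor deletion of one direction). Exchange reactions
(single-entry columns of S, which includes sinks/demands and the biomass
drain), transport reactions (participants in ≥2 compartments) and the
biomass reaction are excluded from the search space — they are not
enzymatic targets.

Defaults and rationale:

- **Ladder**: 10 equal steps over 10%…100% of v_max,prdt. The 0% point is
  the unconstrained optimum and adds no information. Fewer steps coarsen
  the oscillation test but on tree-like networks give identical labels (a
  CLI test exercises 3 vs 10 steps).
- **ε_flat = 1e-6 mmol/gDW/h** (absolute): below the noise of a pair of
  LPs at genome scale, far below any real flux change.
- **Monotonicity mode**: `strict` requires every step to move the right way
  (up to ε_flat); `trend` instead requires perfect Spearman rank
  correlation of 3-point moving-window means, tolerating small wiggles.
  `strict` is the default; the two modes bracket reasonable readings of
  "no change or oscillations".
- **Degeneracy**: the scan consumes plain FBA flux vectors, which are not
  unique at alternate optima. The pipeline is deterministic (fixed solver,
  fixed ordering) but on degenerate genome-scale models the labels can
  depend on the solver's vertex choice; the fixture networks are built
  degeneracy-free (below) so tests are solver-independent.

## Co-production screening

*Secretory metabolites* are those whose exchange can carry positive flux
with no growth requirement (FVA maximum at biomass fraction 0 above
ε_flat); their wild-type secretion is the FVA maximum at 100% of optimal
biomass. Per-product scans run once and are cached; for every unordered
pair the candidate sets are intersected by (reaction, action). Two
amplification candidates must also agree on the flux direction at the top
of both ladders — the amplification level is direction-specific, so
opposite orientations cannot be realised by one overexpression. (This is a
strictly tighter refinement of plain label intersection; without it a
direction would have to be chosen arbitrarily for one of the products.)

Each common target is validated on the mutant: knockout or amplification
applied, biomass re-optimised, and each product's FVA maximum taken at 100%
of the *mutant's* optimal biomass. An intervention passes when every
product's maximum flux rises by more than 5% over wild type and the mutant
retains at least 25% of wild-type growth. Products the wild type does not
secrete (flux < 1e-5 mmol/gDW/h) switch to an absolute test — mutant flux
above 1e-3 mmol/gDW/h — because 5% of ~0 is vacuous. An infeasible mutant
is recorded with zero biomass and `passed = False`, never raised: a screen
must survive its own negatives. All thresholds are configuration fields,
not constants.

**Scoring.** Per product, Score_i = (v_prdt,mut − v_prdt,wt) /
max(v_bio,wt − v_bio,mut, ε_bio): the production gain bought per unit of
growth given up. The overall score is the sum over products. ε_bio = 1e-4
keeps the score finite when growth is numerically unchanged; wild-type
fluxes below 1e-5 are treated as exactly 0 in the numerator (secretion
noise is not a baseline). Records are sorted by overall score descending,
ties broken by reaction id then product pair, so identical inputs yield
byte-identical reports.

**Amplification levels** are theoretical maxima — max v subject to S v = 0
and bounds only — computed on the unperturbed medium-constrained model, by
default with no growth requirement (`amp_reference_fraction = 0`; a growth
requirement during level computation is supported but not the default, and
the choice is exposed in configuration because it changes levels on models
where production competes with growth). For a reversible reaction the
direction is the sign the reaction carries at the top of the enforced-flux
ladder. Reactions whose theoretical maximum is unbounded are excluded from
amplification candidacy: bounds cannot be pinned at infinity.

## Higher-order search

For a chosen product set, the candidate pool is the union (default) or
intersection of per-product targets; every subset of 1–3 actions on
distinct reactions is evaluated exhaustively with the same validation and
scoring. A reaction listed as amplification for one product and knockout
for another contributes both actions to the pool but can never appear twice
in one combination. Amplification levels are resolved once, from the
unperturbed model — re-deriving them inside partially built mutants would
make results order-dependent. Failing and infeasible combinations are kept
in the result (with `passed = False`) for auditability; writers filter to
passing rows by default.

## Media

Packaged presets follow the BiGG sign convention (negative exchange flux =
uptake): `aerobic` = glucose −10, O₂ −2 mmol/gDW/h; `anaerobic` = glucose
−10, zero O₂ uptake. Exchange reactions not named by a medium keep their
model defaults. Media name exchange reactions only; naming anything else is
an error.

## Synthetic fixture networks

The packaged networks are small branched carbon trees chosen so that every
pipeline stage has a hand-derivable outcome:

- `toynet_a` — glucose (uptake ≤ 10) doubled into a precursor A, split
  between a biomass route and a product route. Wild-type biomass 20,
  product maximum 20; the scan marks the product branch for amplification
  and the biomass branch for knockout.
- `toynet_b` — the product branch replaced by R5: A → P + Q, coupling two
  secreted products, with R5 capacity-capped at 12. The cap makes the
  amplified mutant keep biomass 8 (40% of wild type), so (R5, AMP) is the
  unique passing co-production target for the pair: mutant fluxes 12/12,
  Score 1 + 1 = 2. An uncapped branch would consume all carbon when pinned
  at its theoretical maximum and fail the growth floor by construction.
- `random_toy(seed, k)` — seeded trees with k dedicated product branches
  (stoichiometric coefficients in {1,2,3}, capacities in {5, 8, ∞}) plus
  one capacity-capped coupled branch feeding the first two products at a
  strictly better carbon yield than their dedicated routes. The strict
  yield ordering guarantees a unique optimum at every pinned step.

What these fixtures emulate: carbon-limited growth/production trade-offs,
stoichiometric product coupling, capacity-limited amplification, and
infeasible double interventions. What they do not emulate: alternate
optimal flux routes (degeneracy), cofactor/energy coupling, reversible
internal cycles, and the sheer size of genome-scale models. Green tests
therefore certify the algorithmic machinery and its numerics, not the
biological plausibility of targets on any particular organism — for that
the pipeline accepts BiGG models (e.g. iML1515, iMM904 via
`cofseof fetch-model`) unchanged.

Test sizes: the oracle-equivalence suite runs the fixed fixtures plus 20
seeded random networks (2–3 branches each), cross-checking batched FVA,
scan classification, the pairwise sweep and the size-≤2 combination search
against fresh single-purpose scipy (HiGHS) LPs at 1e-6 — a different solver
and code path from the cobrapy/GLPK implementation.

## Numerical choices

- Solver feasibility ~1e-9 (GLPK defaults); all package-level comparisons
  at 1e-6.
- FBA infeasibility is propagated as a status, not an exception, wherever a
  sweep must continue; structural errors (unknown ids, inverted bounds,
  ambiguous biomass flag) raise immediately.
- Exchange detection is purely structural (one nonzero stoichiometric
  entry), so sink/demand pseudo-reactions are pruned alongside true
  exchanges; compartments come from the model's annotations with a
  BiGG-style id-suffix fallback (configurable regex).
- All periplasm/extracellular and other multi-compartment reactions are
  pruned as transport.

## Known limitations

- Classification on degenerate genome-scale models inherits FBA's
  non-uniqueness; a parsimonious secondary objective would change labels
  and is deliberately not applied (plain FBA mirrors standard COBRA
  practice).
- Amplification is fix-at-maximum only and knockout is zero only — no
  graded modulation.
- Gene–protein–reaction mapping is out of scope: targets are reactions,
  not genes.
- The all-pairs sweep considers pairs only; larger product sets enter
  through the explicit product list of the higher-order search.
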