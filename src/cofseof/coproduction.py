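"""Co-production screening: intersect per-product scan targets, validate, score.

Strategy for co-optimizing a set of secreted metabolites with a single
genetic intervention:

1. enumerate every *secretory* metabolite — one whose exchange reaction can
   carry positive (secretion) flux under the medium;
2. run the enforced-flux scan per product and classify internal reactions
   into amplification/knockout candidates;
3. for each unordered product pair, intersect the candidate sets by
   (reaction, action) — a reaction that helps both products the same way is
   a co-production target;
4. validate each common target on the mutant model: fix the intervention,
   re-optimize biomass, and take each product's flux-variability maximum at
   the mutant's optimal biomass. An intervention passes when every product's
   maximum flux rises by more than 5% over wild type (absolute floor for
   products the wild type does not secrete) and the mutant keeps at least
   25% of wild-type growth;
5. rank by score — per product, the flux gain divided by the growth loss,
   summed over products. High scores mean large production gains bought
   with little growth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import cobra
import math
import pandas as pd

from .fseof import NotProducibleError, ScanConfig, TargetClassification, candidate_targets
from .gsmm import (
    AMP,
    EXCHANGE,
    Intervention,
    InterventionSet,
    KO,
    apply_interventions,
    biomass_reaction,
    classify_reactions,
)
from .lp import fba, fva, theoretical_max

__all__ = [
    "CoProductionConfig",
    "SecretoryMetabolite",
    "ValidationResult",
    "ScoreReport",
    "CoProductionRecord",
    "secretory_metabolites",
    "wild_type_reference",
    "common_targets",
    "resolve_amp_levels",
    "validate_intervention",
    "score",
    "pairwise_coproduction",
    "passing_pairs",
    "records_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoProductionConfig:
    """Thresholds and scan settings for co-production screening.

    gain_fraction:
        Required relative increase in a product's maximum flux (0.05 = 5%).
    absolute_gain:
        Replacement absolute test (mmol/gDW/h) for products whose wild-type
        flux is below ``wt_zero`` — 5% of ~0 would be vacuous.
    biomass_retention:
        Minimum mutant biomass as a fraction of wild type (0.25 = at most a
        75% growth drop).
    fva_fraction:
        Biomass fraction at which mutant/wild-type product maxima are read
        from FVA (1.0 = at the exact growth optimum).
    amp_reference_fraction:
        Biomass fraction enforced when computing amplification levels
        (theoretical maxima); 0 = no growth requirement.
    eps_bio:
        Floor on the biomass-loss denominator of the score, keeping it
        finite when growth is (numerically) unchanged.
    """

    scan: ScanConfig = field(default_factory=ScanConfig)
    gain_fraction: float = 0.05
    absolute_gain: float = 1e-3
    wt_zero: float = 1e-5
    biomass_retention: float = 0.25
    fva_fraction: float = 1.0
    amp_reference_fraction: float = 0.0
    eps_bio: float = 1e-4
    eps_flat: float = 1e-6


@dataclass(frozen=True)
class SecretoryMetabolite:
    """A metabolite the network can push into the medium."""

    metabolite_id: str
    exchange_id: str
    #: FVA maximum of the exchange at 100% of optimal biomass (what the
    #: wild type secretes while growing optimally), mmol/gDW/h.
    wt_flux: float


@dataclass(frozen=True)
class ValidationResult:
    """Mutant-vs-wild-type comparison for one intervention set."""

    intervention: InterventionSet
    products: tuple[str, ...]
    wt_flux: Mapping[str, float]
    mut_flux: Mapping[str, float]
    bio_wt: float
    bio_mut: float
    gain_pass: Mapping[str, bool]
    biomass_pass: bool

    @property
    def pass_overall(self) -> bool:
        return self.biomass_pass and all(self.gain_pass.values())


@dataclass(frozen=True)
class ScoreReport:
    """Per-product and overall gain-per-growth-loss scores (dimensionless)."""

    scores: Mapping[str, float]
    overall: float


@dataclass(frozen=True)
class CoProductionRecord:
    """One evaluated intervention for one product set."""

    products: tuple[str, ...]
    intervention: InterventionSet
    validation: ValidationResult
    score_report: ScoreReport

    @property
    def overall_score(self) -> float:
        return self.score_report.overall

    @property
    def passed(self) -> bool:
        return self.validation.pass_overall


def _record_sort_key(record: CoProductionRecord):
    return (-record.overall_score, record.intervention.reaction_ids, record.products)


def secretory_metabolites(
    model: cobra.Model,
    eps: float = 1e-6,
    classes: Mapping[str, str] | None = None,
) -> list[SecretoryMetabolite]:
    """All metabolites whose exchange reaction can secrete under the medium.

    Capability is tested with no growth requirement (FVA maximum at biomass
    fraction 0 above *eps*); the reported wild-type flux is the FVA maximum
    at 100% of optimal biomass. Sorted by exchange id.
    """
    classes = classes if classes is not None else classify_reactions(model)
    biomass_id = biomass_reaction(model).id
    exchanges = [
        r
        for r in model.reactions
        if classes[r.id] == EXCHANGE and r.id != biomass_id and len(r.metabolites) == 1
    ]
    if not exchanges:
        return []
    ids = [r.id for r in exchanges]
    capability = fva(model, ids, fraction_of_optimum=0.0)
    capable = [r for r in exchanges if capability.maximum(r.id) > eps]
    if not capable:
        return []
    wild_type = fva(model, [r.id for r in capable], fraction_of_optimum=1.0)
    found = [
        SecretoryMetabolite(
            metabolite_id=next(iter(r.metabolites)).id,
            exchange_id=r.id,
            wt_flux=wild_type.maximum(r.id),
        )
        for r in capable
    ]
    return sorted(found, key=lambda s: s.exchange_id)


def wild_type_reference(
    model: cobra.Model,
    products: Sequence[str],
    fva_fraction: float = 1.0,
) -> tuple[float, dict[str, float]]:
    """Wild-type biomass flux plus each product's FVA maximum at that growth."""
    bio = fba(model)
    if not bio.ok:
        raise RuntimeError(f"wild-type biomass FBA ended {bio.status}")
    if not products:
        return bio.objective_value, {}
    ranges = fva(model, list(products), fraction_of_optimum=fva_fraction)
    return bio.objective_value, {p: ranges.maximum(p) for p in products}


def common_targets(
    class_a: TargetClassification, class_b: TargetClassification
) -> list[tuple[str, str, int]]:
    """Intersect two classifications by (reaction, action).

    Amplifications must additionally agree on the flux direction at the top
    of both scans — the amplification level is direction-specific, so
    opposite orientations cannot be one overexpression. Returns sorted
    (reaction id, KO|AMP, direction) triples.
    """
    targets_a = dict(class_a.targets())
    result: list[tuple[str, str, int]] = []
    for rid, kind in class_b.targets():
        if targets_a.get(rid) != kind:
            continue
        direction = class_b.directions.get(rid, 1)
        if kind == AMP and class_a.directions.get(rid, 1) != direction:
            continue
        result.append((rid, kind, direction if kind == AMP else 0))
    return sorted(result)


def resolve_amp_levels(
    model: cobra.Model,
    targets: Iterable[tuple[str, str, int]],
    config: CoProductionConfig | None = None,
    cache: dict[tuple[str, int], float] | None = None,
) -> dict[str, float]:
    """Theoretical-maximum amplification levels for the AMP entries of
    *targets*, computed on the unperturbed medium-constrained model.

    Reactions with a non-finite theoretical maximum are omitted (they cannot
    be pinned) — callers must treat absence as 'not amplifiable'.
    """
    config = config or CoProductionConfig()
    cache = cache if cache is not None else {}
    levels: dict[str, float] = {}
    for rid, kind, direction in targets:
        if kind != AMP:
            continue
        key = (rid, 1 if direction >= 0 else -1)
        if key not in cache:
            cache[key] = theoretical_max(
                model,
                rid,
                direction=key[1],
                biomass_fraction=config.amp_reference_fraction,
            )
        if math.isfinite(cache[key]):
            levels[rid] = cache[key]
    return levels


def validate_intervention(
    model: cobra.Model,
    intervention: InterventionSet,
    products: Sequence[str],
    amp_levels: Mapping[str, float] | None = None,
    reference: tuple[float, Mapping[str, float]] | None = None,
    config: CoProductionConfig | None = None,
) -> ValidationResult:
    """Build the mutant, re-optimise biomass, and apply the pass criteria.

    An infeasible (or zero-growth) mutant yields ``pass_overall == False``
    with ``bio_mut = 0`` and zero product fluxes rather than an exception.
    """
    config = config or CoProductionConfig()
    if reference is None:
        bio_wt, wt_flux = wild_type_reference(model, products, config.fva_fraction)
    else:
        bio_wt, ref_flux = reference
        wt_flux = {p: ref_flux[p] for p in products}

    mutant = apply_interventions(model, intervention, amp_levels)
    bio_sol = fba(mutant)
    if not bio_sol.ok:
        mut_flux = {p: 0.0 for p in products}
        bio_mut = 0.0
    else:
        bio_mut = bio_sol.objective_value
        if products:
            ranges = fva(mutant, list(products), fraction_of_optimum=config.fva_fraction)
            mut_flux = {p: ranges.maximum(p) for p in products}
        else:
            mut_flux = {}

    gain_pass: dict[str, bool] = {}
    for p in products:
        if wt_flux[p] < config.wt_zero:
            gain_pass[p] = mut_flux[p] > config.absolute_gain
        else:
            gain_pass[p] = mut_flux[p] > (1.0 + config.gain_fraction) * wt_flux[p]
    biomass_pass = bio_mut >= config.biomass_retention * bio_wt
    return ValidationResult(
        intervention=intervention,
        products=tuple(products),
        wt_flux=dict(wt_flux),
        mut_flux=dict(mut_flux),
        bio_wt=bio_wt,
        bio_mut=bio_mut,
        gain_pass=gain_pass,
        biomass_pass=biomass_pass,
    )


def score(
    validation: ValidationResult, config: CoProductionConfig | None = None
) -> ScoreReport:
    """Gain-per-growth-loss score per product, summed into the overall score.

    ``Score_i = (v_mut_i - v_wt_i) / max(bio_wt - bio_mut, eps_bio)``; a
    wild-type flux below ``wt_zero`` is treated as exactly zero (it is
    secretion noise, not a baseline).
    """
    config = config or CoProductionConfig()
    denominator = max(validation.bio_wt - validation.bio_mut, config.eps_bio)
    scores: dict[str, float] = {}
    for p in validation.products:
        wt = validation.wt_flux[p]
        wt = 0.0 if wt < config.wt_zero else wt
        scores[p] = (validation.mut_flux[p] - wt) / denominator
    return ScoreReport(scores=scores, overall=sum(scores.values()))


def evaluate_intervention(
    model: cobra.Model,
    intervention: InterventionSet,
    products: Sequence[str],
    amp_levels: Mapping[str, float] | None = None,
    reference: tuple[float, Mapping[str, float]] | None = None,
    config: CoProductionConfig | None = None,
) -> CoProductionRecord:
    """Validate and score one intervention; the unit of work of every sweep."""
    validation = validate_intervention(
        model, intervention, products, amp_levels, reference, config
    )
    return CoProductionRecord(
        products=tuple(products),
        intervention=intervention,
        validation=validation,
        score_report=score(validation, config),
    )


def pairwise_coproduction(
    model: cobra.Model,
    config: CoProductionConfig | None = None,
    products: Sequence[str] | None = None,
) -> list[CoProductionRecord]:
    """Screen all unordered pairs of secretory metabolites for single
    interventions that co-optimize both.

    Per-product scans run once and are reused across pairs. Every common
    target is validated and scored; the returned records carry pass flags
    and are sorted by overall score (descending), ties broken by reaction
    id then product pair — a deterministic order, so identical inputs give
    identical reports. Per-pair failures are logged and skipped, never
    aborting the sweep.
    """
    config = config or CoProductionConfig()
    classes = classify_reactions(model)
    secretory = secretory_metabolites(model, eps=config.eps_flat, classes=classes)
    if products is not None:
        wanted = set(products)
        secretory = [s for s in secretory if s.exchange_id in wanted]
    if len(secretory) < 2:
        return []

    exchange_ids = [s.exchange_id for s in secretory]
    bio_wt = fba(model).objective_value
    wt_flux = {s.exchange_id: s.wt_flux for s in secretory}

    classifications: dict[str, TargetClassification | None] = {}
    for eid in exchange_ids:
        try:
            classifications[eid] = candidate_targets(model, eid, config.scan, classes)
        except NotProducibleError as exc:
            logger.warning("skipping %s: %s", eid, exc)
            classifications[eid] = None

    amp_cache: dict[tuple[str, int], float] = {}
    records: list[CoProductionRecord] = []
    for a, b in combinations(sorted(exchange_ids), 2):
        class_a, class_b = classifications[a], classifications[b]
        if class_a is None or class_b is None:
            continue
        for rid, kind, direction in common_targets(class_a, class_b):
            try:
                levels = resolve_amp_levels(
                    model, [(rid, kind, direction)], config, cache=amp_cache
                )
                if kind == AMP and rid not in levels:
                    logger.warning(
                        "skipping AMP of %s for (%s, %s): unbounded theoretical maximum",
                        rid, a, b,
                    )
                    continue
                action = Intervention(rid, kind, levels.get(rid, 0.0) if kind == AMP else 0.0)
                records.append(
                    evaluate_intervention(
                        model,
                        InterventionSet((action,)),
                        [a, b],
                        amp_levels=levels,
                        reference=(bio_wt, wt_flux),
                        config=config,
                    )
                )
            except Exception:
                logger.exception("pair (%s, %s), target %s failed; skipping", a, b, rid)
    records.sort(key=_record_sort_key)
    return records


def passing_pairs(records: Iterable[CoProductionRecord]) -> list[tuple[str, ...]]:
    """Product pairs with at least one passing intervention, sorted."""
    return sorted({r.products for r in records if r.passed})


def records_to_frame(records: Sequence[CoProductionRecord]) -> pd.DataFrame:
    """Tabulate records, one row per evaluated intervention.

    Columns follow the screening-report layout: products and their wild-type
    fluxes, the intervention and its A(mplify)/K(nockout) signature, mutant
    product fluxes, mutant biomass, per-product scores and the overall score.
    """
    if not records:
        return pd.DataFrame()
    n_products = max(len(r.products) for r in records)
    rows = []
    for record in records:
        row: dict[str, object] = {}
        for i in range(n_products):
            tag = chr(ord("a") + i)
            if i < len(record.products):
                p = record.products[i]
                row[f"product_{tag}"] = p
                row[f"wt_flux_{tag}"] = record.validation.wt_flux[p]
                row[f"mut_flux_{tag}"] = record.validation.mut_flux[p]
                row[f"score_{tag}"] = record.score_report.scores[p]
            else:
                row[f"product_{tag}"] = ""
                row[f"wt_flux_{tag}"] = float("nan")
                row[f"mut_flux_{tag}"] = float("nan")
                row[f"score_{tag}"] = float("nan")
        row["intervention"] = ";".join(record.intervention.reaction_ids)
        row["signature"] = record.intervention.signature()
        row["mut_biomass"] = record.validation.bio_mut
        row["overall_score"] = record.overall_score
        row["passed"] = record.passed
        rows.append(row)
    ordered = (
        [c for i in range(n_products) for c in (f"product_{chr(ord('a') + i)}", f"wt_flux_{chr(ord('a') + i)}")]
        + ["intervention", "signature"]
        + [f"mut_flux_{chr(ord('a') + i)}" for i in range(n_products)]
        + ["mut_biomass"]
        + [f"score_{chr(ord('a') + i)}" for i in range(n_products)]
        + ["overall_score", "passed"]
    )
    return pd.DataFrame(rows, columns=ordered)
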