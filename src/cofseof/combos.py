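"""Higher-order intervention search: mixed KO/AMP sets of size up to three.

For a chosen product set, the candidate pool is the union (default) or
intersection of the per-product scan targets; every subset of 1..max_size
actions on distinct reactions is then evaluated exhaustively with the same
mutant-FVA validation and scoring used for single interventions. A reaction
appearing as an amplification target for one product and a knockout target
for another contributes both actions to the pool, but the two can never end
up in the same combination (one reaction, one action).

Amplification levels are resolved once from the unperturbed
medium-constrained model, never per combination — re-deriving them inside a
partially built mutant would make results depend on action order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import cobra

from .coproduction import (
    CoProductionConfig,
    CoProductionRecord,
    _record_sort_key,
    evaluate_intervention,
    resolve_amp_levels,
    wild_type_reference,
)
from .fseof import NotProducibleError, TargetClassification, candidate_targets
from .gsmm import AMP, Intervention, InterventionSet, classify_reactions

__all__ = ["ComboSearchConfig", "candidate_pool", "enumerate_and_evaluate"]

logger = logging.getLogger(__name__)

POOL_POLICIES = ("union", "intersection")


@dataclass(frozen=True)
class ComboSearchConfig:
    """Product set and limits for the exhaustive combination search."""

    products: tuple[str, ...]
    max_size: int = 3
    pool_policy: str = "union"
    base: CoProductionConfig = field(default_factory=CoProductionConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "products", tuple(self.products))
        if not self.products:
            raise ValueError("product set must not be empty")
        if self.max_size not in (1, 2, 3):
            raise ValueError(f"max_size must be 1, 2 or 3, got {self.max_size}")
        if self.pool_policy not in POOL_POLICIES:
            raise ValueError(
                f"pool_policy must be one of {POOL_POLICIES}, got {self.pool_policy!r}"
            )


def candidate_pool(
    model: cobra.Model,
    products: Sequence[str],
    policy: str = "union",
    config: CoProductionConfig | None = None,
    classifications: Mapping[str, TargetClassification] | None = None,
) -> list[tuple[str, str, int]]:
    """Pool of (reaction, KO|AMP, direction) actions over the product set.

    ``union`` merges all per-product targets; ``intersection`` keeps only
    actions shared by every product. Products whose scan fails (not
    producible) contribute nothing under ``union`` and empty the pool under
    ``intersection``. Sorted and duplicate-free.
    """
    if policy not in POOL_POLICIES:
        raise ValueError(f"unknown pool policy {policy!r}")
    config = config or CoProductionConfig()
    per_product: list[set[tuple[str, str, int]]] = []
    for product in products:
        if classifications is not None and product in classifications:
            classification = classifications[product]
        else:
            try:
                classification = candidate_targets(model, product, config.scan)
            except NotProducibleError as exc:
                logger.warning("no targets for %s: %s", product, exc)
                classification = None
        if classification is None:
            per_product.append(set())
            continue
        per_product.append(
            {
                (rid, kind, classification.directions.get(rid, 1) if kind == AMP else 0)
                for rid, kind in classification.targets()
            }
        )
    if not per_product:
        return []
    pooled = set.union(*per_product) if policy == "union" else set.intersection(*per_product)
    if not pooled:
        logger.warning("empty candidate pool for products %s (%s)", list(products), policy)
    return sorted(pooled)


def enumerate_and_evaluate(
    model: cobra.Model,
    config: ComboSearchConfig,
    only_passing: bool = False,
) -> list[CoProductionRecord]:
    """Evaluate every intervention set of size 1..max_size from the pool.

    Combinations repeating a reaction are excluded; amplification actions
    whose theoretical maximum is unbounded are dropped from the pool (their
    bounds cannot be pinned). All evaluated combinations are returned with
    pass flags — infeasible mutants appear with ``bio_mut = 0`` and
    ``passed == False`` rather than being dropped — sorted by overall score
    descending. ``only_passing`` filters to records meeting every threshold.
    """
    base = config.base
    pool = candidate_pool(model, config.products, config.pool_policy, base)
    amp_levels = resolve_amp_levels(model, pool, base)
    pool = [
        entry
        for entry in pool
        if entry[1] != AMP or entry[0] in amp_levels  # drop unbounded amplifications
    ]
    reference = wild_type_reference(model, list(config.products), base.fva_fraction)

    records: list[CoProductionRecord] = []
    for size in range(1, config.max_size + 1):
        for combo in combinations(pool, size):
            rids = [rid for rid, _, _ in combo]
            if len(set(rids)) != size:
                continue  # two actions on one reaction
            actions = tuple(
                Intervention(rid, kind, amp_levels.get(rid, 0.0) if kind == AMP else 0.0)
                for rid, kind, _ in combo
            )
            try:
                records.append(
                    evaluate_intervention(
                        model,
                        InterventionSet(actions, max_size=config.max_size),
                        list(config.products),
                        amp_levels=amp_levels,
                        reference=reference,
                        config=base,
                    )
                )
            except Exception:
                logger.exception("combination %s failed; skipping", rids)
    records.sort(key=_record_sort_key)
    if only_passing:
        records = [r for r in records if r.passed]
    return records
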