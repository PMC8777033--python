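"""Enforced-objective flux scanning (FSEOF) for a single product.

The scan pins the product's exchange flux at an increasing ladder of
fractions of its theoretical maximum while biomass stays the FBA objective,
and records the full flux vector at every step. Reactions whose absolute
flux rises monotonically along the ladder are amplification candidates,
reactions whose absolute flux falls are knockout candidates; flat,
oscillating and sign-flipping trajectories are discarded. Exchange and
transport reactions (and the biomass reaction itself) never enter the
search space — they are not enzymatic engineering targets.

Classification consumes plain FBA flux vectors, which are in general not
unique at alternate optima; with the deterministic single-solver setup used
here the scan is reproducible, and on networks with unique optima it is
solver-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from scipy import stats

from .gsmm import AMP, INTERNAL, KO, biomass_reaction, classify_reactions
from .lp import fba

__all__ = [
    "AMP_CANDIDATE",
    "KO_CANDIDATE",
    "DISCARDED_FLAT",
    "DISCARDED_OSCILLATORY",
    "DISCARDED_SIGNFLIP",
    "NotProducibleError",
    "ScanConfig",
    "ScanProfile",
    "TargetClassification",
    "scan",
    "classify",
    "candidate_targets",
    "export_scan_tsv",
]

AMP_CANDIDATE = "AMP_candidate"
KO_CANDIDATE = "KO_candidate"
DISCARDED_FLAT = "discarded_flat"
DISCARDED_OSCILLATORY = "discarded_oscillatory"
DISCARDED_SIGNFLIP = "discarded_signflip"

#: classification label -> intervention kind
LABEL_TO_KIND = {AMP_CANDIDATE: AMP, KO_CANDIDATE: KO}


class NotProducibleError(RuntimeError):
    """The product's maximum exchange flux is (numerically) zero."""


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the enforced-flux ladder and trajectory classification.

    ``n_steps`` equally spaced product-flux fractions spanning
    ``(fraction_min, fraction_max]`` of the product's theoretical maximum
    (default 10%..100%; the 0% point adds nothing — it is the unconstrained
    optimum). ``eps_flat`` (mmol/gDW/h) separates real flux changes from LP
    noise. ``mode`` is ``"strict"`` (per-step monotonicity up to
    ``eps_flat``) or ``"trend"`` (perfect Spearman rank correlation on
    3-point moving-window means, tolerating small per-step wiggles).
    """

    n_steps: int = 10
    fraction_min: float = 0.1
    fraction_max: float = 1.0
    eps_flat: float = 1e-6
    mode: str = "strict"

    def __post_init__(self) -> None:
        if self.n_steps < 3:
            raise ValueError(f"n_steps must be >= 3, got {self.n_steps}")
        if not 0.0 < self.fraction_min < self.fraction_max <= 1.0:
            raise ValueError(
                "fractions must satisfy 0 < fraction_min < fraction_max <= 1, "
                f"got ({self.fraction_min}, {self.fraction_max})"
            )
        if self.mode not in ("strict", "trend"):
            raise ValueError(f"mode must be 'strict' or 'trend', got {self.mode!r}")

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(
            np.linspace(self.fraction_min, self.fraction_max, self.n_steps)
        )


@dataclass
class ScanProfile:
    """Per-reaction flux trajectories across the enforced product-flux steps.

    ``fluxes`` is a reactions x steps DataFrame (columns are the enforced
    fractions of ``v_max_product``); every column is a biomass-optimal FBA
    flux vector with the product exchange pinned.
    """

    product_id: str
    v_max_biomass: float
    v_max_product: float
    fractions: tuple[float, ...]
    fluxes: pd.DataFrame


@dataclass
class TargetClassification:
    """Label per internal reaction, plus the flux direction each target
    carries at the top of the ladder (used to orient amplification levels
    for reversible reactions; +1, -1, or 0 for flux below ``eps_flat``)."""

    product_id: str
    labels: dict[str, str]
    directions: dict[str, int] = field(default_factory=dict)

    def targets(self) -> list[tuple[str, str]]:
        """The (reaction id, KO|AMP) pairs that survived classification,
        sorted by reaction id."""
        return sorted(
            (rid, LABEL_TO_KIND[label])
            for rid, label in self.labels.items()
            if label in LABEL_TO_KIND
        )


def scan(
    model: cobra.Model, product_exchange_id: str, config: ScanConfig | None = None
) -> ScanProfile:
    """Run the enforced-flux scan for one product exchange reaction.

    The model's bounds are restored on return. Raises
    :class:`NotProducibleError` when the product's maximum flux does not
    exceed ``config.eps_flat``.
    """
    config = config or ScanConfig()
    if product_exchange_id not in model.reactions:
        raise KeyError(f"unknown product exchange {product_exchange_id!r}")
    biomass = biomass_reaction(model)

    v_max_bio = fba(model, biomass).objective_value
    product_solution = fba(model, product_exchange_id)
    if not product_solution.ok:
        raise NotProducibleError(
            f"product FBA for {product_exchange_id!r} ended {product_solution.status}"
        )
    v_max_prdt = product_solution.objective_value
    if v_max_prdt <= config.eps_flat:
        raise NotProducibleError(
            f"{product_exchange_id!r} is not producible "
            f"(max flux {v_max_prdt:.3g} <= eps_flat {config.eps_flat:.3g})"
        )

    columns: dict[float, pd.Series] = {}
    product_rxn = model.reactions.get_by_id(product_exchange_id)
    for x in config.fractions:
        pinned = x * v_max_prdt
        with model:
            product_rxn.bounds = (pinned, pinned)
            step = fba(model, biomass)
        if not step.ok:
            raise RuntimeError(
                f"enforced step x={x:.3g} of {product_exchange_id!r} ended "
                f"{step.status}; the pinned value lies inside the feasible range "
                "so this indicates a solver failure"
            )
        columns[x] = step.fluxes
    fluxes = pd.DataFrame(columns)
    fluxes.index.name = "reaction"
    return ScanProfile(
        product_id=product_exchange_id,
        v_max_biomass=v_max_bio,
        v_max_product=v_max_prdt,
        fractions=config.fractions,
        fluxes=fluxes,
    )


def _classify_trajectory(v: np.ndarray, eps: float, mode: str) -> str:
    """Label one signed flux trajectory; see :class:`ScanConfig` for modes."""
    if (v > eps).any() and (v < -eps).any():
        return DISCARDED_SIGNFLIP
    magnitude = np.abs(v)
    if magnitude.max() - magnitude.min() <= eps:
        return DISCARDED_FLAT
    if mode == "strict":
        steps = np.diff(magnitude)
        if (steps >= -eps).all() and magnitude[-1] - magnitude[0] > eps:
            return AMP_CANDIDATE
        if (steps <= eps).all() and magnitude[0] - magnitude[-1] > eps:
            return KO_CANDIDATE
        return DISCARDED_OSCILLATORY
    # trend mode: perfect rank correlation of 3-point moving-window means
    window = np.convolve(magnitude, np.ones(3) / 3.0, mode="valid")
    rho = stats.spearmanr(window, np.arange(window.size)).statistic
    if np.isclose(rho, 1.0) and magnitude[-1] - magnitude[0] > eps:
        return AMP_CANDIDATE
    if np.isclose(rho, -1.0) and magnitude[0] - magnitude[-1] > eps:
        return KO_CANDIDATE
    return DISCARDED_OSCILLATORY


def classify(
    profile: ScanProfile,
    config: ScanConfig | None = None,
    reactions: Sequence[str] | None = None,
) -> TargetClassification:
    """Classify trajectories (all of them, or the given subset)."""
    config = config or ScanConfig()
    rids = list(reactions) if reactions is not None else list(profile.fluxes.index)
    labels: dict[str, str] = {}
    directions: dict[str, int] = {}
    for rid in rids:
        v = profile.fluxes.loc[rid].to_numpy(dtype=float)
        labels[rid] = _classify_trajectory(v, config.eps_flat, config.mode)
        last = v[-1]
        directions[rid] = 0 if abs(last) <= config.eps_flat else (1 if last > 0 else -1)
    return TargetClassification(profile.product_id, labels, directions)


def candidate_targets(
    model: cobra.Model,
    product_exchange_id: str,
    config: ScanConfig | None = None,
    classes: Mapping[str, str] | None = None,
) -> TargetClassification:
    """Scan one product and classify only the internal search space.

    Exchange and transport reactions and the biomass reaction are excluded
    before classification.
    """
    config = config or ScanConfig()
    classes = classes if classes is not None else classify_reactions(model)
    biomass_id = biomass_reaction(model).id
    searchable = [
        r.id
        for r in model.reactions
        if classes[r.id] == INTERNAL and r.id != biomass_id
    ]
    profile = scan(model, product_exchange_id, config)
    return classify(profile, config, reactions=searchable)


def export_scan_tsv(
    profile: ScanProfile,
    path: str | Path,
    classification: TargetClassification | None = None,
) -> None:
    """Write the trajectory table (rows = reactions, columns = fractions),
    with a trailing ``label`` column when a classification is supplied."""
    table = profile.fluxes.copy()
    table.columns = [f"{x:.6g}" for x in profile.fractions]
    if classification is not None:
        table["label"] = [
            classification.labels.get(rid, "") for rid in table.index
        ]
    table.to_csv(path, sep="\t", float_format="%.6g")
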