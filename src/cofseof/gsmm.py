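"""Genome-scale model handling: I/O, reaction classification, media, mutants.

Models are held as :class:`cobra.Model` objects (stoichiometric matrix S of
size m metabolites x n reactions, flux bounds in mmol/gDW/h, linear objective
weights with the biomass reaction flagged through a nonzero coefficient).
This module adds the bookkeeping the strain-design pipeline needs on top:

* structural classification of every reaction as ``exchange`` (boundary
  pseudo-reaction with a single stoichiometric entry, which includes sinks
  and demands), ``transport`` (participants span two or more compartments)
  or ``internal`` — only internal reactions enter the engineering search
  space, since exchanges and transporters are not enzymatic targets;
* medium application (named exchange-bound overrides, BiGG sign convention:
  negative exchange flux is uptake, positive is secretion);
* mutant construction from small intervention sets — knockouts close both
  bounds to zero, amplifications pin both bounds at a fixed flux level,
  emulating constitutive overexpression at the reaction's capacity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import cobra
import yaml
from cobra.io import load_json_model, read_sbml_model, save_json_model

__all__ = [
    "EXCHANGE",
    "TRANSPORT",
    "INTERNAL",
    "KO",
    "AMP",
    "THEORETICAL_MAX",
    "ModelValidationError",
    "MediumSpec",
    "Intervention",
    "InterventionSet",
    "load_model",
    "save_model",
    "biomass_reaction",
    "validate_model",
    "classify_reactions",
    "apply_medium",
    "apply_interventions",
]

EXCHANGE = "exchange"
TRANSPORT = "transport"
INTERNAL = "internal"

KO = "KO"
AMP = "AMP"
#: Sentinel amplification level: resolve to the reaction's theoretical
#: maximum flux at mutant-construction time (see :func:`cofseof.lp.theoretical_max`).
THEORETICAL_MAX = "theoretical_max"

#: BiGG-style compartment suffix, e.g. ``glc__D_e`` -> ``e``. Overridable for
#: models using other id schemes.
COMPARTMENT_SUFFIX = re.compile(r"_([a-zA-Z][a-zA-Z0-9]{0,3})$")


class ModelValidationError(ValueError):
    """A model or configuration violates a structural requirement."""


# ---------------------------------------------------------------------------
# model I/O


def load_model(path: str | Path, fmt: str | None = None) -> cobra.Model:
    """Load an SBML (L3 + fbc) or BiGG-style JSON model and validate it.

    Parameters
    ----------
    path:
        Model file. Format is inferred from the suffix (``.json`` vs
        ``.xml``/``.sbml``) unless *fmt* (``"json"`` or ``"sbml"``) is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "sbml"
    if fmt == "json":
        model = load_json_model(str(path))
    elif fmt == "sbml":
        model = read_sbml_model(str(path))
    else:
        raise ValueError(f"unknown model format {fmt!r} (expected 'json' or 'sbml')")
    validate_model(model)
    return model


def save_model(model: cobra.Model, path: str | Path) -> None:
    """Write *model* as BiGG-style JSON (stable, pretty-printed byte layout)."""
    save_json_model(model, str(path), sort=False, pretty=True)


def biomass_reaction(model: cobra.Model) -> cobra.Reaction:
    """Return the single reaction flagged by a nonzero objective weight."""
    flagged = [r for r in model.reactions if r.objective_coefficient]
    if len(flagged) != 1:
        raise ModelValidationError(
            f"model {model.id!r} must flag exactly one biomass/objective reaction, "
            f"found {len(flagged)}: {[r.id for r in flagged]}"
        )
    return flagged[0]


def validate_model(model: cobra.Model) -> None:
    """Check the structural invariants required by the pipeline.

    Raises
    ------
    ModelValidationError
        On inverted bounds, missing/ambiguous biomass flag, or reactions
        without any stoichiometry (columns referencing no metabolite).
    """
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        if math.isnan(rxn.lower_bound) or math.isnan(rxn.upper_bound):
            raise ModelValidationError(f"reaction {rxn.id!r} has NaN bounds")
    biomass_reaction(model)


# ---------------------------------------------------------------------------
# reaction classification


def compartment_of(met: cobra.Metabolite, pattern: re.Pattern = COMPARTMENT_SUFFIX) -> str:
    """Compartment tag of a metabolite: the annotated compartment, else the
    id suffix matched by *pattern*, else ``""``."""
    if met.compartment:
        return str(met.compartment)
    hit = pattern.search(met.id)
    return hit.group(1) if hit else ""


def classify_reactions(
    model: cobra.Model, pattern: re.Pattern = COMPARTMENT_SUFFIX
) -> dict[str, str]:
    """Assign every reaction to exactly one of exchange/transport/internal.

    A reaction is *exchange* iff its column of S has exactly one nonzero
    entry (boundary pseudo-reactions, including sinks and demands),
    *transport* iff its participating metabolites span at least two
    compartments, and *internal* otherwise. Total and deterministic.
    """
    classes: dict[str, str] = {}
    for rxn in model.reactions:
        mets = [m for m, coef in rxn.metabolites.items() if coef != 0]
        if len(mets) <= 1:
            classes[rxn.id] = EXCHANGE
        elif len({compartment_of(m, pattern) for m in mets}) >= 2:
            classes[rxn.id] = TRANSPORT
        else:
            classes[rxn.id] = INTERNAL
    return classes


# ---------------------------------------------------------------------------
# media


def _load_media_presets() -> dict[str, dict[str, list[float]]]:
    text = resources.files("cofseof.data").joinpath("media.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class MediumSpec:
    """Named exchange-bound overrides defining a growth condition.

    ``bounds`` maps exchange-reaction ids to ``(lower, upper)`` flux bounds in
    mmol/gDW/h, BiGG sign convention (negative = uptake). Exchange reactions
    not named keep their model-default bounds.
    """

    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    label: str = "custom"

    @classmethod
    def preset(cls, name: str) -> "MediumSpec":
        """A packaged preset: ``aerobic`` (glucose −10, O2 −2 mmol/gDW/h) or
        ``anaerobic`` (glucose −10, zero O2 uptake)."""
        presets = _load_media_presets()
        if name not in presets:
            raise KeyError(
                f"unknown medium preset {name!r}; available: {sorted(presets)}"
            )
        bounds = {rid: (float(lb), float(ub)) for rid, (lb, ub) in presets[name].items()}
        return cls(bounds=bounds, label=name)

    @classmethod
    def aerobic(cls) -> "MediumSpec":
        return cls.preset("aerobic")

    @classmethod
    def anaerobic(cls) -> "MediumSpec":
        return cls.preset("anaerobic")

    @classmethod
    def from_yaml(cls, path: str | Path, label: str | None = None) -> "MediumSpec":
        """Read ``{exchange_id: [lb, ub], ...}`` from a YAML file."""
        raw = yaml.safe_load(Path(path).read_text())
        bounds = {rid: (float(lb), float(ub)) for rid, (lb, ub) in raw.items()}
        return cls(bounds=bounds, label=label or Path(path).stem)


def apply_medium(model: cobra.Model, medium: MediumSpec) -> cobra.Model:
    """Return a copy of *model* with the medium's exchange bounds applied.

    Raises
    ------
    ModelValidationError
        If a named id is missing from the model or is not an exchange
        reaction (single-entry column of S).
    """
    classes = classify_reactions(model)
    unknown = [rid for rid in medium.bounds if rid not in model.reactions]
    if unknown:
        raise ModelValidationError(
            f"medium {medium.label!r} names exchange reactions absent from the "
            f"model: {sorted(unknown)}"
        )
    non_exchange = [rid for rid in medium.bounds if classes[rid] != EXCHANGE]
    if non_exchange:
        raise ModelValidationError(
            f"medium {medium.label!r} names non-exchange reactions: "
            f"{sorted(non_exchange)}"
        )
    constrained = model.copy()
    for rid, (lb, ub) in medium.bounds.items():
        constrained.reactions.get_by_id(rid).bounds = (lb, ub)
    return constrained


# ---------------------------------------------------------------------------
# interventions


@dataclass(frozen=True)
class Intervention:
    """One engineering action on a reaction.

    ``kind`` is ``KO`` (close both bounds to zero) or ``AMP`` (pin both
    bounds at ``level``). For AMP, ``level`` is a finite flux in mmol/gDW/h
    or the :data:`THEORETICAL_MAX` sentinel, resolved by the caller before
    mutant construction.
    """

    reaction_id: str
    kind: str
    level: float | str = THEORETICAL_MAX

    def __post_init__(self) -> None:
        if self.kind not in (KO, AMP):
            raise ValueError(f"intervention kind must be KO or AMP, got {self.kind!r}")


@dataclass(frozen=True)
class InterventionSet:
    """An ordered set of 1–``max_size`` actions on distinct reactions."""

    actions: tuple[Intervention, ...]
    max_size: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "actions", tuple(self.actions))
        if not 1 <= len(self.actions) <= self.max_size:
            raise ValueError(
                f"intervention set must contain 1..{self.max_size} actions, "
                f"got {len(self.actions)}"
            )
        rids = [a.reaction_id for a in self.actions]
        if len(set(rids)) != len(rids):
            raise ValueError(f"duplicate reaction in intervention set: {rids}")

    def __iter__(self) -> Iterator[Intervention]:
        return iter(self.actions)

    def __len__(self) -> int:
        return len(self.actions)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(a.reaction_id for a in self.actions)

    def signature(self) -> str:
        """ASCII action signature, 'A' per amplification and 'K' per knockout."""
        return "".join("A" if a.kind == AMP else "K" for a in self.actions)

    def validate_against(
        self, model: cobra.Model, classes: Mapping[str, str] | None = None
    ) -> None:
        """Check every action targets an existing internal, non-biomass reaction."""
        classes = classes if classes is not None else classify_reactions(model)
        biomass_id = biomass_reaction(model).id
        for action in self.actions:
            rid = action.reaction_id
            if rid not in model.reactions:
                raise ModelValidationError(f"intervention names unknown reaction {rid!r}")
            if rid == biomass_id:
                raise ModelValidationError("biomass reaction cannot be an intervention target")
            if classes.get(rid) != INTERNAL:
                raise ModelValidationError(
                    f"reaction {rid!r} is {classes.get(rid)}; only internal reactions "
                    "are valid intervention targets"
                )


def apply_interventions(
    model: cobra.Model,
    interventions: InterventionSet,
    amp_levels: Mapping[str, float] | None = None,
) -> cobra.Model:
    """Build the mutant model for an intervention set; the input is untouched.

    KO actions set both bounds of the reaction to zero; AMP actions fix both
    bounds at the amplification level taken from *amp_levels* (keyed by
    reaction id) or, failing that, from the action's own ``level``. The level
    must be finite — an unbounded theoretical maximum cannot be pinned.
    """
    mutant = model.copy()
    for action in interventions:
        if action.reaction_id not in mutant.reactions:
            raise ModelValidationError(
                f"intervention names unknown reaction {action.reaction_id!r}"
            )
        rxn = mutant.reactions.get_by_id(action.reaction_id)
        if action.kind == KO:
            rxn.bounds = (0.0, 0.0)
        else:
            level: float | str | None = None
            if amp_levels is not None and action.reaction_id in amp_levels:
                level = amp_levels[action.reaction_id]
            else:
                level = action.level
            if not isinstance(level, (int, float)) or not math.isfinite(level):
                raise ModelValidationError(
                    f"amplification of {action.reaction_id!r} needs a finite flux "
                    f"level, got {level!r}"
                )
            rxn.bounds = (float(level), float(level))
    return mutant
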