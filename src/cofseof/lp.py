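"""Linear-programming layer: FBA, batched FVA, theoretical-maximum queries.

Flux balance analysis solves ``max c^T v`` subject to ``S v = 0`` and
``vl <= v <= vu``; flux variability analysis fixes the objective at a
fraction of its optimum and then minimises/maximises each queried reaction
flux in turn, reusing one solver instance across the whole batch (warm
restarts). Both are delegated to cobrapy's solver stack (GLPK by default);
this module normalises statuses, tolerances and error handling so the
scanning and screening layers above never talk to a solver directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import cobra
import pandas as pd
from cobra.flux_analysis import flux_variability_analysis

from .gsmm import biomass_reaction

__all__ = [
    "FEASIBILITY_TOL",
    "InfeasibleError",
    "SolverError",
    "FluxDistribution",
    "FVAResult",
    "fba",
    "fva",
    "theoretical_max",
]

#: Acceptance tolerance on mass balance and bound violations; a comfortable
#: margin above the backend solver's own (1e-9) tolerances.
FEASIBILITY_TOL = 1e-6

_UNBOUNDED_STATUSES = {"unbounded", "infeasible_or_unbounded", "undefined"}


class InfeasibleError(RuntimeError):
    """The LP has no feasible point under the requested constraints."""


class SolverError(RuntimeError):
    """The backend solver failed for a non-structural (numerical) reason."""


@dataclass
class FluxDistribution:
    """One steady-state flux vector with its objective value.

    ``fluxes`` is indexed by reaction id (mmol/gDW/h); it is ``None`` when
    the problem was not solved to optimality. Infeasibility is propagated in
    ``status`` rather than raised, so screening loops can record and move on.
    """

    fluxes: pd.Series | None
    objective_value: float
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a fixed fraction of the optimal objective.

    ``bounds`` has one row per queried reaction with columns ``minimum`` and
    ``maximum`` (mmol/gDW/h).
    """

    bounds: pd.DataFrame
    fraction_of_optimum: float

    def minimum(self, reaction_id: str) -> float:
        return float(self.bounds.at[reaction_id, "minimum"])

    def maximum(self, reaction_id: str) -> float:
        return float(self.bounds.at[reaction_id, "maximum"])


def _rid(reaction: str | cobra.Reaction) -> str:
    return reaction.id if hasattr(reaction, "id") else str(reaction)


def fba(
    model: cobra.Model,
    objective: str | cobra.Reaction | None = None,
    sense: str = "max",
) -> FluxDistribution:
    """Solve one flux balance problem.

    Parameters
    ----------
    objective:
        Reaction to optimise; defaults to the model's flagged objective.
    sense:
        ``"max"`` or ``"min"``.

    Non-optimal solver terminations are returned in ``status`` (objective 0,
    no fluxes), never raised.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    with model:
        if objective is not None:
            model.objective = model.reactions.get_by_id(_rid(objective))
        model.objective_direction = "max" if sense == "max" else "min"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            solution = model.optimize(raise_error=False)
    if solution.status != "optimal":
        return FluxDistribution(None, 0.0, solution.status)
    return FluxDistribution(
        solution.fluxes.copy(), float(solution.objective_value), "optimal"
    )


def fva(
    model: cobra.Model,
    reactions: list[str | cobra.Reaction] | None = None,
    fraction_of_optimum: float = 1.0,
) -> FVAResult:
    """Batched flux variability analysis.

    The flagged objective is first maximised, its lower bound is fixed at
    ``fraction_of_optimum`` times that optimum, and each queried reaction is
    then minimised and maximised (two LPs per reaction) on a single solver
    instance.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError(
            f"fraction_of_optimum must lie in [0, 1], got {fraction_of_optimum}"
        )
    reaction_ids = [_rid(r) for r in (reactions if reactions is not None else model.reactions)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            frame = flux_variability_analysis(
                model,
                reaction_list=reaction_ids,
                fraction_of_optimum=fraction_of_optimum,
                processes=1,
            )
    except Exception as exc:  # cobra raises Infeasible (optlang) subclasses
        raise InfeasibleError(
            f"FVA infeasible at objective fraction {fraction_of_optimum}: {exc}"
        ) from exc
    return FVAResult(bounds=frame, fraction_of_optimum=fraction_of_optimum)


def theoretical_max(
    model: cobra.Model,
    reaction: str | cobra.Reaction,
    direction: int = 1,
    biomass_fraction: float = 0.0,
) -> float:
    """Largest flux a reaction can carry under stoichiometry and bounds.

    With ``direction=+1`` the flux is maximised; with ``-1`` it is minimised
    (the theoretical maximum of the reverse direction, returned as a negative
    value suitable for pinning a reversible reaction). By default no growth
    is required (``biomass_fraction=0``); a positive fraction additionally
    holds biomass at that share of its optimum.

    Returns ``±inf`` when the LP is unbounded — such reactions cannot be
    amplification targets (their bounds cannot be pinned at infinity).
    """
    rid = _rid(reaction)
    if rid not in model.reactions:
        raise KeyError(f"unknown reaction {rid!r}")
    with model:
        if biomass_fraction > 0.0:
            bio = biomass_reaction(model)
            opt = model.slim_optimize(error_value=None)
            if opt is None:
                raise InfeasibleError("model infeasible while fixing biomass for theoretical_max")
            bio.lower_bound = biomass_fraction * opt
        model.objective = model.reactions.get_by_id(rid)
        model.objective_direction = "max" if direction >= 0 else "min"
        value = model.slim_optimize(error_value=math.nan)
        status = model.solver.status
    if status in _UNBOUNDED_STATUSES:
        return math.inf if direction >= 0 else -math.inf
    if status != "optimal" or math.isnan(value):
        raise InfeasibleError(
            f"theoretical_max({rid!r}) did not solve to optimality (status {status!r})"
        )
    return float(value)
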