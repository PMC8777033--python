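"""Deterministic toy metabolic networks with analytically known outcomes.

These small branched carbon networks make every layer of the pipeline
testable without downloading genome-scale models. They are trees (one
substrate, dedicated branches, no alternative routes of equal carbon
yield), so every LP in the pipeline has a unique optimum and results are
solver-independent — which real genome-scale models, with their massive
degeneracy, are not.

``toynet_a``: a linear chain with one product branch. Glucose enters at up
to 10 mmol/gDW/h, is doubled into precursor A, and A is split between the
biomass route (R2 -> B -> biomass) and the product route (R3 -> P,
secreted). Wild-type biomass flux is 20; the product's theoretical maximum
is 20; the enforced-flux scan marks R3 for amplification and R2 for
knockout.

``toynet_b``: the co-production scenario. The product branch is replaced by
R5: A -> P + Q, stoichiometrically coupling two secreted products, and R5
is capacity-capped at 12 so that amplifying it to its theoretical maximum
leaves carbon for growth (mutant biomass 8 = 40% of wild type). (R5, AMP)
is the unique passing common target for the pair (P, Q).

``random_toy``: seeded branched networks in the same family, with one
coupled branch shared by the first two products, randomized stoichiometry
in {1,2,3} and randomized branch capacities.
"""

from __future__ import annotations

from importlib import resources

import cobra
import numpy as np
from cobra import Metabolite, Model, Reaction

__all__ = [
    "toynet_a",
    "toynet_b",
    "random_toy",
    "packaged_fixture_text",
    "TOYNET_A_FACTS",
    "TOYNET_B_FACTS",
]

_BIG = 1000.0

#: Hand-derived expectations for the fixed fixtures; every entry is
#: re-verified against an independent LP oracle in the test suite.
TOYNET_A_FACTS = {
    "n_metabolites": 6,
    "n_reactions": 8,
    "biomass_max": 20.0,
    "product_max": {"EX_P_e": 20.0},
    "amp_candidates": {"EX_P_e": ["R3"]},
    "ko_candidates": {"EX_P_e": ["R2"]},
    "flat": {"EX_P_e": ["R1"]},
}

TOYNET_B_FACTS = {
    "biomass_max": 20.0,
    "product_max": {"EX_P_e": 12.0, "EX_Q_e": 12.0},
    "secretory": ["EX_P_e", "EX_Q_e"],
    "common_amp": ["R5"],
    "common_ko": ["R2"],
    "amp_r5_level": 12.0,
    "amp_r5_mutant_biomass": 8.0,
    "amp_r5_scores": {"EX_P_e": 1.0, "EX_Q_e": 1.0},
}


def _reaction(rid: str, mets: dict, lb: float = 0.0, ub: float = _BIG) -> Reaction:
    rxn = Reaction(rid, lower_bound=lb, upper_bound=ub)
    rxn.add_metabolites(mets)
    return rxn


def toynet_a() -> Model:
    """Linear chain: glc -> 2 A; A split between biomass and product P."""
    model = Model("toynet_a")
    glc_e = Metabolite("glc_e", compartment="e")
    glc_c = Metabolite("glc_c", compartment="c")
    a = Metabolite("A_c", compartment="c")
    b = Metabolite("B_c", compartment="c")
    p = Metabolite("P_c", compartment="c")
    p_e = Metabolite("P_e", compartment="e")
    model.add_reactions(
        [
            _reaction("EX_glc_e", {glc_e: -1}, lb=-10.0),
            _reaction("T_glc", {glc_e: -1, glc_c: 1}),
            _reaction("R1", {glc_c: -1, a: 2}),
            _reaction("R2", {a: -1, b: 1}),
            _reaction("R3", {a: -1, p: 1}),
            _reaction("BIOMASS", {b: -1}),
            _reaction("T_P", {p: -1, p_e: 1}),
            _reaction("EX_P_e", {p_e: -1}),
        ]
    )
    model.objective = "BIOMASS"
    return model


def toynet_b() -> Model:
    """toynet_a with the product branch replaced by the coupled reaction
    R5: A -> P + Q (capacity 12), plus transport/exchange for Q."""
    model = toynet_a()
    model.id = "toynet_b"
    model.remove_reactions(["R3"], remove_orphans=False)
    a = model.metabolites.get_by_id("A_c")
    p = model.metabolites.get_by_id("P_c")
    q = Metabolite("Q_c", compartment="c")
    q_e = Metabolite("Q_e", compartment="e")
    model.add_reactions(
        [
            _reaction("R5", {a: -1, p: 1, q: 1}, ub=12.0),
            _reaction("T_Q", {q: -1, q_e: 1}),
            _reaction("EX_Q_e", {q_e: -1}),
        ]
    )
    model.objective = "BIOMASS"
    return model


def random_toy(seed: int, n_branches: int = 3) -> Model:
    """Seeded branched carbon network: one substrate, ``n_branches``
    dedicated product branches, one biomass branch, and (for two or more
    branches) one capacity-capped coupled branch producing the first two
    products at a strictly better carbon yield than their dedicated routes.

    Stoichiometric coefficients are drawn from {1, 2, 3} and dedicated
    branch capacities from {5, 8, unbounded}; the same seed always yields
    the identical model.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    model = Model(f"toy_rand_s{seed}_k{n_branches}")
    glc_e = Metabolite("glc_e", compartment="e")
    glc_c = Metabolite("glc_c", compartment="c")
    a = Metabolite("A_c", compartment="c")
    b = Metabolite("B_c", compartment="c")
    reactions = [
        _reaction("EX_glc_e", {glc_e: -1}, lb=-10.0),
        _reaction("T_glc", {glc_e: -1, glc_c: 1}),
        _reaction("R1", {glc_c: -1, a: int(rng.integers(1, 4))}),
        _reaction("R_bio", {a: -1, b: int(rng.integers(1, 4))}),
        _reaction("BIOMASS", {b: -1}),
    ]
    products = []
    for i in range(1, n_branches + 1):
        p_c = Metabolite(f"P{i}_c", compartment="c")
        p_e = Metabolite(f"P{i}_e", compartment="e")
        products.append(p_c)
        yield_i = int(rng.integers(1, 3))  # dedicated yield 1 or 2 per A
        cap = float(rng.choice([5.0, 8.0, _BIG]))
        reactions.extend(
            [
                _reaction(f"RP{i}", {a: -1, p_c: yield_i}, ub=cap),
                _reaction(f"T_P{i}", {p_c: -1, p_e: 1}),
                _reaction(f"EX_P{i}_e", {p_e: -1}),
            ]
        )
    if n_branches >= 2:
        # coupled branch: strictly better yield (3) than any dedicated route,
        # small capacity so amplification can leave residual growth
        cap = float(rng.choice([4.0, 6.0, 8.0]))
        reactions.append(
            _reaction("RC", {a: -1, products[0]: 3, products[1]: 3}, ub=cap)
        )
    model.add_reactions(reactions)
    model.objective = "BIOMASS"
    return model


def packaged_fixture_text(name: str) -> str:
    """Raw JSON text of a packaged fixture (``toynet_a`` or ``toynet_b``)."""
    return resources.files("cofseof.data").joinpath(f"{name}.json").read_text()
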