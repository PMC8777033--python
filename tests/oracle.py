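"""Independent naive LP oracle used to cross-check the implementation.

Everything here is deliberately primitive and separate from the package's
solving path: the stoichiometric matrix is assembled by hand, every query
is a fresh ``scipy.optimize.linprog`` (HiGHS) call — a different solver
from the cobrapy/GLPK stack under test — and the scan/classification/
validation/scoring rules are re-implemented from their definitions. Only
model *data* (ids, stoichiometry, bounds, objective flag) is read from the
cobra container.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.optimize import linprog

EPS = 1e-6


def _matrices(model, overrides=None):
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rids = [r.id for r in model.reactions]
    S = np.zeros((len(met_index), len(rids)))
    bounds = []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if overrides and rxn.id in overrides:
            lb, ub = overrides[rxn.id]
        bounds.append((lb, ub))
    return S, bounds, rids


def biomass_id(model):
    flagged = [r.id for r in model.reactions if r.objective_coefficient]
    assert len(flagged) == 1
    return flagged[0]


def solve(model, objective, sense="max", overrides=None):
    """One LP: returns (status, objective value, {reaction: flux})."""
    S, bounds, rids = _matrices(model, overrides)
    c = np.zeros(len(rids))
    c[rids.index(objective)] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 3:
        return "unbounded", math.inf if sense == "max" else -math.inf, None
    if res.status != 0:
        return "infeasible", None, None
    return "optimal", float(res.x[rids.index(objective)]), dict(zip(rids, res.x))


def fva(model, reaction_ids, fraction, overrides=None):
    """Two independent LPs per reaction after fixing biomass at the fraction."""
    bio = biomass_id(model)
    status, opt, _ = solve(model, bio, overrides=overrides)
    assert status == "optimal", status
    fixed = dict(overrides or {})
    bio_ub = next(r.upper_bound for r in model.reactions if r.id == bio)
    if bio in fixed:
        bio_ub = fixed[bio][1]
    fixed[bio] = (fraction * opt, bio_ub)
    out = {}
    for rid in reaction_ids:
        _, lo, _ = solve(model, rid, sense="min", overrides=fixed)
        _, hi, _ = solve(model, rid, sense="max", overrides=fixed)
        out[rid] = (lo, hi)
    return out


def classify_trajectory(trajectory, eps=EPS):
    """Re-derivation of the trajectory rules from their definitions."""
    t = np.asarray(trajectory, dtype=float)
    if (t > eps).any() and (t < -eps).any():
        return "discarded_signflip"
    m = np.abs(t)
    if m.max() - m.min() <= eps:
        return "discarded_flat"
    rises = all(m[i + 1] - m[i] >= -eps for i in range(len(m) - 1))
    falls = all(m[i + 1] - m[i] <= eps for i in range(len(m) - 1))
    if rises and m[-1] - m[0] > eps:
        return "AMP_candidate"
    if falls and m[0] - m[-1] > eps:
        return "KO_candidate"
    return "discarded_oscillatory"


def scan(model, product_id, fractions):
    """Pinned-product ladder, one naive LP per step."""
    bio = biomass_id(model)
    status, vmax, _ = solve(model, product_id)
    assert status == "optimal" and vmax > EPS
    steps = []
    for x in fractions:
        pinned = x * vmax
        status, _, fluxes = solve(model, bio, overrides={product_id: (pinned, pinned)})
        assert status == "optimal", f"step {x} {status}"
        steps.append(fluxes)
    return vmax, steps


def internal_reactions(model):
    """Exchange/transport pruning re-derived from the definitions."""
    bio = biomass_id(model)
    keep = []
    for rxn in model.reactions:
        mets = [m for m, c in rxn.metabolites.items() if c != 0]
        if len(mets) <= 1 or rxn.id == bio:
            continue
        if len({m.compartment or m.id.rsplit("_", 1)[-1] for m in mets}) >= 2:
            continue
        keep.append(rxn.id)
    return keep


def candidate_targets(model, product_id, fractions, eps=EPS):
    """(labels, final-step directions) over the internal search space."""
    _, steps = scan(model, product_id, fractions)
    labels, directions = {}, {}
    for rid in internal_reactions(model):
        traj = [s[rid] for s in steps]
        labels[rid] = classify_trajectory(traj, eps)
        last = traj[-1]
        directions[rid] = 0 if abs(last) <= eps else (1 if last > 0 else -1)
    return labels, directions


def secretory(model, eps=EPS):
    """Exchange reactions that can carry positive flux, with WT secretion."""
    bio = biomass_id(model)
    out = []
    for rxn in model.reactions:
        mets = [m for m, c in rxn.metabolites.items() if c != 0]
        if len(mets) != 1 or rxn.id == bio:
            continue
        capability = fva(model, [rxn.id], 0.0)[rxn.id][1]
        if capability > eps:
            wt = fva(model, [rxn.id], 1.0)[rxn.id][1]
            out.append((rxn.id, wt))
    return sorted(out)


def theoretical_max(model, rid, direction=1):
    sense = "max" if direction >= 0 else "min"
    status, value, _ = solve(model, rid, sense=sense)
    if status == "unbounded":
        return math.inf if direction >= 0 else -math.inf
    assert status == "optimal"
    return value


def evaluate(model, actions, products, wt_reference, *, gain=0.05, abs_gain=1e-3,
             wt_zero=1e-5, retention=0.25, eps_bio=1e-4):
    """Validate and score one intervention set with naive LPs.

    ``actions`` is a list of (reaction_id, kind, level) with level already
    resolved for amplifications. Returns a comparable summary dict.
    """
    bio_wt, wt_flux = wt_reference
    overrides = {}
    for rid, kind, level in actions:
        overrides[rid] = (0.0, 0.0) if kind == "KO" else (level, level)
    bio = biomass_id(model)
    status, bio_mut, _ = solve(model, bio, overrides=overrides)
    if status != "optimal":
        bio_mut, mut_flux = 0.0, {p: 0.0 for p in products}
    else:
        ranges = fva(model, products, 1.0, overrides=overrides)
        mut_flux = {p: ranges[p][1] for p in products}
    gain_pass = {}
    for p in products:
        if wt_flux[p] < wt_zero:
            gain_pass[p] = mut_flux[p] > abs_gain
        else:
            gain_pass[p] = mut_flux[p] > (1.0 + gain) * wt_flux[p]
    biomass_pass = bio_mut >= retention * bio_wt
    denom = max(bio_wt - bio_mut, eps_bio)
    scores = {
        p: (mut_flux[p] - (0.0 if wt_flux[p] < wt_zero else wt_flux[p])) / denom
        for p in products
    }
    return {
        "bio_mut": bio_mut,
        "mut_flux": mut_flux,
        "passed": biomass_pass and all(gain_pass.values()),
        "scores": scores,
        "overall": sum(scores.values()),
    }


def pairwise(model, fractions, eps=EPS):
    """Full naive co-production sweep; returns {(pair, rids, sig): summary}."""
    secretory_list = secretory(model, eps)
    exchange_ids = [eid for eid, _ in secretory_list]
    wt_flux = dict(secretory_list)
    _, bio_wt, _ = solve(model, biomass_id(model))
    per_product = {eid: candidate_targets(model, eid, fractions, eps) for eid in exchange_ids}
    results = {}
    for a, b in combinations(sorted(exchange_ids), 2):
        la, da = per_product[a]
        lb, db = per_product[b]
        for rid in sorted(set(la) & set(lb)):
            kind = {"AMP_candidate": "AMP", "KO_candidate": "KO"}.get(la[rid])
            if kind is None or lb[rid] != la[rid]:
                continue
            if kind == "AMP" and da[rid] != db[rid]:
                continue
            if kind == "AMP":
                level = theoretical_max(model, rid, da[rid])
                if not math.isfinite(level):
                    continue
            else:
                level = 0.0
            summary = evaluate(
                model, [(rid, kind, level)], [a, b], (bio_wt, wt_flux)
            )
            results[((a, b), (rid,), "A" if kind == "AMP" else "K")] = summary
    return results
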