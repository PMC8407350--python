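"""Independent test oracles, kept free of the code paths they check."""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def vertex_enumeration_optimum(S, lb, ub, c, tol=1e-9):
    """Brute-force LP optimum of max c'v s.t. S v = 0, lb <= v <= ub.

    Enumerates candidate vertices of the flux polytope: every subset of
    variables pinned at a finite bound with the remainder solved from
    the equality system.  Only valid for tiny networks.
    """
    S = np.asarray(S, float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    best = None
    n_free = rank
    for free in combinations(range(n), n_free):
        fixed = [j for j in range(n) if j not in free]
        A = S[:, free]
        for choice in product(*[(lb[j], ub[j]) for j in fixed]):
            b = -S[:, fixed] @ np.asarray(choice)
            x_free, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.linalg.norm(A @ x_free - b) > tol:
                continue
            v = np.empty(n)
            v[list(free)] = x_free
            v[fixed] = choice
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best


def degree_of_reduction(formula, charge):
    """Electrons available relative to CO2/H2O/NH4+/HPO4^2-/SO4^2-."""
    f = formula or {}
    return (
        4 * f.get("C", 0)
        + f.get("H", 0)
        - 2 * f.get("O", 0)
        - 3 * f.get("N", 0)
        + 5 * f.get("P", 0)
        + 6 * f.get("S", 0)
        - charge
    )


def electron_balance_residual(model, solution):
    """Net degree-of-reduction flux across all exchanges plus biomass.

    At steady state with balanced internal reactions, the electrons
    entering via exchanged species must equal the electrons leaving via
    exchanged species and biomass; the residual is the biomass term,
    returned so tests can close the balance against biomass composition.
    """
    total = 0.0
    for r in model.reactions:
        if r.subsystem != "exchange":
            continue
        v = solution.fluxes.get(r.id, 0.0)
        for sid, coef in r.stoichiometry.items():
            sp = model.get_species(sid)
            # exchange convention: coef=-1, flux<0 is uptake
            total += v * coef * degree_of_reduction(sp.formula, sp.charge)
    return total


def biomass_electron_content(model):
    """Degree-of-reduction drained per unit biomass flux (per gDW)."""
    bm = model.get_reaction("biomass")
    total = 0.0
    for sid, coef in bm.stoichiometry.items():
        sp = model.get_species(sid)
        total += -coef * degree_of_reduction(sp.formula, sp.charge)
    return total
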