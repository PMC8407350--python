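"""Flux balance analysis: Max c'v subject to S v = 0, vmin <= v <= vmax.

The LP is solved with the HiGHS routines behind
:func:`scipy.optimize.linprog`.  Optimal solutions are reported as the
parsimonious flux distribution: total absolute flux is minimized in a
second LP with the objective pinned at its optimum, so that degenerate
alternative optima yield one reproducible flux vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .core import MetabolicModel, Reaction

FEAS_TOL = 1e-9
OPT_TOL = 1e-8


class FBAError(ValueError):
    pass


@dataclass(frozen=True)
class BoundOverride:
    reaction_id: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(
                f"override for {self.reaction_id!r}: lower {self.lower} > upper {self.upper}"
            )


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_id: str = ""

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _apply_overrides(
    model: MetabolicModel, overrides: Sequence[BoundOverride]
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = model.bounds()
    idx = {rid: i for i, rid in enumerate(model.reaction_ids)}
    for ov in overrides:
        if ov.reaction_id not in idx:
            raise FBAError(f"override references unknown reaction {ov.reaction_id!r}")
        i = idx[ov.reaction_id]
        lb[i], ub[i] = ov.lower, ov.upper
    return lb, ub


def _linprog(c, A_eq, b_eq, lb, ub):
    return linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )


def solve_fba(
    model: MetabolicModel,
    overrides: Sequence[BoundOverride] = (),
    objective: Optional[str] = None,
    sense: str = "max",
    parsimonious: bool = True,
) -> FluxSolution:
    """Solve the FBA linear program.

    Infeasibility and unboundedness are reported in ``status``, never
    silently as zero fluxes.  With ``parsimonious`` (default) the
    returned flux vector additionally minimizes total absolute flux at
    the fixed optimal objective.
    """
    objective = objective or model.objective_id
    if not model.has_reaction(objective):
        raise FBAError(f"objective {objective!r} not in model")
    if sense not in ("max", "min"):
        raise FBAError(f"sense must be max or min, got {sense!r}")

    S = model.stoichiometric_matrix()
    lb, ub = _apply_overrides(model, overrides)
    n = len(model.reactions)
    j_obj = model.reaction_ids.index(objective)
    c = np.zeros(n)
    c[j_obj] = -1.0 if sense == "max" else 1.0

    res = _linprog(c, S, np.zeros(S.shape[0]), lb, ub)
    if res.status == 2:
        return FluxSolution("infeasible", float("nan"), {}, objective)
    if res.status == 3:
        return FluxSolution("unbounded", float("nan"), {}, objective)
    if not res.success:  # pragma: no cover - numerical failure
        raise FBAError(f"LP solver failed: {res.message}")
    z_opt = res.x[j_obj]

    x = res.x
    if parsimonious:
        # min sum |v| with v = p - q, p,q >= 0, objective flux pinned
        lb2 = lb.copy()
        ub2 = ub.copy()
        lb2[j_obj] = ub2[j_obj] = z_opt
        A = np.hstack([S, -S])
        lo = np.concatenate([np.clip(lb2, 0, None), np.clip(-ub2, 0, None)])
        hi = np.concatenate([np.clip(ub2, 0, None), np.clip(-lb2, 0, None)])
        res2 = _linprog(np.ones(2 * n), A, np.zeros(S.shape[0]), lo, hi)
        if res2.success:
            x = res2.x[:n] - res2.x[n:]

    fluxes = dict(zip(model.reaction_ids, x))
    return FluxSolution("optimal", float(z_opt), fluxes, objective)


def knockout(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Copy of the model with both bounds of ``reaction_id`` set to zero."""
    if not model.has_reaction(reaction_id):
        raise FBAError(f"cannot knock out unknown reaction {reaction_id!r}")
    out = model.copy()
    r = out.get_reaction(reaction_id)
    r.lower_bound = 0.0
    r.upper_bound = 0.0
    return out


DONOR_EXCHANGE = {"nitrite": "EX_no2_e", "formate": "EX_for_e"}


def atp_yield(model: MetabolicModel, electron_donor: str) -> float:
    """Net ATP yield (mmol ATP per mmol donor): maximize maintenance-ATP
    flux at unit donor uptake with growth fixed to zero."""
    if electron_donor not in DONOR_EXCHANGE:
        raise FBAError(f"unknown electron donor {electron_donor!r}")
    ex = DONOR_EXCHANGE[electron_donor]
    overrides = [
        BoundOverride(ex, -1.0, -1.0),
        BoundOverride("biomass", 0.0, 0.0),
        BoundOverride("ATPM_c0", 0.0, 1000.0),
    ]
    # other donors closed for a clean per-donor yield
    for other, other_ex in DONOR_EXCHANGE.items():
        if other != electron_donor:
            overrides.append(BoundOverride(other_ex, 0.0, 0.0))
    base = model.get_reaction(ex)
    if base.upper_bound == 0.0 and base.lower_bound == 0.0:
        raise FBAError("no donor flux permitted by the model bounds")
    sol = solve_fba(model, overrides, objective="ATPM_c0", sense="max",
                    parsimonious=False)
    if not sol.optimal:
        raise FBAError(f"ATP yield LP not optimal: {sol.status}")
    return sol.objective_value


# ---------------------------------------------------------------------------
# electron partition bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class PartitionReport:
    """Electron bookkeeping of an optimal solution.

    ``electron_fractions``: share of nitrite-derived electron pairs
    routed to reverse flow (quinol / NADH / ferredoxin) versus direct
    respiration; ``reverse_fluxes``: absolute reverse-flow fluxes (mmol
    gDW-1 h-1); ``nitrite_per_carbon``: nitrite oxidation flux over net
    inorganic-carbon fixation; ``atp_partition``: maintenance split.
    """

    electron_fractions: Dict[str, float]
    reverse_fluxes: Dict[str, float]
    nitrite_per_carbon: float
    atp_partition: Dict[str, float]


def net_carbon_fixation(model: MetabolicModel, solution: FluxSolution) -> float:
    """Net CO2 uptake (mmol gDW-1 h-1), counting formate-derived CO2
    recycling: total inorganic carbon drawn into organic matter."""
    v_co2 = -solution.fluxes.get("EX_co2_e", 0.0)
    v_fdh = solution.fluxes.get("FDH_c0", 0.0)
    return v_co2 + v_fdh


def partition_report(model: MetabolicModel, solution: FluxSolution) -> PartitionReport:
    if not solution.optimal:
        raise FBAError("partition report requires an optimal solution")
    v = solution.fluxes
    v_nxr = v.get("NXR_p0", 0.0)

    # reverse flow = PMF-consuming direction of each complex
    rev_quinol = max(-v.get("CYTBC1_c0", 0.0), 0.0)       # cyt c -> quinol
    rev_nadh = max(-v.get("NUO_c0", 0.0), 0.0)            # quinol -> NADH
    rev_fdx = max(v.get("NUO2M_c0", 0.0), 0.0)            # quinol -> ferredoxin

    biomass_rxn = model.get_reaction("biomass")
    mu = v.get("biomass", 0.0)
    gam_rate = -biomass_rxn.stoichiometry.get("atp_c", 0.0) * mu
    ngam_rate = v.get("ATPM_c0", 0.0)

    fixation = net_carbon_fixation(model, solution)
    n_per_c = v_nxr / fixation if fixation > 1e-12 else float("inf")

    if v_nxr > 1e-12:
        frac = {
            "quinol": rev_quinol / v_nxr,
            "NADH": rev_nadh / v_nxr,
            "ferredoxin": rev_fdx / v_nxr,
        }
        # the respired remainder makes ATP; attribute it to its sinks
        resp = max(1.0 - sum(frac.values()), 0.0)
        atp_sinks = gam_rate + ngam_rate
        biosynth_atp = max(v_nxr * resp - atp_sinks, 0.0)
        atp_total = atp_sinks + biosynth_atp
        if atp_total > 0:
            frac["maintenance_ATP"] = resp * ngam_rate / atp_total
            frac["growth_ATP"] = resp * gam_rate / atp_total
        else:
            frac["maintenance_ATP"] = frac["growth_ATP"] = 0.0
        frac["direct_respiration"] = max(1.0 - sum(frac.values()), 0.0)
    else:
        frac = {
            "quinol": 0.0,
            "NADH": 0.0,
            "ferredoxin": 0.0,
            "maintenance_ATP": 0.0,
            "growth_ATP": 0.0,
            "direct_respiration": 0.0,
        }

    return PartitionReport(
        electron_fractions=frac,
        reverse_fluxes={"quinol": rev_quinol, "NADH": rev_nadh, "ferredoxin": rev_fdx},
        nitrite_per_carbon=n_per_c,
        atp_partition={"GAM": gam_rate, "NGAM": ngam_rate,
                       "biosynthesis": max(v_nxr - gam_rate - ngam_rate, 0.0)},
    )


def solution_table(model: MetabolicModel, solution: FluxSolution):
    """Flux table (reaction id, name, subsystem, flux) as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "reaction": r.id,
            "name": r.name,
            "subsystem": r.subsystem,
            "flux": solution.fluxes.get(r.id, float("nan")),
        }
        for r in model.reactions
    ]
    return pd.DataFrame(rows)
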