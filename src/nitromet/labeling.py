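"""Synthetic 13C-labeling dynamics and chemostat data generators.

The labeling simulator integrates pool-level enrichment kinetics

    d e_p / dt  =  sum_in  v_in (e_source - e_p) / P_p

for metabolite pools after a step change in tracer enrichment —
enrichment (not positional-isotopomer) resolution, with reported MIDs
derived under the binomial approximation.  A dual-pool
channeling/dilution structure (an inactive sub-pool that only slowly
exchanges with the pathway-active sub-pool) reproduces the signature of
substrate channeling: metabolites downstream of a channeled precursor
label *faster* than the measured (mixed) precursor pool.

Flow convention: ``flux`` is mmol gDW-1 h-1 of destination-pool
equivalents (source-pool equivalents for flows to "out"); a destination
whose carbons come from several sources carries one flow per source
with flux split by carbon contribution.  Pool sizes are umol gDW-1 and
times minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .calibration import RatePair
from .isotope import MID, EnrichmentSeries, binomial_mid

TRACER = "tracer"
OUT = "out"

ODE_ATOL = 1e-9
ODE_RTOL = 1e-6


class LabelingError(ValueError):
    pass


@dataclass(frozen=True)
class Pool:
    id: str
    size: float         # umol gDW-1
    n_carbons: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise LabelingError(f"pool {self.id!r}: size must be positive")
        if self.n_carbons < 1:
            raise LabelingError(f"pool {self.id!r}: n_carbons must be >= 1")


@dataclass(frozen=True)
class Flow:
    source: str         # pool id or "tracer"
    dest: str           # pool id or "out"
    flux: float         # mmol gDW-1 h-1 (see module docstring)

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise LabelingError("flow flux must be non-negative")


@dataclass
class LabelingNetwork:
    pools: List[Pool]
    flows: List[Flow]
    tracer_enrichment: float          # step value at t = 0
    initial_enrichment: float = 0.0   # all pools before the step

    def pool(self, pid: str) -> Pool:
        for p in self.pools:
            if p.id == pid:
                return p
        raise LabelingError(f"unknown pool {pid!r}")

    def carbon_balance(self) -> Dict[str, float]:
        """Per-pool carbon inflow minus outflow (mmol C gDW-1 h-1)."""
        resid = {p.id: 0.0 for p in self.pools}
        n = {p.id: p.n_carbons for p in self.pools}
        for f in self.flows:
            if f.dest == OUT:
                resid[f.source] -= f.flux * n[f.source]
                continue
            resid[f.dest] += f.flux * n[f.dest]
            if f.source != TRACER:
                resid[f.source] -= f.flux * n[f.dest]
        return resid

    def require_balanced(self, tol: float = 1e-6) -> None:
        resid = self.carbon_balance()
        bad = {k: v for k, v in resid.items() if abs(v) > tol}
        if bad:
            raise LabelingError(f"network not flux-balanced: {bad}")


@dataclass(frozen=True)
class ChannelingConfig:
    """Inactive-pool dilution structure.

    ``inactive_fraction``: per-metabolite fraction f in [0, 1) of the
    measured pool that does not participate in pathway flux.
    ``exchange_rate``: first-order exchange (h-1) between active and
    inactive sub-pools.  With ``bypass_measured_pool`` the pathway runs
    entirely through the active sub-pool (substrate channeling), so the
    measured, mixed pool lags the flux-carrying one.
    """

    inactive_fraction: Mapping[str, float] = field(default_factory=dict)
    exchange_rate: float = 0.05
    bypass_measured_pool: bool = True

    def __post_init__(self) -> None:
        for k, f in self.inactive_fraction.items():
            if not 0 <= f < 1:
                raise LabelingError(f"inactive fraction for {k!r} must be in [0,1)")
        if self.exchange_rate < 0:
            raise LabelingError("exchange rate must be non-negative")


@dataclass
class LabelingResult:
    series: Dict[str, EnrichmentSeries]
    mids: Dict[str, List[MID]]


def simulate_labeling(
    net: LabelingNetwork,
    channeling: Optional[ChannelingConfig] = None,
    times: Sequence[float] = (0, 1.5, 3, 5, 8, 11, 15, 20, 30, 45, 60, 90, 120),
    seed: Optional[int] = None,
    noise_sd: float = 0.0,
) -> LabelingResult:
    """Integrate pool enrichments after the tracer step and report the
    measured series and binomially derived MIDs per pool."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times[0] != 0 or np.any(np.diff(times) <= 0):
        raise LabelingError("times must be sorted, unique and start at 0")
    if noise_sd < 0:
        raise LabelingError("noise_sd must be non-negative")
    net.require_balanced()
    channeling = channeling or ChannelingConfig()

    pools = net.pools
    idx = {p.id: i for i, p in enumerate(pools)}
    npools = len(pools)
    f_inact = np.array(
        [channeling.inactive_fraction.get(p.id, 0.0) for p in pools]
    )
    has_inactive = f_inact > 0
    k_ex = channeling.exchange_rate / 60.0  # per minute

    # active sub-pool sizes carry the pathway flux
    act_size = np.array([p.size * (1 - f) for p, f in zip(pools, f_inact)])

    inflows: List[List[Tuple[int, float]]] = [[] for _ in range(npools)]
    tracer_in: List[List[float]] = [[] for _ in range(npools)]
    for fl in net.flows:
        if fl.dest == OUT:
            continue
        j = idx[fl.dest]
        rate = fl.flux * 1000.0 / 60.0  # umol per gDW per minute
        if fl.source == TRACER:
            tracer_in[j].append(rate)
        else:
            inflows[j].append((idx[fl.source], rate))

    a = net.tracer_enrichment

    def rhs(t, y):
        e_act = y[:npools]
        e_inact = y[npools:]
        d_act = np.zeros(npools)
        for j in range(npools):
            for i, rate in inflows[j]:
                d_act[j] += rate * (e_act[i] - e_act[j]) / act_size[j]
            for rate in tracer_in[j]:
                d_act[j] += rate * (a - e_act[j]) / act_size[j]
        d_inact = np.where(has_inactive, k_ex * (e_act - e_inact), 0.0)
        d_act = d_act - np.where(
            has_inactive,
            k_ex * f_inact * np.array([p.size for p in pools]) *
            (e_act - e_inact) / act_size,
            0.0,
        )
        return np.concatenate([d_act, d_inact])

    y0 = np.full(2 * npools, net.initial_enrichment)
    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])) if times[-1] > 0 else (0.0, 1.0),
        y0,
        t_eval=times if times[-1] > 0 else None,
        method="LSODA",
        atol=ODE_ATOL,
        rtol=ODE_RTOL,
    )
    if not sol.success:
        raise LabelingError(f"ODE integration failed: {sol.message}")
    Y = sol.y if times[-1] > 0 else np.repeat(y0[:, None], len(times), axis=1)

    rng = np.random.default_rng(seed)
    series: Dict[str, EnrichmentSeries] = {}
    mids: Dict[str, List[MID]] = {}
    for p in pools:
        j = idx[p.id]
        e_act = Y[j]
        e_inact = Y[npools + j]
        measured = (1 - f_inact[j]) * e_act + f_inact[j] * e_inact
        measured = np.clip(measured, 0.0, 1.0)
        series[p.id] = EnrichmentSeries(p.id, times, measured)
        pool_mids = []
        for e_t in measured:
            mid = binomial_mid(p.id, p.n_carbons, float(e_t))
            if noise_sd > 0:
                noisy = mid.fractions + rng.normal(0.0, noise_sd, mid.fractions.shape)
                noisy = np.clip(noisy, 0.0, None)
                mid = MID(p.id, p.n_carbons, noisy / noisy.sum())
            pool_mids.append(mid)
        mids[p.id] = pool_mids
    return LabelingResult(series=series, mids=mids)


# ---------------------------------------------------------------------------
# chemostat dataset generator
# ---------------------------------------------------------------------------

@dataclass
class ChemostatDataset:
    pairs: List[RatePair]
    planted: Dict[str, float]       # gam, ngam, yield, slope
    noise_sd: float
    seed: int

    def to_tsv(self) -> str:
        lines = ["uptake\tgrowth"]
        for p in self.pairs:
            lines.append(f"{p.uptake:.8f}\t{p.growth:.8f}")
        return "\n".join(lines) + "\n"


def generate_chemostat_dataset(
    gam: float,
    ngam: float,
    atp_yield: float,
    dilution_rates: Sequence[float],
    noise_sd: float,
    seed: int,
    slope: Optional[float] = None,
    model=None,
) -> ChemostatDataset:
    """Uptake-vs-growth pairs on the maintenance line with Gaussian noise.

    uptake_i = slope * mu_i + ngam / yield + eps_i.  The slope is either
    given directly or measured from ``model`` (minimum nitrite uptake at
    fixed growth, after setting the planted GAM/NGAM).
    """
    rates = list(dilution_rates)
    if len(set(rates)) != len(rates) or any(r <= 0 for r in rates):
        raise LabelingError("dilution rates must be distinct and positive")
    if noise_sd < 0:
        raise LabelingError("noise_sd must be non-negative")
    if slope is None:
        if model is None:
            raise LabelingError("provide either slope or a model to measure it")
        from .calibration import model_uptake_slope, set_maintenance

        slope = model_uptake_slope(set_maintenance(model, gam=gam, ngam=ngam))
    rng = np.random.default_rng(seed)
    pairs = []
    for mu in rates:
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        pairs.append(RatePair(max(slope * mu + ngam / atp_yield + eps, 0.0), mu))
    return ChemostatDataset(
        pairs=pairs,
        planted={"gam": gam, "ngam": ngam, "yield": atp_yield, "slope": slope},
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tracer-experiment network builders
# ---------------------------------------------------------------------------

DEFAULT_POOL_SIZES = {
    # umol gDW-1, drawn once (fixed seed 20210817) from the 0.1-5 range
    "co2": 5.0,
    "akg": 0.45,
    "glu": 2.6,
    "pep": 0.31,
    "ser": 0.72,
    "gly": 1.1,
    "for": 0.58,
    "pyr": 0.24,
}


def rtca_labeling_network(
    fixation_flux: float = 0.27,
    tracer_enrichment: float = 0.65,
) -> LabelingNetwork:
    """Bicarbonate-step network: DIC pool feeding an rTCA-style chain
    CO2 -> (pep, akg) -> downstream amino acids, fluxes at the scale of
    the chemolithoautotrophic FBA solution."""
    v = fixation_flux
    pools = [
        Pool("co2", DEFAULT_POOL_SIZES["co2"], 1),
        Pool("pep", DEFAULT_POOL_SIZES["pep"], 3),
        Pool("akg", DEFAULT_POOL_SIZES["akg"], 5),
        Pool("glu", DEFAULT_POOL_SIZES["glu"], 5),
    ]
    v_pep = 0.4 * v
    v_akg = 0.6 * v
    flows = [
        Flow(TRACER, "co2", 20.0),          # DIC exchange with sparged gas
        Flow("co2", OUT, 20.0 - v),
        Flow("co2", "pep", v_pep / 3),      # 3-carbon equivalents
        Flow("pep", OUT, v_pep / 3),
        Flow("co2", "akg", v_akg / 5),
        Flow("akg", "glu", v_akg / 5),
        Flow("glu", OUT, v_akg / 5),
    ]
    return LabelingNetwork(pools, flows, tracer_enrichment)


@dataclass
class FormateBatchResult:
    headspace_13c: EnrichmentSeries          # 13CO2 fraction series
    formate_enrichment: EnrichmentSeries     # intracellular formate
    series: Dict[str, EnrichmentSeries]
    mids: Dict[str, List[MID]]


def generate_formate_batch(
    formate_oxidation_flux: float,
    assimilation_flux: float,
    rgp_active: bool,
    times: Sequence[float] = (0, 15, 30, 60, 180, 300),
    seed: Optional[int] = None,
    headspace_volume_ml: float = 70.0,
    unlabeled_mM: float = 0.5,
    labeled_mM: float = 1.0,
    extracellular_dilution: float = 1.0,
    dic_pool_size: float = 2000.0,
    noise_sd: float = 0.0,
) -> FormateBatchResult:
    """Serum-bottle [13C]formate experiment.

    Residual unlabeled formate mixes with the labeled addition, so the
    formate pool enrichment approaches labeled/(labeled+unlabeled),
    optionally damped by ``extracellular_dilution`` (additional
    unlabeled carbon sources of unresolved mechanism).  The
    dissolved-inorganic-carbon pool (``dic_pool_size``, umol gDW-1
    equivalent) is large — it buffers medium bicarbonate and headspace
    CO2 — so downstream labeling through CO2 is slow.  With
    ``rgp_active`` the serine/glycine pool receives formate carbon
    directly through the THF route; otherwise all labeling is routed
    through the CO2 pool (indirect assimilation) and serine/glycine
    label onset lags CO2.
    """
    if headspace_volume_ml <= 0:
        raise LabelingError("headspace volume must be positive")
    if formate_oxidation_flux < 0 or assimilation_flux < 0:
        raise LabelingError("fluxes must be non-negative")
    if not 0 < extracellular_dilution <= 1:
        raise LabelingError("extracellular_dilution must be in (0, 1]")
    tracer_e = extracellular_dilution * labeled_mM / (labeled_mM + unlabeled_mM)

    v_ox = formate_oxidation_flux
    v_fix = assimilation_flux
    pools = [
        Pool("for", DEFAULT_POOL_SIZES["for"], 1),
        Pool("co2", dic_pool_size, 1),
        Pool("pyr", DEFAULT_POOL_SIZES["pyr"], 3),
        Pool("ser", DEFAULT_POOL_SIZES["ser"], 3),
        Pool("gly", DEFAULT_POOL_SIZES["gly"], 2),
    ]
    v_up = v_ox + (2.0 / 3.0 * v_fix if rgp_active else 0.0)
    v_ser = v_fix / 3.0   # serine equivalents formed
    flows = [Flow(TRACER, "for", v_up), Flow("for", "co2", v_ox)]
    if rgp_active:
        # 2 of 3 serine carbons from formate via the THF route, 1 from CO2
        flows += [
            Flow("for", "ser", 2.0 / 3.0 * v_ser),
            Flow("co2", "ser", 1.0 / 3.0 * v_ser),
        ]
        v_co2_fix = v_ser  # CO2 into the serine carboxyl
    else:
        flows += [Flow("co2", "pyr", v_ser), Flow("pyr", "ser", v_ser)]
        v_co2_fix = 3.0 * v_ser
    flows += [
        Flow("ser", "gly", v_ser),        # glycine keeps 2 of serine's 3 C
        Flow("gly", OUT, v_ser),
        Flow("ser", OUT, v_ser / 3.0),    # remaining serine carbon drained
    ]
    # CO2 pool balance: in = v_ox (+ pyr respiration none), out = fixation + vented
    v_vent = v_ox - v_co2_fix
    if v_vent < 0:
        raise LabelingError("assimilation flux exceeds CO2 production")
    if v_vent > 0:
        flows.append(Flow("co2", OUT, v_vent))
    if not rgp_active:
        pass
    net = LabelingNetwork(pools, flows, tracer_e)
    result = simulate_labeling(net, None, times, seed=seed, noise_sd=noise_sd)

    # headspace: cumulative vented CO2 at the CO2-pool enrichment
    times_arr = np.asarray(times, dtype=float)
    e_co2 = result.series["co2"].enrichment
    background = 0.2  # umol unlabeled CO2-equivalents initially in headspace
    labeled = np.concatenate(
        [[0.0], np.cumsum(0.5 * (e_co2[1:] + e_co2[:-1]) * np.diff(times_arr))]
    ) * (v_vent * 1000.0 / 60.0)
    total = background + v_vent * 1000.0 / 60.0 * times_arr
    frac = np.where(total > 0, labeled / np.maximum(total, 1e-12), 0.0)
    headspace = EnrichmentSeries("headspace_13co2", times_arr, frac)
    return FormateBatchResult(
        headspace_13c=headspace,
        formate_enrichment=result.series["for"],
        series=result.series,
        mids=result.mids,
    )
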