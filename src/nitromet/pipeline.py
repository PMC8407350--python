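"""End-to-end pipeline: build, calibrate, run scenarios, generate
labeling fixtures, and write a hashed output manifest."""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Dict

import numpy as np

from .build import BuildOptions, build_core_model
from .calibration import calibrate
from .fba import atp_yield, partition_report, solve_fba, BoundOverride
from .io import (
    RunConfig,
    read_rate_pairs,
    sha256_file,
    write_flux_tsv,
    write_json_model,
    write_mids_tsv,
    write_sbml_model,
)
from .labeling import (
    ChannelingConfig,
    generate_chemostat_dataset,
    generate_formate_batch,
    rtca_labeling_network,
    simulate_labeling,
)
from .scenarios import (
    compare_formate_assimilation,
    complex_i_limited_formate,
    run_scenario,
    standard_scenarios,
)

log = logging.getLogger("nitromet")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Dict[str, str]:
    """Execute build -> calibrate -> scenarios -> isotope/simulation and
    return a manifest mapping output paths to content hashes."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, str] = {}
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    log.info(
        "pipeline start: seed=%d tolerances: LP feasibility 1e-9, ODE 1e-9/1e-6",
        config.seed,
    )

    def emit(path: Path) -> None:
        manifest[str(path.relative_to(out))] = sha256_file(path)

    stage = "build"
    try:
        model = build_core_model(
            etc=config.etc,
            maint=config.maintenance,
            options=BuildOptions(
                rgp_enabled=config.rgp_enabled,
                hydrogenase_enabled=config.hydrogenase_enabled,
            ),
        )
        yld = atp_yield(model, "nitrite")
        log.info("built model: %d species, %d reactions, nitrite ATP yield %.3f",
                 len(model.species), len(model.reactions), yld)

        stage = "calibrate"
        if config.rate_pairs_tsv:
            pairs = read_rate_pairs(config.rate_pairs_tsv)
        else:
            ds = generate_chemostat_dataset(
                gam=config.maintenance.gam,
                ngam=config.maintenance.ngam,
                atp_yield=yld,
                dilution_rates=np.linspace(0.002, 0.012, 20),
                noise_sd=0.0,
                seed=config.seed,
                slope=(config.operating_point[0] - config.maintenance.ngam / yld)
                / config.operating_point[1],
            )
            pairs = ds.pairs
            (out / "chemostat_pairs.tsv").write_text(ds.to_tsv())
            emit(out / "chemostat_pairs.tsv")
        model, cal = calibrate(model, pairs, yld, config.operating_point)
        (out / "calibration.json").write_text(
            json.dumps(
                {
                    "ngam": cal.ngam,
                    "gam": cal.gam,
                    "intercept_uptake": cal.intercept_uptake,
                    "slope": cal.slope,
                    "r_squared": cal.r_squared,
                    "residual_sd": cal.residual_sd,
                    "atp_yield_nitrite": yld,
                },
                indent=1,
            )
        )
        emit(out / "calibration.json")

        write_json_model(model, out / "model.json")
        emit(out / "model.json")
        write_sbml_model(model, out / "model.xml")
        emit(out / "model.xml")

        stage = "scenarios"
        scen = standard_scenarios()
        results = {}
        ref = run_scenario(model, scen["B"])
        for label in "ABCD":
            results[label] = run_scenario(
                model, scen[label], reference=ref if label in "CD" else None
            )
        solA = results["A"].solution
        write_flux_tsv(model, solA, out / "fluxes_scenario_A.tsv")
        emit(out / "fluxes_scenario_A.tsv")
        rep = partition_report(model, solA)
        rgp = compare_formate_assimilation(model, 6.0)
        secretion = complex_i_limited_formate(
            model, 6.0, config.measured_formate_growth
        )
        (out / "scenarios.json").write_text(
            json.dumps(
                {
                    "growth": {k: r.growth for k, r in results.items()},
                    "fold_vs_B": {
                        k: r.fold_vs_reference for k, r in results.items()
                    },
                    "reverse_fluxes": rep.reverse_fluxes,
                    "nitrite_per_carbon": rep.nitrite_per_carbon,
                    "rgp_comparison": rgp,
                    "secretion_candidates": {
                        s.candidate: s.secreted for s in secretion
                    },
                },
                indent=1,
                default=float,
            )
        )
        emit(out / "scenarios.json")

        stage = "isotope"
        net = rtca_labeling_network(
            fixation_flux=float(
                max(solA.fluxes.get("NUO2M_c0", 0.27), 0.05)
            ),
            tracer_enrichment=config.tracer_fraction,
        )
        res = simulate_labeling(
            net,
            ChannelingConfig(inactive_fraction={"akg": 0.5}, exchange_rate=0.05),
            seed=config.seed,
            noise_sd=0.005,
        )
        mids = [m for series in res.mids.values() for m in series]
        write_mids_tsv(mids, out / "bicarbonate_tracer_mids.tsv")
        emit(out / "bicarbonate_tracer_mids.tsv")

        batch = generate_formate_batch(
            formate_oxidation_flux=6.0,
            assimilation_flux=0.35,
            rgp_active=config.rgp_enabled,
            seed=config.seed,
        )
        (out / "formate_batch.json").write_text(
            json.dumps(
                {
                    "times_min": batch.headspace_13c.times_min.tolist(),
                    "headspace_13co2_fraction": batch.headspace_13c.enrichment.tolist(),
                    "intracellular_formate_enrichment": batch.formate_enrichment.enrichment.tolist(),
                },
                indent=1,
            )
        )
        emit(out / "formate_batch.json")
    except Exception as e:  # noqa: BLE001 - abort with stage name
        if isinstance(e, PipelineError):
            raise
        raise PipelineError(stage, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline done: %d outputs", len(manifest))
    return manifest
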