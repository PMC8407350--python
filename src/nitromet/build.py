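"""Curated core model of N. moscoviensis carbon and energy metabolism.

The network covers the respiratory chain of a nitrite oxidizer
(periplasmic NXR feeding cytochrome c, bd-type terminal oxidase,
PMF-driven reverse electron flow through complex III, complex I and the
ferredoxin-reducing 2M-type complex I, ATP synthase), the reductive TCA
cycle with anaplerosis, lumped gluconeogenesis/pentose-phosphate and
monomer biosynthesis sufficient for the measured biomass equation,
formate metabolism (FocA transport, soluble NAD+-linked FDH) and the
reductive glycine pathway, nitrogen assimilation, and the exchange set
of the mineral NOB medium.

Periplasmic protons (``h_p``) are the proton-motive-force bookkeeping
pool: only translocation reactions touch them, each moving the integer
charge-equivalents fixed by :class:`~nitromet.core.ETCStoichiometry`.

Every internal reaction is element- and charge-balanced at construction
time; an unbalanced curation error aborts the build naming the reaction
and element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

from .biomass import biomass_reaction_from_composition, load_composition
from .chem import balanced, make_species
from .core import (
    BiomassComposition,
    ETCStoichiometry,
    MaintenanceParams,
    MetabolicModel,
    ModelConstructionError,
    Reaction,
    Species,
    check_balance,
)

#: ModelSEED id of the formate-tetrahydrofolate ligase step, the entry
#: point of the reductive glycine pathway (knocked out to disable RGP).
RXN_FORMATE_THF_LIGASE = "rxn00690_c0"

#: candidate secreted organics for the complex-I-limitation analysis
SECRETION_CANDIDATES = ("ac", "pyr", "succ", "mal", "ala", "glu")


@dataclass(frozen=True)
class BuildOptions:
    rgp_enabled: bool = True
    hydrogenase_enabled: bool = True
    #: quinol-dependent octaheme nitrite reductase as an alternative
    #: assimilatory route (off by default; ferredoxin NirA is the default)
    octaheme_assimilation: bool = False


def build_core_model(
    etc: Optional[ETCStoichiometry] = None,
    biomass: Optional[BiomassComposition] = None,
    maint: Optional[MaintenanceParams] = None,
    options: BuildOptions = BuildOptions(),
) -> MetabolicModel:
    """Assemble the validated core model.

    With no arguments, builds the default model: shipped biomass
    composition, documented ETC stoichiometry with H+/ATP calibrated to
    a net nitrite ATP yield of 1.0, and nominal maintenance (GAM 535,
    NGAM 0.90) pending calibration.
    """
    etc = etc or ETCStoichiometry()
    biomass = biomass or load_composition()
    maint = maint if maint is not None else MaintenanceParams(gam=535.0, ngam=0.90)

    sp = make_species()
    rxns: List[Reaction] = []

    def add(rid, name, skeleton, lower=-1000.0, upper=1000.0, subsystem="", gene_note=""):
        rxns.append(
            balanced(rid, name, skeleton, sp, lower, upper, subsystem, gene_note)
        )

    # ------------------------------------------------------------------
    # electron transport chain (charge equivalents per 2 e-)
    # ------------------------------------------------------------------
    n_nxr = etc.nxr_periplasmic_h
    n_iii = etc.complex_iii
    n_i = etc.complex_i
    n_2m = etc.complex_i_2m
    n_ox = etc.terminal_oxidase
    n_atp = etc.h_per_atp

    # NXR: NO2- + H2O -> NO3- + 2 H+ (periplasm) + 2 e- to cytochrome c
    add(
        "NXR_p0",
        "nitrite oxidoreductase (periplasmic)",
        {
            "no2_p": -1, "h2o_c": -1, "ficytc_p": -2,
            "no3_p": 1, "h_p": n_nxr, "focytc_p": 2,
            "h_c": n_nxr - 2,  # chemistry releases 2 H+; n_nxr go periplasmic
        },
        lower=0.0,
        subsystem="ETC",
        gene_note="NXR, membrane-bound periplasmic",
    )
    # bd-type terminal oxidase: charge separation, no pumping beyond it
    add(
        "CYTBD_c0",
        "cytochrome bd terminal oxidase",
        {
            "focytc_p": -4, "o2_c": -1, "h_c": -(4 + 2 * n_ox),
            "ficytc_p": 4, "h2o_c": 2, "h_p": 2 * n_ox,
        },
        lower=0.0,
        subsystem="ETC",
    )
    # complex III (Q-cycle), reversible: quinol -> cyt c pumps n_iii
    add(
        "CYTBC1_c0",
        "cytochrome bc1 complex (complex III)",
        {
            "q8h2_c": -1, "ficytc_p": -2, "h_c": -(n_iii - 2),
            "q8_c": 1, "focytc_p": 2, "h_p": n_iii,
        },
        subsystem="ETC",
    )
    # complex I, reversible: NADH + Q -> NAD + QH2 pumps n_i
    add(
        "NUO_c0",
        "NADH dehydrogenase (complex I)",
        {
            "nadh_c": -1, "q8_c": -1, "h_c": -(n_i + 1),
            "nad_c": 1, "q8h2_c": 1, "h_p": n_i,
        },
        subsystem="ETC",
    )
    # 2M-type complex I, written in the reductive (ferredoxin) direction
    add(
        "NUO2M_c0",
        "2M-type complex I (ferredoxin-reducing)",
        {
            "q8h2_c": -1, "fdxo_c": -1, "h_p": -n_2m,
            "q8_c": 1, "fdxr_c": 1, "h_c": n_2m + 2,
        },
        subsystem="ETC",
        gene_note="hypothesized ferredoxin reduction via reverse electron flow",
    )
    add(
        "ATPS_c0",
        "ATP synthase",
        {
            "adp_c": -1, "pi_c": -1, "h_p": -n_atp,
            "atp_c": 1, "h2o_c": 1, "h_c": n_atp - 1,
        },
        subsystem="ETC",
    )
    add(
        "ATPM_c0",
        "ATP maintenance (NGAM)",
        {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
        lower=maint.ngam,
        subsystem="maintenance",
    )
    add(
        "THD_c0",
        "NAD(P) transhydrogenase",
        {"nadh_c": -1, "nadp_c": -1, "nad_c": 1, "nadph_c": 1},
        subsystem="redox",
    )

    # ------------------------------------------------------------------
    # formate metabolism and the reductive glycine pathway
    # ------------------------------------------------------------------
    add("FOCA_c0", "formate channel FocA", {"for_e": -1, "for_c": 1}, subsystem="transport")
    add(
        "FDH_c0",
        "soluble NAD+-linked formate dehydrogenase",
        {"for_c": -1, "nad_c": -1, "co2_c": 1, "nadh_c": 1},
        lower=0.0,
        subsystem="formate",
    )
    if options.hydrogenase_enabled:
        add(
            "HYD_c0",
            "NiFe hydrogenase (stub)",
            {"h2_c": -1, "nad_c": -1, "nadh_c": 1},
            lower=0.0,
            subsystem="formate",
        )
        add("H2t_c0", "H2 diffusion", {"h2_e": -1, "h2_c": 1}, subsystem="transport")

    if options.rgp_enabled:
        add(
            RXN_FORMATE_THF_LIGASE,
            "formate-tetrahydrofolate ligase",
            {
                "for_c": -1, "thf_c": -1, "atp_c": -1,
                "10fthf_c": 1, "adp_c": 1, "pi_c": 1,
            },
            lower=0.0,
            subsystem="RGP",
        )
    add(
        "MTHFC_c0",
        "methenyl-THF cyclohydrolase",
        {"10fthf_c": -1, "h_c": -1, "methf_c": 1, "h2o_c": 1},
        subsystem="RGP",
    )
    add(
        "MTHFD_c0",
        "methylene-THF dehydrogenase (NADP)",
        {"methf_c": -1, "nadph_c": -1, "mlthf_c": 1, "nadp_c": 1},
        subsystem="RGP",
    )
    add(
        "GCS_c0",
        "glycine cleavage system (reversible)",
        {
            "co2_c": -1, "nh4_c": -1, "mlthf_c": -1, "nadh_c": -1,
            "gly_c": 1, "thf_c": 1, "nad_c": 1,
        },
        subsystem="RGP",
    )
    add(
        "SHMT_c0",
        "serine hydroxymethyltransferase",
        {"ser_c": -1, "thf_c": -1, "gly_c": 1, "mlthf_c": 1, "h2o_c": 1},
        subsystem="RGP",
    )
    add(
        "SERD_c0",
        "serine dehydratase",
        {"ser_c": -1, "pyr_c": 1, "nh4_c": 1},
        lower=0.0,
        subsystem="RGP",
    )

    # ------------------------------------------------------------------
    # reductive TCA cycle and anaplerosis
    # ------------------------------------------------------------------
    add(
        "ACL_c0",
        "ATP-citrate lyase",
        {
            "cit_c": -1, "atp_c": -1, "coa_c": -1,
            "oaa_c": 1, "accoa_c": 1, "adp_c": 1, "pi_c": 1,
        },
        lower=0.0,
        subsystem="rTCA",
    )
    add("ACONT_c0", "aconitase", {"icit_c": -1, "cit_c": 1}, subsystem="rTCA")
    add(
        "ICDH_c0",
        "isocitrate dehydrogenase (carboxylating)",
        {"akg_c": -1, "co2_c": -1, "nadph_c": -1, "icit_c": 1, "nadp_c": 1},
        subsystem="rTCA",
    )
    add(
        "OFOR_c0",
        "2-oxoglutarate:ferredoxin oxidoreductase",
        {
            "succoa_c": -1, "co2_c": -1, "fdxr_c": -1,
            "akg_c": 1, "coa_c": 1, "fdxo_c": 1,
        },
        subsystem="rTCA",
    )
    add(
        "SCS_c0",
        "succinyl-CoA synthetase",
        {
            "succ_c": -1, "coa_c": -1, "atp_c": -1,
            "succoa_c": 1, "adp_c": 1, "pi_c": 1,
        },
        subsystem="rTCA",
    )
    add(
        "FRD_c0",
        "fumarate reductase / succinate dehydrogenase (quinol)",
        {"fum_c": -1, "q8h2_c": -1, "succ_c": 1, "q8_c": 1},
        subsystem="rTCA",
    )
    add("FUM_c0", "fumarase", {"mal_c": -1, "fum_c": 1, "h2o_c": 1}, subsystem="rTCA")
    add(
        "MDH_c0",
        "malate dehydrogenase",
        {"oaa_c": -1, "nadh_c": -1, "h_c": -1, "mal_c": 1, "nad_c": 1},
        subsystem="rTCA",
    )
    add(
        "PFOR_c0",
        "pyruvate:ferredoxin oxidoreductase",
        {
            "accoa_c": -1, "co2_c": -1, "fdxr_c": -1,
            "pyr_c": 1, "coa_c": 1, "fdxo_c": 1,
        },
        subsystem="rTCA",
    )
    add(
        "PC_c0",
        "pyruvate carboxylase",
        {
            "pyr_c": -1, "hco3_c": -1, "atp_c": -1,
            "oaa_c": 1, "adp_c": 1, "pi_c": 1,
        },
        lower=0.0,
        subsystem="anaplerosis",
    )
    add(
        "PPC_c0",
        "PEP carboxylase",
        {"pep_c": -1, "hco3_c": -1, "oaa_c": 1, "pi_c": 1},
        lower=0.0,
        subsystem="anaplerosis",
    )
    add(
        "PPS_c0",
        "PEP synthetase",
        {
            "pyr_c": -1, "atp_c": -1, "h2o_c": -1,
            "pep_c": 1, "amp_c": 1, "pi_c": 1,
        },
        lower=0.0,
        subsystem="gluconeogenesis",
    )
    add("ADK_c0", "adenylate kinase", {"amp_c": -1, "atp_c": -1, "adp_c": 2}, subsystem="energy")
    add(
        "ACS_c0",
        "acetyl-CoA synthetase",
        {
            "ac_c": -1, "atp_c": -1, "coa_c": -1,
            "accoa_c": 1, "amp_c": 1, "pi_c": 2,
        },
        lower=0.0,
        subsystem="anaplerosis",
    )
    add(
        "CA_c0",
        "carbonic anhydrase",
        {"co2_c": -1, "h2o_c": -1, "hco3_c": 1, "h_c": 1},
        subsystem="anaplerosis",
    )

    # ------------------------------------------------------------------
    # gluconeogenesis and pentose phosphate (lumped)
    # ------------------------------------------------------------------
    add("ENO_c0", "enolase + phosphoglycerate mutase", {"pg3_c": -1, "pep_c": 1, "h2o_c": 1})
    add(
        "GAPDH_c0",
        "phosphoglycerate kinase + GAPDH",
        {
            "pg3_c": -1, "atp_c": -1, "nadh_c": -1, "h_c": -1,
            "gap_c": 1, "adp_c": 1, "pi_c": 1, "nad_c": 1,
        },
        subsystem="gluconeogenesis",
    )
    add(
        "FBP_c0",
        "aldolase + fructose-1,6-bisphosphatase",
        {"gap_c": -2, "h2o_c": -1, "f6p_c": 1, "pi_c": 1},
        lower=0.0,
        subsystem="gluconeogenesis",
    )
    add("PGI_c0", "phosphoglucose isomerase", {"f6p_c": -1, "g6p_c": 1})
    add(
        "PPPNOX1_c0",
        "non-oxidative pentose phosphate (net R5P)",
        {"f6p_c": -2, "gap_c": -1, "r5p_c": 3},
        subsystem="pentose phosphate",
    )
    add(
        "PPPNOX2_c0",
        "transketolase (net E4P)",
        {"f6p_c": -1, "gap_c": -1, "e4p_c": 1, "r5p_c": 1},
        subsystem="pentose phosphate",
    )

    # ------------------------------------------------------------------
    # nitrogen and sulfur assimilation
    # ------------------------------------------------------------------
    add(
        "NIRA_c0",
        "ferredoxin-nitrite reductase (assimilatory)",
        {
            "no2_c": -1, "fdxr_c": -3, "h_c": -8,
            "nh4_c": 1, "h2o_c": 2, "fdxo_c": 3,
        },
        lower=0.0,
        subsystem="N assimilation",
    )
    if options.octaheme_assimilation:
        add(
            "ONR_c0",
            "octaheme nitrite reductase (quinol, assimilatory)",
            {
                "no2_c": -1, "q8h2_c": -3, "h_c": -2,
                "nh4_c": 1, "h2o_c": 2, "q8_c": 3,
            },
            lower=0.0,
            upper=0.0,  # alternative route, opened explicitly
            subsystem="N assimilation",
        )
    add(
        "GS_c0",
        "glutamine synthetase",
        {
            "glu_c": -1, "nh4_c": -1, "atp_c": -1,
            "gln_c": 1, "adp_c": 1, "pi_c": 1,
        },
        lower=0.0,
        subsystem="N assimilation",
    )
    add(
        "GOGAT_c0",
        "glutamate synthase (ferredoxin)",
        {"gln_c": -1, "akg_c": -1, "fdxr_c": -1, "glu_c": 2, "fdxo_c": 1},
        lower=0.0,
        subsystem="N assimilation",
    )
    add(
        "SULFAS_c0",
        "assimilatory sulfate reduction (lumped)",
        {
            "so4_c": -1, "atp_c": -3, "nadph_c": -4,
            "h2s_c": 1, "amp_c": 1, "adp_c": 2, "pi_c": 4, "nadp_c": 4,
        },
        lower=0.0,
        subsystem="S assimilation",
    )

    # ------------------------------------------------------------------
    # monomer biosynthesis (lumped, standard pathway costs)
    # ------------------------------------------------------------------
    def lump(rid, name, skeleton, n_atp_cost=0, n_nadph=0, n_nadh_made=0):
        s = dict(skeleton)
        if n_atp_cost:
            s.update(
                {
                    "atp_c": s.get("atp_c", 0) - n_atp_cost,
                    "adp_c": s.get("adp_c", 0) + n_atp_cost,
                    "pi_c": s.get("pi_c", 0) + n_atp_cost,
                }
            )
        if n_nadph:
            s.update(
                {
                    "nadph_c": s.get("nadph_c", 0) - n_nadph,
                    "nadp_c": s.get("nadp_c", 0) + n_nadph,
                }
            )
        if n_nadh_made:
            s.update(
                {
                    "nad_c": s.get("nad_c", 0) - n_nadh_made,
                    "nadh_c": s.get("nadh_c", 0) + n_nadh_made,
                }
            )
        add(rid, name, s, lower=0.0, subsystem="biosynthesis")

    lump("ALAS_c0", "alanine synthesis", {"pyr_c": -1, "glu_c": -1, "ala_c": 1, "akg_c": 1})
    lump(
        "ARGS_c0",
        "arginine synthesis (lumped)",
        {
            "glu_c": -1, "gln_c": -1, "asp_c": -1, "hco3_c": -1,
            "arg_c": 1, "akg_c": 1, "fum_c": 1,
        },
        n_atp_cost=4,
        n_nadph=1,
    )
    lump("ASPS_c0", "aspartate synthesis", {"oaa_c": -1, "glu_c": -1, "asp_c": 1, "akg_c": 1})
    lump(
        "HISS_c0",
        "histidine synthesis (lumped)",
        {
            "r5p_c": -1, "10fthf_c": -1, "gln_c": -2,
            "his_c": 1, "thf_c": 1, "glu_c": 1, "akg_c": 1, "pi_c": 1,
        },
        n_atp_cost=5,
        n_nadh_made=2,
    )
    lump(
        "ILES_c0",
        "isoleucine synthesis (lumped)",
        {
            "thr_c": -1, "pyr_c": -1, "glu_c": -1,
            "ile_c": 1, "akg_c": 1, "nh4_c": 1, "co2_c": 1,
        },
        n_nadph=1,
    )
    lump(
        "LEUS_c0",
        "leucine synthesis (lumped)",
        {
            "pyr_c": -2, "accoa_c": -1, "glu_c": -1,
            "leu_c": 1, "akg_c": 1, "co2_c": 2, "coa_c": 1,
        },
        n_nadph=1,
        n_nadh_made=1,
    )
    lump(
        "LYSS_c0",
        "lysine synthesis (lumped, DAP pathway)",
        {
            "oaa_c": -1, "pyr_c": -1, "glu_c": -2,
            "lys_c": 1, "akg_c": 2, "co2_c": 1,
        },
        n_atp_cost=1,
        n_nadph=2,
    )
    lump(
        "METS_c0",
        "methionine synthesis (lumped)",
        {
            "oaa_c": -1, "glu_c": -1, "accoa_c": -1, "h2s_c": -1, "mlthf_c": -1,
            "nadh_c": -1, "nad_c": 1,
            "met_c": 1, "akg_c": 1, "ac_c": 1, "thf_c": 1, "coa_c": 1,
        },
        n_atp_cost=1,
        n_nadph=2,
    )
    lump(
        "PHES_c0",
        "phenylalanine synthesis (lumped)",
        {
            "pep_c": -2, "e4p_c": -1, "glu_c": -1,
            "phe_c": 1, "akg_c": 1, "co2_c": 1, "pi_c": 3,
        },
        n_atp_cost=1,
        n_nadph=1,
    )
    lump(
        "TYRS_c0",
        "tyrosine synthesis (lumped)",
        {
            "pep_c": -2, "e4p_c": -1, "glu_c": -1,
            "tyr_c": 1, "akg_c": 1, "co2_c": 1, "pi_c": 3,
        },
        n_atp_cost=1,
        n_nadph=1,
        n_nadh_made=1,
    )
    lump("PROS_c0", "proline synthesis", {"glu_c": -1, "pro_c": 1}, n_atp_cost=1, n_nadph=2)
    lump(
        "SERS_c0",
        "serine synthesis (from 3PG)",
        {"pg3_c": -1, "glu_c": -1, "ser_c": 1, "akg_c": 1, "pi_c": 1},
        n_nadh_made=1,
    )
    lump(
        "THRS_c0",
        "threonine synthesis",
        {"oaa_c": -1, "glu_c": -1, "thr_c": 1, "akg_c": 1},
        n_atp_cost=2,
        n_nadph=2,
    )
    lump(
        "VALS_c0",
        "valine synthesis",
        {"pyr_c": -2, "glu_c": -1, "val_c": 1, "akg_c": 1, "co2_c": 1},
        n_nadph=1,
    )

    # nucleotides
    lump(
        "AMPS_c0",
        "AMP synthesis (lumped purine pathway)",
        {
            "r5p_c": -1, "gly_c": -1, "10fthf_c": -2, "hco3_c": -1,
            "gln_c": -2, "asp_c": -2,
            "amp_c": 1, "thf_c": 2, "glu_c": 2, "fum_c": 2,
        },
        n_atp_cost=6,
    )
    lump(
        "GMPS_c0",
        "GMP synthesis (lumped purine pathway)",
        {
            "r5p_c": -1, "gly_c": -1, "10fthf_c": -2, "hco3_c": -1,
            "gln_c": -3, "asp_c": -1,
            "gmp_c": 1, "thf_c": 2, "glu_c": 3, "fum_c": 1,
        },
        n_atp_cost=7,
        n_nadh_made=1,
    )
    lump(
        "UMPS_c0",
        "UMP synthesis (lumped pyrimidine pathway)",
        {
            "r5p_c": -1, "gln_c": -1, "asp_c": -1, "hco3_c": -1,
            "ump_c": 1, "glu_c": 1, "co2_c": 1,
        },
        n_atp_cost=2,
        n_nadh_made=1,
    )
    lump(
        "CMPS_c0",
        "CMP synthesis (lumped pyrimidine pathway)",
        {
            "r5p_c": -1, "gln_c": -2, "asp_c": -1, "hco3_c": -1,
            "cmp_c": 1, "glu_c": 2, "co2_c": 1,
        },
        n_atp_cost=3,
        n_nadh_made=1,
    )

    # carbohydrate and lipid
    lump("GLYCS_c0", "glucan synthesis", {"g6p_c": -1, "glucan_c": 1, "pi_c": 1}, n_atp_cost=1)
    lump(
        "FAS160_c0",
        "palmitate synthesis",
        {"accoa_c": -8, "pmt_c": 1, "coa_c": 8},
        n_atp_cost=7,
        n_nadph=14,
    )
    lump("G3PD_c0", "glycerol-3-phosphate dehydrogenase", {"gap_c": -1, "nadh_c": -1, "nad_c": 1, "glyc3p_c": 1})
    lump(
        "LIPS_c0",
        "phosphatidate surrogate assembly",
        {"pmt_c": -2, "glyc3p_c": -1, "lipid_c": 1, "h2o_c": 2},
        n_atp_cost=1,
    )
    # ash uptake is a pure drain; synthesis is transport (below)

    # ------------------------------------------------------------------
    # transport and exchange
    # ------------------------------------------------------------------
    add("NO2tp_c0", "nitrite porin (medium/periplasm)", {"no2_e": -1, "no2_p": 1}, subsystem="transport")
    add("NO2tc_c0", "nitrite transport (periplasm/cytoplasm)", {"no2_p": -1, "no2_c": 1}, subsystem="transport")
    add("NO3tp_c0", "nitrate efflux", {"no3_p": -1, "no3_e": 1}, subsystem="transport")
    add("NH4t_c0", "ammonium transport", {"nh4_e": -1, "nh4_c": 1}, subsystem="transport")
    for small in ("o2", "co2", "h2o", "pi", "so4"):
        add(f"{small.upper()}t_c0", f"{small} transport", {f"{small}_e": -1, f"{small}_c": 1}, subsystem="transport")
    add("ASHt_c0", "mineral uptake (lumped)", {"ash_e": -1, "ash_c": 1}, subsystem="transport")
    for org in SECRETION_CANDIDATES:
        add(f"{org.upper()}t_c0", f"{org} transport", {f"{org}_c": -1, f"{org}_e": 1}, subsystem="transport")

    def exchange(sid, lower, upper=1000.0):
        rxns.append(
            Reaction(
                f"EX_{sid}",
                f"{sid} exchange",
                {sid: -1.0},
                lower_bound=lower,
                upper_bound=upper,
                subsystem="exchange",
            )
        )

    exchange("no2_e", -10.0)          # electron donor, scenario-controlled
    exchange("no3_e", 0.0)
    exchange("nh4_e", 0.0)            # closed: chemostat medium is nitrite-N
    exchange("for_e", 0.0)            # opened by formate scenarios
    exchange("o2_e", -1000.0)
    exchange("co2_e", -1000.0)
    exchange("h2o_e", -1000.0)
    exchange("pi_e", -1000.0)
    exchange("so4_e", -1000.0)
    exchange("ash_e", -1000.0)
    exchange("h2_e", 0.0, 0.0)
    rxns.append(
        Reaction("EX_h_c", "proton exchange (medium reference)", {"h_c": -1.0},
                 -1000.0, 1000.0, subsystem="exchange")
    )
    for org in SECRETION_CANDIDATES:
        exchange(f"{org}_e", 0.0, 0.0)  # opened only by the secretion analysis

    # biomass objective
    rxns.append(biomass_reaction_from_composition(biomass, maint.gam))

    model = MetabolicModel(
        species=[s for s in sp.values()],
        reactions=rxns,
        objective_id="biomass",
        name="nitromet-core",
    )
    report = check_balance(model)
    if report:
        first = report[0]
        raise ModelConstructionError(
            f"core model construction produced an unbalanced reaction: "
            f"{first.reaction_id} ({first.element}, residual {first.residual})"
        )
    return model
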