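"""Species chemistry for the core N. moscoviensis network.

Formulas are the dominant protonation state at pH ~7 (BiGG-style), so
that element and charge balancing are mutually consistent.  Electron
carriers with large invariant scaffolds (ferredoxin, cytochrome c) are
abstract: empty formula, redox state carried by the charge.

`balanced(...)` closes a reaction skeleton in H and O by adding
cytoplasmic protons and water, then *verifies* every element and the
charge; a skeleton with wrong C/N/P/S bookkeeping fails loudly at model
construction time.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

from .core import ModelConstructionError, Reaction, Species

# id -> (name, compartment, formula, charge)
_C, _P, _E = "cytoplasm", "periplasm", "extracellular"


def _f(expr: str) -> Dict[str, int]:
    """Parse 'C6H12O6'-style formula strings."""
    import re

    out: Dict[str, int] = {}
    for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", expr):
        if el:
            out[el] = out.get(el, 0) + (int(n) if n else 1)
    return out


SPECIES_TABLE: Dict[str, Tuple[str, str, str, int]] = {
    # small inorganics
    "h2o_c": ("water", _C, "H2O", 0),
    "h_c": ("proton (cytoplasm)", _C, "H", 1),
    "h_p": ("proton (periplasm, PMF charge equivalent)", _P, "H", 1),
    "o2_c": ("oxygen", _C, "O2", 0),
    "co2_c": ("carbon dioxide", _C, "CO2", 0),
    "hco3_c": ("bicarbonate", _C, "CHO3", -1),
    "nh4_c": ("ammonium", _C, "H4N", 1),
    "pi_c": ("phosphate", _C, "HO4P", -2),
    "so4_c": ("sulfate", _C, "O4S", -2),
    "h2s_c": ("hydrogen sulfide", _C, "H2S", 0),
    "h2_c": ("dihydrogen", _C, "H2", 0),
    "no2_c": ("nitrite (cytoplasm)", _C, "NO2", -1),
    "no2_p": ("nitrite (periplasm)", _P, "NO2", -1),
    "no3_p": ("nitrate (periplasm)", _P, "NO3", -1),
    # energy and redox carriers
    "atp_c": ("ATP", _C, "C10H12N5O13P3", -4),
    "adp_c": ("ADP", _C, "C10H12N5O10P2", -3),
    "amp_c": ("AMP", _C, "C10H12N5O7P", -2),
    "nad_c": ("NAD+", _C, "C21H26N7O14P2", -1),
    "nadh_c": ("NADH", _C, "C21H27N7O14P2", -2),
    "nadp_c": ("NADP+", _C, "C21H25N7O17P3", -3),
    "nadph_c": ("NADPH", _C, "C21H26N7O17P3", -4),
    "fdxo_c": ("ferredoxin (oxidized)", _C, "", 0),
    "fdxr_c": ("ferredoxin (reduced, 2e-)", _C, "", -2),
    "q8_c": ("quinone", _C, "C49H74O4", 0),
    "q8h2_c": ("quinol", _C, "C49H76O4", 0),
    "ficytc_p": ("cytochrome c (oxidized)", _P, "", 1),
    "focytc_p": ("cytochrome c (reduced)", _P, "", 0),
    "coa_c": ("coenzyme A", _C, "C21H32N7O16P3S", -4),
    # central carbon
    "accoa_c": ("acetyl-CoA", _C, "C23H34N7O17P3S", -4),
    "succoa_c": ("succinyl-CoA", _C, "C25H35N7O19P3S", -5),
    "pyr_c": ("pyruvate", _C, "C3H3O3", -1),
    "pep_c": ("phosphoenolpyruvate", _C, "C3H2O6P", -3),
    "oaa_c": ("oxaloacetate", _C, "C4H2O5", -2),
    "mal_c": ("malate", _C, "C4H4O5", -2),
    "fum_c": ("fumarate", _C, "C4H2O4", -2),
    "succ_c": ("succinate", _C, "C4H4O4", -2),
    "akg_c": ("2-oxoglutarate", _C, "C5H4O5", -2),
    "cit_c": ("citrate", _C, "C6H5O7", -3),
    "icit_c": ("isocitrate", _C, "C6H5O7", -3),
    "ac_c": ("acetate", _C, "C2H3O2", -1),
    "for_c": ("formate", _C, "CHO2", -1),
    "pg3_c": ("3-phosphoglycerate", _C, "C3H4O7P", -3),
    "gap_c": ("glyceraldehyde 3-phosphate", _C, "C3H5O6P", -2),
    "f6p_c": ("fructose 6-phosphate", _C, "C6H11O9P", -2),
    "g6p_c": ("glucose 6-phosphate", _C, "C6H11O9P", -2),
    "r5p_c": ("ribose 5-phosphate", _C, "C5H9O8P", -2),
    "e4p_c": ("erythrose 4-phosphate", _C, "C4H7O7P", -2),
    "glyc3p_c": ("glycerol 3-phosphate", _C, "C3H7O6P", -2),
    # one-carbon / THF
    "thf_c": ("tetrahydrofolate", _C, "C19H21N7O6", -2),
    "10fthf_c": ("10-formyl-THF", _C, "C20H21N7O7", -2),
    "methf_c": ("5,10-methenyl-THF", _C, "C20H20N7O6", -1),
    "mlthf_c": ("5,10-methylene-THF", _C, "C20H21N7O6", -2),
    # amino acids (free, pH 7)
    "ala_c": ("L-alanine", _C, "C3H7NO2", 0),
    "arg_c": ("L-arginine", _C, "C6H15N4O2", 1),
    "asp_c": ("L-aspartate", _C, "C4H6NO4", -1),
    "glu_c": ("L-glutamate", _C, "C5H8NO4", -1),
    "gln_c": ("L-glutamine", _C, "C5H10N2O3", 0),
    "gly_c": ("glycine", _C, "C2H5NO2", 0),
    "his_c": ("L-histidine", _C, "C6H9N3O2", 0),
    "ile_c": ("L-isoleucine", _C, "C6H13NO2", 0),
    "leu_c": ("L-leucine", _C, "C6H13NO2", 0),
    "lys_c": ("L-lysine", _C, "C6H15N2O2", 1),
    "met_c": ("L-methionine", _C, "C5H11NO2S", 0),
    "phe_c": ("L-phenylalanine", _C, "C9H11NO2", 0),
    "pro_c": ("L-proline", _C, "C5H9NO2", 0),
    "ser_c": ("L-serine", _C, "C3H7NO3", 0),
    "thr_c": ("L-threonine", _C, "C4H9NO3", 0),
    "tyr_c": ("L-tyrosine", _C, "C9H11NO3", 0),
    "val_c": ("L-valine", _C, "C5H11NO2", 0),
    # nucleoside monophosphates (free, -2)
    "gmp_c": ("GMP", _C, "C10H12N5O8P", -2),
    "ump_c": ("UMP", _C, "C9H11N2O9P", -2),
    "cmp_c": ("CMP", _C, "C9H12N3O8P", -2),
    # macromolecular building blocks
    "glucan_c": ("glucan repeat unit", _C, "C6H10O5", 0),
    "pmt_c": ("palmitate", _C, "C16H31O2", -1),
    "lipid_c": ("phosphatidate surrogate (dipalmitoyl)", _C, "C35H67O8P", -2),
    # extracellular pool
    "no2_e": ("nitrite (medium)", _E, "NO2", -1),
    "no3_e": ("nitrate (medium)", _E, "NO3", -1),
    "nh4_e": ("ammonium (medium)", _E, "H4N", 1),
    "for_e": ("formate (medium)", _E, "CHO2", -1),
    "o2_e": ("oxygen (medium)", _E, "O2", 0),
    "co2_e": ("carbon dioxide (medium)", _E, "CO2", 0),
    "h2o_e": ("water (medium)", _E, "H2O", 0),
    "pi_e": ("phosphate (medium)", _E, "HO4P", -2),
    "so4_e": ("sulfate (medium)", _E, "O4S", -2),
    "h2_e": ("dihydrogen (medium)", _E, "H2", 0),
    "ac_e": ("acetate (medium)", _E, "C2H3O2", -1),
    "pyr_e": ("pyruvate (medium)", _E, "C3H3O3", -1),
    "succ_e": ("succinate (medium)", _E, "C4H4O4", -2),
    "mal_e": ("malate (medium)", _E, "C4H4O5", -2),
    "ala_e": ("L-alanine (medium)", _E, "C3H7NO2", 0),
    "glu_e": ("L-glutamate (medium)", _E, "C5H8NO4", -1),
}

#: abstract mineral pool for the inorganic biomass fraction (mass only)
ASH_MASS = 100.0


def make_species() -> Dict[str, Species]:
    out: Dict[str, Species] = {}
    for sid, (name, comp, formula, charge) in SPECIES_TABLE.items():
        out[sid] = Species(sid, name, comp, _f(formula), charge)
    out["ash_c"] = Species("ash_c", "inorganic ash pool", _C, {}, 0, mass=ASH_MASS)
    out["ash_e"] = Species("ash_e", "inorganic ash pool (medium)", _E, {}, 0, mass=ASH_MASS)
    return out


def balanced(
    rid: str,
    name: str,
    skeleton: Mapping[str, float],
    species: Mapping[str, Species],
    lower: float = -1000.0,
    upper: float = 1000.0,
    subsystem: str = "",
    gene_note: str = "",
    tol: float = 1e-9,
) -> Reaction:
    """Close ``skeleton`` in O and H with water/protons, verify balance.

    Raises :class:`ModelConstructionError` naming the reaction and the
    first offending element if C/N/P/S or charge do not close — H2O/H+
    adjustment cannot repair those.
    """
    stoich = dict(skeleton)

    def residual(el: str) -> float:
        return sum(
            coef * (species[sid].formula or {}).get(el, 0)
            for sid, coef in stoich.items()
        )

    r_o = residual("O")
    if abs(r_o) > tol:
        stoich["h2o_c"] = stoich.get("h2o_c", 0.0) - r_o
        if abs(stoich["h2o_c"]) <= tol:
            del stoich["h2o_c"]
    r_h = residual("H")
    if abs(r_h) > tol:
        stoich["h_c"] = stoich.get("h_c", 0.0) - r_h
        if abs(stoich["h_c"]) <= tol:
            del stoich["h_c"]

    for el in ("C", "N", "O", "H", "P", "S"):
        r = residual(el)
        if abs(r) > tol:
            raise ModelConstructionError(
                f"reaction {rid!r} does not balance element {el} (residual {r:+g})"
            )
    r_q = sum(coef * species[sid].charge for sid, coef in stoich.items())
    if abs(r_q) > tol:
        raise ModelConstructionError(
            f"reaction {rid!r} does not balance charge (residual {r_q:+g}); "
            "a species formula/charge pair is likely inconsistent"
        )
    return Reaction(rid, name, stoich, lower, upper, subsystem, gene_note)
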