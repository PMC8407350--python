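"""Biomass objective function from measured composition.

The biomass pseudo-reaction drains precursor species in amounts that
account for exactly 1 g of dry biomass per gDW, using *residue* masses
for polymer fractions (amino acids and nucleotides are drained as free
monomers, but their mass contribution is counted after loss of the
condensation water, so the drained composition corresponds to the
polymerized cell).  Growth-associated maintenance ATP (GAM) is folded
into the same reaction.

Measured macromolecule fractions sum to 98.3 % before the assumed DNA
and inorganic values are folded in; they are renormalized to 100 %.

Simplifications (documented):
  * DNA (1 % dry wt) is drained as ribonucleotide units together with
    RNA — at this mass fraction the deoxyribose reduction cost is
    negligible for the flux results.
  * Tyr uses the reported mean (SD not determined); Asn/Gln demands are
    folded into the measured Asp/Glu pools; Cys/Trp carry zero demand.
  * The soluble-metabolite/ion pool is an abstract ash drain.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Mapping

import pandas as pd

from .chem import ASH_MASS, SPECIES_TABLE, _f
from .core import ATOMIC_MASS, BiomassComposition, Reaction

WATER_MASS = 18.015

#: amino-acid key (as in the composition table) -> species id
AA_SPECIES = {
    "Ala": "ala_c",
    "Arg": "arg_c",
    "Asp": "asp_c",
    "Glu": "glu_c",
    "Gly": "gly_c",
    "His": "his_c",
    "Ile": "ile_c",
    "Leu": "leu_c",
    "Lys": "lys_c",
    "Met": "met_c",
    "Phe": "phe_c",
    "Pro": "pro_c",
    "Ser": "ser_c",
    "Thr": "thr_c",
    "Tyr": "tyr_c",
    "Val": "val_c",
}

NUCLEOTIDES = ("amp_c", "gmp_c", "ump_c", "cmp_c")


def _species_mass(sid: str) -> float:
    formula = _f(SPECIES_TABLE[sid][2])
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


def residue_mass(sid: str) -> float:
    """Monomer mass minus one water (polymerized residue)."""
    return _species_mass(sid) - WATER_MASS


def load_composition() -> BiomassComposition:
    """The shipped N. moscoviensis measurements."""
    data = resources.files("nitromet.data")
    macro = pd.read_csv(data / "biomass_macromolecules.tsv", sep="\t")
    aa = pd.read_csv(data / "amino_acid_composition.tsv", sep="\t")
    fractions = dict(zip(macro["molecule"], macro["percent_dry_weight"].astype(float)))
    return BiomassComposition(
        macro_fractions={
            "protein": fractions["protein"],
            "carbohydrate": fractions["carbohydrate"],
            "lipid": fractions["lipid"],
            "RNA": fractions["RNA"],
            "DNA": fractions["DNA"],
            "inorganic": fractions["inorganic"],
        },
        amino_acids=dict(
            zip(aa["amino_acid"], aa["umol_per_mg_dry_weight"].astype(float))
        ),
    )


def biomass_coefficients(biomass: BiomassComposition) -> Dict[str, float]:
    """Precursor drains (mmol gDW-1, positive numbers) for 1 g biomass."""
    fr = biomass.normalized_fractions()
    coeffs: Dict[str, float] = {}

    protein_g = fr.get("protein", 0.0) / 100.0
    if protein_g > 0:
        if not biomass.amino_acids or sum(biomass.amino_acids.values()) <= 0:
            raise ValueError("protein fraction positive but no amino acid data")
        rel = {AA_SPECIES[k]: v for k, v in biomass.amino_acids.items() if v > 0}
        mass_per_unit = sum(v * residue_mass(sid) for sid, v in rel.items())  # mg/unit
        scale = 1000.0 * protein_g / mass_per_unit  # mmol per relative unit
        for sid, v in rel.items():
            coeffs[sid] = v * scale

    nucleotide_g = (fr.get("RNA", 0.0) + fr.get("DNA", 0.0)) / 100.0
    if nucleotide_g > 0:
        per_mol_mass = sum(residue_mass(sid) for sid in NUCLEOTIDES)  # equimolar
        n = 1000.0 * nucleotide_g / per_mol_mass
        for sid in NUCLEOTIDES:
            coeffs[sid] = coeffs.get(sid, 0.0) + n

    carb_g = fr.get("carbohydrate", 0.0) / 100.0
    if carb_g > 0:
        coeffs["glucan_c"] = 1000.0 * carb_g / _species_mass("glucan_c")

    lipid_g = fr.get("lipid", 0.0) / 100.0
    if lipid_g > 0:
        coeffs["lipid_c"] = 1000.0 * lipid_g / _species_mass("lipid_c")

    ash_g = fr.get("inorganic", 0.0) / 100.0
    if ash_g > 0:
        coeffs["ash_c"] = 1000.0 * ash_g / ASH_MASS

    return coeffs


def component_mass(sid: str) -> float:
    """Documented per-species mass (g/mmol x 1000) used in the 1-g check."""
    if sid == "ash_c":
        return ASH_MASS
    if sid in AA_SPECIES.values() or sid in NUCLEOTIDES:
        return residue_mass(sid)
    return _species_mass(sid)


def biomass_reaction_from_composition(
    biomass: BiomassComposition, gam: float
) -> Reaction:
    """Biomass pseudo-reaction (flux unit h-1) draining 1 g of precursors
    per gDW plus ``gam`` mmol ATP of growth-associated maintenance."""
    if gam < 0:
        raise ValueError("GAM must be non-negative")
    coeffs = biomass_coefficients(biomass)
    stoich = {sid: -c for sid, c in coeffs.items()}
    stoich["atp_c"] = stoich.get("atp_c", 0.0) - gam
    stoich["h2o_c"] = -gam
    stoich["adp_c"] = gam
    stoich["pi_c"] = gam
    stoich["h_c"] = gam
    return Reaction(
        "biomass",
        "biomass objective (measured composition)",
        stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="biomass",
    )


def biomass_mass_drain(reaction: Reaction) -> float:
    """Grams of biomass components drained per gDW (should be 1.000)."""
    total = 0.0
    for sid, coef in reaction.stoichiometry.items():
        if coef >= 0 or sid in ("atp_c", "h2o_c"):
            continue
        total += -coef * component_mass(sid) / 1000.0
    return total
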