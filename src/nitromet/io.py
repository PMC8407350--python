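"""Model and data I/O: SBML L3V1 (fbc), a lossless JSON dialect, TSV
tables, and the structured run configuration.

JSON dialect schema (documented contract, used by the test suite)::

    {
      "name": str,
      "objective": str,
      "species": [{"id", "name", "compartment", "formula": {el: int} | null,
                   "charge": int, "mass": float | null}, ...],
      "reactions": [{"id", "name", "stoichiometry": {species-id: coeff},
                     "lower_bound", "upper_bound", "subsystem",
                     "gene_note"}, ...]
    }
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from .calibration import RatePair
from .core import (
    COMPARTMENTS,
    ETCStoichiometry,
    MaintenanceParams,
    MetabolicModel,
    Reaction,
    Species,
)


class ModelIOError(ValueError):
    pass


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "name": model.name,
        "objective": model.objective_id,
        "species": [
            {
                "id": s.id,
                "name": s.name,
                "compartment": s.compartment,
                "formula": dict(s.formula) if s.formula is not None else None,
                "charge": s.charge,
                "mass": s.mass,
            }
            for s in model.species
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gene_note": r.gene_note,
            }
            for r in model.reactions
        ],
    }


def model_from_dict(payload: dict) -> MetabolicModel:
    try:
        species = [
            Species(
                id=s["id"],
                name=s.get("name", s["id"]),
                compartment=s["compartment"],
                formula=s.get("formula", {}),
                charge=int(s.get("charge", 0)),
                mass=s.get("mass"),
            )
            for s in payload["species"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", r["id"]),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                subsystem=r.get("subsystem", ""),
                gene_note=r.get("gene_note", ""),
            )
            for r in payload["reactions"]
        ]
        return MetabolicModel(species, reactions, payload["objective"],
                              name=payload.get("name", "model"))
    except KeyError as e:
        raise ModelIOError(f"model JSON missing key: {e}") from None


def write_json_model(model: MetabolicModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))


def read_json_model(path) -> MetabolicModel:
    text = Path(path).read_text()
    if not text.strip():
        raise ModelIOError(f"empty model file: {path}")
    return model_from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# SBML L3V1 + fbc
# ---------------------------------------------------------------------------

_SBML_COMPARTMENT = {"cytoplasm": "c0", "periplasm": "p0", "extracellular": "e0"}
_SBML_COMPARTMENT_BACK = {v: k for k, v in _SBML_COMPARTMENT.items()}


def _sid(raw: str) -> str:
    """SBML-legal identifier."""
    out = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    return out if re.match(r"[A-Za-z_]", out) else "_" + out


def write_sbml_model(model: MetabolicModel, path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.name))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in COMPARTMENTS:
        c = sbml_model.createCompartment()
        c.setId(_SBML_COMPARTMENT[comp])
        c.setName(comp)
        c.setConstant(True)
        c.setSize(1.0)

    for s in model.species:
        sp = sbml_model.createSpecies()
        sp.setId(_sid(s.id))
        sp.setName(s.name)
        sp.setCompartment(_SBML_COMPARTMENT[s.compartment])
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        splug.setCharge(s.charge)
        if s.formula:
            splug.setChemicalFormula(
                "".join(f"{el}{n}" for el, n in sorted(s.formula.items()))
            )
        if s.mass is not None:
            sp.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                        f"<p>mass={s.mass}</p></body>")

    bounds_seen: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"bnd_{len(bounds_seen)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    for r in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId(_sid(r.id))
        rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        if r.subsystem or r.gene_note:
            rx.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>subsystem={r.subsystem}</p><p>gene_note={r.gene_note}</p>"
                "</body>"
            )
        for sid, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(_sid(sid))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    fo = obj.createFluxObjective()
    fo.setReaction(_sid(model.objective_id))
    fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelIOError(f"failed to write SBML to {path}")


def read_sbml_model(path) -> MetabolicModel:
    import libsbml

    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"no such file: {path}")
    if not path.read_text().strip():
        raise ModelIOError(f"empty model file: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelIOError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelIOError(f"no model element in {path}")

    def parse_notes(notes: Optional[str]) -> Dict[str, str]:
        if not notes:
            return {}
        return dict(re.findall(r"<p>\s*(\w+)=([^<]*)</p>", notes))

    species: List[Species] = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula: Optional[Dict[str, int]] = {}
        if splug is not None and splug.isSetChemicalFormula():
            formula = {
                el: int(n) if n else 1
                for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", splug.getChemicalFormula())
            }
        notes = parse_notes(sp.getNotesString() if sp.isSetNotes() else None)
        mass = float(notes["mass"]) if "mass" in notes else None
        species.append(
            Species(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=_SBML_COMPARTMENT_BACK[sp.getCompartment()],
                formula=formula,
                charge=splug.getCharge() if splug is not None else 0,
                mass=mass,
            )
        )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    reactions: List[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb = params.get(rplug.getLowerFluxBound(), -1000.0)
        ub = params.get(rplug.getUpperFluxBound(), 1000.0)
        notes = parse_notes(rx.getNotesString() if rx.isSetNotes() else None)
        reactions.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or rx.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=notes.get("subsystem", "").strip(),
                gene_note=notes.get("gene_note", "").strip(),
            )
        )

    mplug = sbml_model.getPlugin("fbc")
    objective_id = ""
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()
    return MetabolicModel(species, reactions, objective_id,
                          name=sbml_model.getId())


def roundtrip_model(path) -> MetabolicModel:
    """Read a model file (SBML .xml/.sbml or the JSON dialect)."""
    p = Path(path)
    if not p.exists():
        raise ModelIOError(f"no such file: {p}")
    if p.suffix == ".json":
        return read_json_model(p)
    return read_sbml_model(p)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_flux_tsv(model: MetabolicModel, solution, path) -> None:
    from .fba import solution_table

    solution_table(model, solution).to_csv(path, sep="\t", index=False)


def read_rate_pairs(path) -> List[RatePair]:
    df = pd.read_csv(path, sep="\t")
    if not {"uptake", "growth"} <= set(df.columns):
        raise ModelIOError("rate-pair TSV needs 'uptake' and 'growth' columns")
    return [RatePair(float(u), float(g)) for u, g in zip(df["uptake"], df["growth"])]


def read_mids_tsv(path):
    """TSV of raw MIDs: metabolite, n_carbons, M0..Mmax columns."""
    from .isotope import MID

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        n = int(row["n_carbons"])
        fractions = [float(row[f"M{i}"]) for i in range(n + 1)]
        out.append(MID(str(row["metabolite"]), n, fractions))
    return out


def write_mids_tsv(mids, path) -> None:
    nmax = max(m.n_carbons for m in mids)
    rows = []
    for m in mids:
        row = {"metabolite": m.metabolite, "n_carbons": m.n_carbons}
        for i in range(nmax + 1):
            row[f"M{i}"] = m.fractions[i] if i <= m.n_carbons else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "etc", "options", "maintenance", "scenarios", "isotope", "seeds",
    "output_dir", "operating_point", "rate_pairs_tsv", "measured_formate_growth",
}


@dataclass
class RunConfig:
    etc: ETCStoichiometry = field(default_factory=ETCStoichiometry)
    rgp_enabled: bool = True
    hydrogenase_enabled: bool = True
    maintenance: MaintenanceParams = field(
        default_factory=lambda: MaintenanceParams(gam=535.0, ngam=0.90)
    )
    operating_point: tuple = (8.5, 0.006)
    #: measured formate-growth rate for the complex-I cap (h-1)
    measured_formate_growth: float = 0.004
    p13: float = 0.0107
    tracer_fraction: float = 0.65
    seed: int = 20210817
    output_dir: str = "nitromet_out"
    rate_pairs_tsv: Optional[str] = None


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ModelIOError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    if "etc" in raw:
        cfg.etc = ETCStoichiometry(**raw["etc"])
    opts = raw.get("options", {})
    cfg.rgp_enabled = bool(opts.get("rgp_enabled", True))
    cfg.hydrogenase_enabled = bool(opts.get("hydrogenase_enabled", True))
    if "maintenance" in raw:
        cfg.maintenance = MaintenanceParams(**raw["maintenance"])
    if "operating_point" in raw:
        cfg.operating_point = tuple(raw["operating_point"])
    if "measured_formate_growth" in raw:
        cfg.measured_formate_growth = float(raw["measured_formate_growth"])
    iso = raw.get("isotope", {})
    cfg.p13 = float(iso.get("p13", cfg.p13))
    cfg.tracer_fraction = float(iso.get("tracer_fraction", cfg.tracer_fraction))
    seeds = raw.get("seeds", {})
    cfg.seed = int(seeds.get("master", cfg.seed))
    cfg.output_dir = str(raw.get("output_dir", cfg.output_dir))
    if "rate_pairs_tsv" in raw and raw["rate_pairs_tsv"] is not None:
        p = Path(raw["rate_pairs_tsv"])
        if not p.exists():
            raise ModelIOError(f"rate pairs TSV not found: {p}")
        cfg.rate_pairs_tsv = str(p)
    return cfg


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
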