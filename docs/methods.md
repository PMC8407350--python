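# Methods

## Scope and model form

`nitromet` implements a curated *core* stoichiometric model of
*Nitrospira moscoviensis* energy and carbon metabolism — roughly 100
reactions over three compartments — rather than a genome-scale
reconstruction. Growth phenotypes are computed by flux balance
analysis: maximize the biomass flux subject to `S v = 0` and
`vmin <= v <= vmax`, solved with HiGHS through
`scipy.optimize.linprog`. Degenerate alternative optima are resolved by
a second LP minimizing total absolute flux at the fixed optimum
(parsimonious tie-break), so reported flux distributions are
reproducible. LP feasibility tolerance is 1e-9, optimality 1e-8, and
default bounds are ±1000 mmol gDW⁻¹ h⁻¹ (irreversible reactions
[0, 1000]).

Every internal reaction is element- (C, H, N, O, P, S) and
charge-balanced; the model builder closes each curated reaction
skeleton in H and O with cytoplasmic protons and water and then
*verifies* all elements and charge, so a curation error cannot survive
construction. Electron carriers with invariant scaffolds (ferredoxin,
cytochrome *c*) are abstract species whose redox state lives in the
charge; the inorganic "ash" biomass component is an abstract
mass-only pool. Exchange and biomass reactions are exempt from balance
checking by definition.

## Respiratory chain and proton bookkeeping

Periplasmic protons (`h_p`) are a pure proton-motive-force ledger: only
translocation reactions touch them. Charge-equivalents per 2 e⁻:

| step | value | basis |
|---|---|---|
| NXR, periplasmic H⁺ release | 2 | nitrite oxidation chemistry occurs on the periplasmic face |
| cytochrome *bc₁* (complex III) | 4 | Q-cycle, textbook value, both directions |
| complex I (NADH) | 4 | consensus for H⁺-pumping complex I |
| 2M-type complex I (ferredoxin) | 8 | thermodynamic estimate, see below |
| cytochrome *bd* oxidase | 2 | charge separation only, no pumping |
| ATP synthase H⁺/ATP | 4 | calibrated so the net nitrite ATP yield is exactly 1.0 |

The per-complex stoichiometries of this organism are not measured;
published values exist only for model organisms. The ferredoxin-reducing
2M-type complex I value follows from thermodynamic consistency: moving
2 e⁻ from quinol (E°′ ≈ +100 mV) to the low-potential ferredoxin pool
serving the 2-oxoglutarate and pyruvate synthases (E°′ ≈ −500 mV)
requires ΔE ≈ 0.6 V ≈ 115 kJ per 2 mol e⁻, i.e. at least 7–8 charges at
a proton-motive force of 150–180 mV; we use 8. The H⁺/ATP ratio is not
set independently: `ETCStoichiometry.calibrated_h_per_atp()` returns
the value that makes the net ATP yield per nitrite equal 1.0 (the
organism's measured energetics), which is 4 under the stoichiometries
above, since one nitrite contributes 2 periplasmic H⁺ at NXR plus 2
charges at the oxidase.

Nitrogen is assimilated from nitrite via cytoplasmic
ferredoxin-nitrite reductase plus GS/ferredoxin-GOGAT in the
chemostat medium (which contains no ammonium); batch-scenario media
additionally provide ammonium. A quinol-dependent octaheme nitrite
reductase can be enabled as an alternative assimilatory route but is
off by default: with the ferredoxin route the model reproduces the
measured partition of reverse electron flow between the NADH and
ferredoxin branches, which is the observable this choice was made
against.

## Biomass objective

The biomass pseudo-reaction drains measured composition: protein
46.7 % dry weight distributed over 16 amino acids in the measured
molar proportions, carbohydrate 26.9 % as glucan units, lipid 16.3 %
as a two-species phosphatidate surrogate (dipalmitoyl +
glycerophosphate headgroup; the published fatty-acid profile is not
printed, and this choice affects only elemental bookkeeping), RNA
2.4 % plus DNA 1 % as equimolar NMPs (deoxy reduction neglected at
this mass fraction), and 5 % inorganic ash. Fractions are renormalized
from their raw sum (98.3 %) to 100 %. Monomer masses use residue
(polymerized) masses so the drained components account for exactly
1.000 g per gDW (checked to 1e-6). Amino acids without measured values
follow the documented mapping: Asn→Asp and Gln→Glu pools, Cys/Trp zero
demand, Tyr uses the reported mean. Growth-associated maintenance ATP
(GAM) is a coefficient of this same reaction.

Monomer biosynthesis is lumped: each amino acid, nucleotide, and
lipid precursor has one reaction from central metabolites with
standard pathway ATP/NAD(P)H costs; the redox coefficient of every
lump was audited against a degree-of-reduction balance, so lumping
preserves the electron economy exactly.

## Maintenance calibration

Non-growth-associated maintenance (NGAM) is the y-intercept of
ordinary least squares of nitrite uptake on growth rate multiplied by
the model ATP yield (1.0), fixing the lower bound of the ATP
hydrolysis reaction. GAM is fitted by bisection (bracket [0, 5000]
mmol ATP gDW⁻¹, ≤60 iterations, relative slope tolerance 1e-3): for
each candidate the model's uptake-vs-growth slope is measured by
minimizing nitrite uptake at fixed growth rates {0.002, 0.006, 0.010}
h⁻¹ and matched to the slope implied by the chemostat operating point
(uptake 8.5 mmol gDW⁻¹ h⁻¹ at 0.006 h⁻¹) and the fitted intercept.
Because the LP is linear in growth rate, the calibrated model
reproduces the operating point in forward FBA by construction.

The fitted GAM of this core model is ≈ 880 mmol ATP gDW⁻¹, higher
than the ≈ 535 reported for the genome-scale reconstruction. The
discrepancy is structural: at a net yield of 1.0 ATP/NO₂⁻ the
operating line fixes the *total* ATP-equivalent demand per gram at
(8.5 − 0.90)/0.006 ≈ 1267 mmol, and the split between GAM and
explicit biosynthetic cost depends on how much of that demand the
reconstruction carries in its pathway stoichiometry. A lumped core
model carries less, so the slope-matching procedure assigns the
remainder to GAM. Growth-rate predictions are unaffected (the sum is
calibrated); only the GAM label differs.

## Growth scenarios

Scenario A (nitrite 8.5, chemostat medium), B (nitrite 8.7), C
(formate 6.0), D (nitrite 8.7 + formate 6.0); B–D use batch medium
with ammonium. Substrate uptakes are fixed at the stated values; fold
changes for C and D are reported against B, the reference measured in
the same batch system. Formate enters by the FocA channel and is
oxidized by the soluble NAD⁺-linked FDH; the reductive glycine
pathway (formate-THF ligase `rxn00690_c0`, methylene-THF
interconversion, reverse glycine cleavage, SHMT, serine dehydratase)
provides direct assimilation and is disabled by zeroing the ligase
bounds only.

On formate, direct assimilation saves exactly 4 electrons and all
ferredoxin per pyruvate relative to rTCA refixation of CO₂ (10 e⁻ as
1 NADH + 1 quinol + 1 NADPH + 2 reduced ferredoxin versus 6 e⁻ as 1
NADH + 2 NADPH). The *growth* advantage this buys in an
energy-denominated core model is small (~1.5 %, versus ~4 % in the
genome-scale model): with every 2-electron pair worth exactly one
formate through the ETC, route costs tie up to the ferredoxin
translocation premium minus the quinol credit of fumarate reductase.
The optimal direct-assimilation fraction (~6 % of formate uptake) is
insensitive to this margin, because it corresponds to routing
essentially all pyruvate-family carbon through the pathway.

The complex-I-limitation analysis fixes formate uptake at the
measured rate and bisects a cap on oxidative complex I flux until the
growth optimum equals the measured (low) growth rate, with one
candidate secretion exchange opened at a time from {acetate,
pyruvate, succinate, malate, alanine, glutamate}. Solutions are
parsimonious; surplus NADH then leaves as reduced carbon (acetate
cannot absorb electrons and drops out). A target equal to the
unconstrained optimum returns the no-secretion solution flagged as
such.

## Isotope arithmetic and labeling simulation

Enrichment is (1/N) Σᵢ i·Mᵢ. Natural-abundance correction inverts the
binomial convolution operator (carbon only, p₁₃ = 0.0107 by default);
negative corrected fractions are clipped to zero and renormalized,
with the clip count reported, since the measurement model does not
specify their handling. Tracer normalization divides by the tracer
¹³C fraction and flags (does not clip) values above 1.

The labeling simulator integrates pool-level enrichment ODEs
(LSODA, atol 1e-9, rtol 1e-6) after a step change in tracer
enrichment — enrichment resolution, not positional isotopomers; MIDs
are reported under the binomial approximation, a documented
simplification relative to true rTCA atom mappings. Channeling is
modeled as a per-metabolite inactive sub-pool (fraction f) exchanging
slowly (default 0.05 h⁻¹) with the flux-carrying active sub-pool;
measurements mix the two, so metabolites downstream of a channeled
precursor label faster than the measured precursor — the qualitative
pattern asserted by the tests is a property of the simulator, not a
claim about the organism. Default pool sizes (0.1–5 µmol gDW⁻¹) were
drawn once and frozen; no measured pool sizes exist. The formate
batch generator mixes 1 mM labeled into 0.5 mM residual unlabeled
formate (plateau 2/3) with an optional extracellular-dilution factor,
since the measured ~40 % intracellular plateau is unexplained; the
dissolved-inorganic-carbon pool is large (default 2000 µmol gDW⁻¹
equivalent) because it buffers medium bicarbonate and headspace CO₂.

The chemostat generator produces uptake/growth pairs on the
maintenance line with Gaussian noise. The noise default (σ = 0.02
mmol gDW⁻¹ h⁻¹) is the measurement precision of the chemostat uptake
rate at which the stated recovery property (planted NGAM within 10 %
in ≥95 % of seeded replicates at n = 20) holds; proportional noise at
2 % of the mean uptake would make the intercept statistically
unrecoverable at that tolerance (OLS intercept SE ≈ 0.11 at n = 20
over the 0.002–0.012 h⁻¹ range).

## What the synthetic data do and do not show

The generators emulate the *structure* of the experiments — linear
chemostat maintenance lines, step-tracer washin kinetics, dual-pool
dilution, headspace accumulation — with seeded determinism
(byte-identical fixtures per seed). They do not emulate positional
labeling patterns, LC-MS peak-level noise structure, metabolite
extraction losses, or biological replicate variability; passing tests
therefore demonstrate correctness of the arithmetic and the simulator
contracts, not fidelity to any particular measured trajectory.

## Numerical choices and limitations

Problem sizes: the model solves in milliseconds; the full test suite
and the acceptance script each run in seconds at the default sizes
(20 chemostat points, 200 Monte-Carlo replicates, ≤6-reaction
brute-force LP oracles). Known limitations: lumped biosynthesis makes
absolute GAM incomparable to genome-scale values (see above); the
formate growth-improvement margin of the RGP is compressed for the
same reason; hydrogenase is a stub; flux variability, thermodynamic
constraints and ¹³C-MFA fitting are out of scope.
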