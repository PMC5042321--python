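# Methods

## Thermodynamic model

The model is the transformed biochemical thermodynamics of Alberty /
Thauer at pH 7: every species carries a standard transformed formation
energy ΔGf°′ (kJ mol⁻¹, 298.15 K), the proton is assigned the fixed
convention value RT·ln(10⁻⁷) = −39.96 kJ mol⁻¹ and, like water, never
appears in a reaction quotient. Activities are concentrations over 1 M
for solutes and partial pressures over 1 bar for gases; activity
coefficients are taken as 1 throughout (dilute-solution assumption).
Reaction energies are ΔG = ΔG°′ + RT·Σν·ln a; half-couple potentials are
E = E°′ + (RT/nF)·ln(Πa_ox/Πa_red), and coupling a donor to an acceptor
gives ΔG = −nFΔE with ΔE = E_acc − E_don.

**Constants.** `data/thermo_constants.tsv` embeds formation energies and
half-couple potentials (Thauer-style pH-7 values, each row tagged with
its source). Couples whose sides are fully covered by tabulated ΔGf°′
are cross-checked at load-test time: E°′ must equal −ΔG°′/(nF) within
1 mV (five couples carry the full decomposition; couples involving CoA
thioesters, adenylylated sulfur species or the alanine couple — whose
formation-energy route misses the tabulated E°′ by slightly more than
1 mV — store E°′ only). Physical constants: R = 8.3145 J mol⁻¹ K⁻¹,
F = 96 485 C mol⁻¹, 1 bar = 10⁵ Pa.

**Temperature.** The default is 298.15 K, the temperature at which the
tabulated constants are defined and at which the model's reference
numbers (0.03 Pa, −23 kJ mol⁻¹, −244 mV) arise. Temperature is a
parameter everywhere; at the 310 K culture temperature the lactate
equilibrium pressure becomes ≈ 0.05 Pa (ΔG°′ values are treated as
temperature-independent, i.e. ΔH corrections are not modelled).

**Equilibrium hydrogen pressure.** For a reaction containing H₂ with
signed stoichiometry ν_H2, the pressure solving ΔG = 0 is
P* = exp(−(ΔG°′ + RT·Σ_other ν ln a)/(ν_H2·RT)) bar. The implementation
is closed-form; tests verify the round trip ΔG(P*) = 0 to 10⁻⁶ kJ mol⁻¹
for both producing (ν = +1) and consuming (ν = −4) stoichiometries.

**Ion-translocation investment.** The chemiosmotic energy available from
m singly charged ions moving down a fold-ratio concentration gradient is
E_inv = −m·RT·ln(fold) ≤ 0, with ΔpH gradients mapped as fold = 10^ΔpH.
Only the concentration term is modelled: an electrical membrane
potential (Δψ) term is deliberately absent, because the investment is
defined here purely over a concentration gradient; adding Δψ would
change the magnitude, not the structure, of the argument. The invested
energy enters in two provably equivalent ways: added to ΔG°′ when
solving for the tolerated H₂ pressure (factor exp(|E_inv|/(ν_H2·RT)),
exactly 10^(m·ΔpH) per H₂), or as an effective acceptor-potential shift
|ΔE| = |E_inv|/(nF) on the 2-electron H₂ couple. A 100-point
random-conditions test holds the two routes to 0.1 % of each other.

**Methanogen threshold.** The minimum H₂ pressure for 4H₂ + CO₂ → CH₄ +
2H₂O is computed from the same table (ΔG°′ ≈ −131 kJ mol⁻¹) with CH₄ and
CO₂ at 1 bar — the simplest closed headspace assumption, which
reproduces the literature threshold of 0.2 Pa and a hydrogen-couple
potential of −244 mV at that pressure. The 1-bar choice is an inference,
not a measured condition; both gases are parameters of `Conditions`.

## Pathway model

The thirteen-enzyme network (LDH, POR, PTA, ACK, FDN, HUP, HYD, COO,
SAT, APR, DSV, ALD, ADH) is represented as a redox ladder: every enzyme
with a redox role is a rung at the Nernst potential of its half-couple
under the given conditions; PTA, ACK and SAT are substrate-level steps
and carry no rung. Electron flow is feasible strictly from more negative
to more positive potentials (equality = no driving force).

Sink scenarios are judged by that rule over the required 2-electron
transfers: the sulfate and hydrogen sinks carry both the LDH and POR
legs (and hence traverse the ATP-generating POR-PTA-ACK branch), while
the ethanol and alanine sinks re-oxidise only the LDH electrons and
bypass ATP generation. The reported "total ΔG per lactate" sums −nFΔE
over those transfers, each donor against its least favourable required
acceptor; the sulfate branch is evaluated at the level of half-couple
potentials only (no APS/ATP stoichiometric bookkeeping — none is needed
for the feasibility question). One genuinely condition-dependent detail:
the alanine sink's couple contains pyruvate on its oxidised side, so it
is feasible at standard state but turns marginal at 0.1 mM pyruvate
unless alanine is also scarce; the ethanol sink behaves oppositely
(marginally infeasible at standard state by ~7 mV, clearly feasible at
physiological lactate/pyruvate). Scenario evaluation therefore defaults
to the physiological condition set.

The investment's two readings are kept deliberately distinct:
feasibility arithmetic treats it as raising the *effective* acceptor
potential of Coo, while `apply_investment_to_ladder` draws the COO rung
displaced downward by the same magnitude — the picture of an
energy-subsidised electron elevator. Both use |ΔE| = |E_inv|/nF and are
additive in energy.

`syntrophy_window` packages the producer's tolerated maximum (with
optional investment) against the methanogen's minimum; overlap
(strictly max > min) is the syntrophy-feasibility verdict.

## Variant screen

Per-clone VCFs are read with pysam. The alternate-allele fraction comes
from the VarScan `FREQ` percent string when present, else `AD`/`DP`
(both the VarScan scalar-AD and the standard Number=R dialects).
Variants are unified across clones by (replicon, position, ref, alt)
after parsimony normalisation — shared-suffix then shared-prefix
trimming with position adjustment. Full left-alignment against a
reference genome is out of scope (no reference is consumed), so
repeat-mediated alternative placements are not collapsed; the padded and
anchored representations that arise in practice are.

Absence semantics follow the evidence: a record with coverage and zero
alternate support is fraction 0, while a site entirely absent from a
clone's file is *missing* (a variant caller emits only called sites, so
absence proves nothing). Missing entries disqualify a variant from
candidacy in both screen modes, and round-trip exactly as omitted
records when matrices are written back to VCF.

State calls use thresholds (0.1, 0.9): ≥ 0.9 present, ≤ 0.1 absent,
otherwise a mixed allele signature. The thresholds are an inference (no
published calling rule exists for read-fraction heatmaps) and are
exposed on every entry point. The screen itself is exhaustive and
deterministic: present in all positives and absent in all negatives,
with permissive mode counting mixed positives as present — the mode that
admits clones carrying heterogeneous genotypes or multiple genome
copies. Permissive candidates are a superset of strict candidates by
construction, and results are invariant to clone order.

Effect annotation is intentionally minimal: indel reading-frame
(length difference mod 3) and codon-level consequence of a variant
placed on a user-supplied CDS, flagging the biologically double-edged
loss of a TGA codon (premature stop vs selenocysteine residue). Full
functional annotation belongs to upstream tools.

## Synthetic data

The generator emulates a clone re-sequencing experiment, not reads: no
FASTQ, no error model, no reference genome. Defaults are the study
conditions — 5 clean positives, 2 mixed-signature positives, 3
negatives, 55 background variants, 2 planted variants. Background
positions are uniform over a 3.5 Mb chromosome and 0.2 Mb megaplasmid
(approximate DvH replicon sizes). Read fractions are drawn per intended
state from Beta distributions with means 0.98 / 0.02 / 0.5 (present /
absent / mixed) and per-state concentration parameters; `None` means
noiseless exact fractions (1, 0, 0.5). Background state patterns are
drawn independently of phenotype but rejection-sampled away from
patterns concordant with the labels in either orientation — without
this, random backgrounds produce occasional false concordances and the
zero-noise screen could not be guaranteed to recover exactly the planted
set. Consequently, passing recovery tests demonstrate the screen's
logic, not its false-positive rate on truly random backgrounds; the
noise-sweep test (sensitivity declining as Beta spread grows, 200
replicates per level) probes robustness instead.

`make_paper_fixture` freezes one such panel: 26 + 27 chromosome SNPs and
INDELs, 2 + 2 on the megaplasmid (57 total), with the two planted
variants at chromosome positions 3 142 197 (G→A) and 2 381 876 (GAG
deletion, anchored CGAG>C) — fully present in s1–s5, mixed (0.5) in
ns1–ns2, absent in ns3–ns5. Per-variant fractions of the other 55 are
constructed (each carried by at least one clone on both sides of the
phenotype split); only the aggregate counts and the concordance pattern
mirror the real experiment, whose per-clone genotype table is not
reproduced here. The fixture is golden-tested: any change to its
construction fails the suite.

VCF output is VarScan-flavoured (GT/DP/RD/AD/FREQ, FREQ as a percent
string with four decimals, so fractions survive a round trip to 10⁻⁶).

## Numerical and testing choices

Energies are kept in kJ mol⁻¹, potentials in volts, pressures in bar
internally and Pa at the interfaces; all conversions live in
`ThermoConstants`. Ladder ordering ties break alphabetically. Display
rounds pressures to 2 significant figures (with the 1-s.f. value
alongside), energies to 3, potentials to the mV. Problem sizes in the
test suite — 100-point route-equivalence grids, 20-seed recovery runs,
200-replicate noise sweeps on 22-variant panels — keep the full suite
around ten seconds while leaving the Monte-Carlo assertions
well-resolved.

## Limitations

Closed-form equilibrium thermodynamics only: no kinetics, no flux
balance, no growth or yield prediction, no co-culture dynamics, and no
formate-transfer branch beyond FDN's rung on the ladder. ΔGf°′ values
are 25 °C constants applied unchanged at other temperatures. The screen
consumes variant calls as given — mapping artefacts, calling errors and
copy-number effects upstream of the VCF are invisible to it, and the
synthetic generator models none of them.
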