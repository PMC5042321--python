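# syntherm

Bioenergetics of syntrophic lactate oxidation in *Desulfovibrio vulgaris*
Hildenborough (DvH), and a phenotype-concordance screen for the genetic
variants behind it.

Sulfate reducers like DvH normally respire lactate with sulfate. Without
sulfate they can only keep oxidising lactate if a partner — here the
hydrogenotrophic methanogen *Methanococcus maripaludis* — keeps the
hydrogen partial pressure low enough (interspecies hydrogen transfer).
`syntherm` models when that works, and screens re-sequenced clone panels
for the mutations that distinguish syntrophy-competent genotypes.

## The model

All quantities use the transformed (pH 7) convention: E°′ and ΔGf°′ at
1 M solutes / 1 bar gases, H⁺ and water never enter a reaction quotient.

* **Reaction energies.** ΔG°′ = Σ ν·ΔGf°′ and
  ΔG = ΔG°′ + RT·Σ ν·ln a, with solute activities c/1 M and gas
  activities p/1 bar.
* **Redox ladder.** Each pathway enzyme sits at the Nernst potential of
  its half-couple, E = E°′ + (RT/nF)·ln(a_ox/a_red); electrons flow only
  from more negative to more positive rungs. Coupling a donor and an
  acceptor gives ΔG = −nFΔE.
* **The hydrogen bottleneck.** Fermentative lactate oxidation
  (lactate⁻ → pyruvate⁻ + H₂) is endergonic by ≈ +43.2 kJ mol⁻¹ at
  standard state. At 1 mM lactate and 0.1 mM pyruvate it only becomes
  exergonic below ≈ 0.03 Pa H₂ — under the ≈ 0.2 Pa a methanogen needs
  for 4H₂ + CO₂ → CH₄ + 2H₂O. The windows do not overlap: plain
  fermentation cannot feed a methanogen.
* **Chemiosmotic rescue.** Letting m singly charged ions flow down a
  membrane gradient invests −m·RT·ln(fold) into the reaction
  (2 ions × 100-fold ≈ −23 kJ mol⁻¹). Per H₂ produced, each ion over a
  2-pH-unit gradient multiplies the tolerated H₂ pressure by exactly
  10^ΔpH = 100 (0.03 Pa → 3 Pa > 0.2 Pa), equivalently shifting the
  effective acceptor potential of the ion-translocating Coo hydrogenase
  by |ΔE| = |E_inv|/nF ≈ 60–120 mV.
* **Variant screen.** Per-clone VCFs (VarScan FREQ or AD/DP dialects)
  merge into a variants × clones matrix of alternate-allele read
  fractions; a candidate variant is *present* (fraction ≥ 0.9) in every
  syntrophy-positive clone and *absent* (≤ 0.1) in every negative clone,
  with a permissive mode that accepts mixed allele signatures in
  positives. Minimal effect annotation covers reading-frame and
  codon-level consequences (including TGA stop/selenocysteine
  replacement).

## Worked example

```bash
python examples/syntrophy_window.py
```

```
ΔG°' (lactate⁻ → pyruvate⁻ + H₂) = +43.2 kJ/mol
Producer ceiling (no investment):  0.027 Pa H₂
Methanogen floor (4H₂+CO₂→CH₄):    0.19 Pa H₂
Overlap: False
Invest 1 ion over a 2-pH-unit gradient: -11.4 kJ/mol
Producer ceiling with investment:  2.72 Pa H₂ (×100)
Overlap: True
```

Reading: without energy investment the lactate fermenter's equilibrium
H₂ ceiling (0.03 Pa, one significant figure) sits below the
methanogenesis floor (0.2 Pa), so syntrophy is thermodynamically
blocked; translocating a single ion per H₂ over a 2-pH-unit gradient
raises the ceiling a hundred-fold to ≈ 3 Pa and opens the window. The
other scripts in `examples/` walk the redox ladder and sink scenarios
(`redox_ladder.py`), the ten-clone concordance screen
(`variant_screen.py`) and codon-effect annotation (`codon_effects.py`).

A thin CLI mirrors the library:

```bash
syntherm window                      # the numbers above
syntherm ladder --plot ladder.svg    # electron tower
syntherm simulate variants --seed 4 --out panel/
syntherm screen run --vcf-dir panel/ --labels panel/labels.tsv
```

## Scope

No kinetics, flux balance, growth prediction or activity-coefficient
corrections; variant calling itself (read mapping, VarScan) is upstream —
only its VCF output format is consumed. Constants ship in
`src/syntherm/data/thermo_constants.tsv` and can be overridden.
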