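"""The hydrogen-pressure window for syntrophic lactate oxidation.

Computes the standard free energy of lactate⁻ → pyruvate⁻ + H₂, the
equilibrium H₂ pressure at realistic metabolite concentrations, and how
chemiosmotic ion translocation moves that ceiling past the methanogen's
minimum requirement.
"""

from syntherm import (
    Conditions, IonInvestment, LACTATE_FERMENTATION,
    ion_translocation_energy, standard_delta_g, syntrophy_window,
)

dg0 = standard_delta_g(LACTATE_FERMENTATION)
print(f"ΔG°' (lactate⁻ → pyruvate⁻ + H₂) = {dg0:+.1f} kJ/mol")
print("  → strongly endergonic at standard state: fermentation is blocked "
      "unless products are kept scarce.\n")

cond = Conditions.physiological()  # 1 mM lactate, 0.1 mM pyruvate, 298.15 K
closed = syntrophy_window(cond)
print(f"Producer ceiling (no investment):  {closed.max_h2_tolerated:.3f} Pa H₂")
print(f"Methanogen floor (4H₂+CO₂→CH₄):    {closed.min_h2_required:.2f} Pa H₂")
print(f"Overlap: {closed.overlap}  → the producer stalls below what the "
      "methanogen needs; plain fermentation cannot sustain syntrophy.\n")

inv = IonInvestment.from_delta_ph(n_ions=1, delta_ph=2)
print(f"Invest 1 ion over a 2-pH-unit gradient: {inv.energy:.1f} kJ/mol "
      f"(2 ions × 100-fold would give {ion_translocation_energy(2, 100):.1f} kJ/mol)")
opened = syntrophy_window(cond, inv)
print(f"Producer ceiling with investment:  {opened.max_h2_tolerated:.2f} Pa H₂ "
      f"(×{opened.max_h2_tolerated / closed.max_h2_tolerated:.0f})")
print(f"Overlap: {opened.overlap}  → one translocated ion per H₂ raises the "
      "ceiling a hundred-fold, opening the window for interspecies hydrogen transfer.")
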