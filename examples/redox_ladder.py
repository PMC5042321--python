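"""The electron tower of the lactate-oxidation / sulfate-respiration network.

Places every redox enzyme at its Nernst potential, shows which electron
sinks can accept LDH electrons, and how the Coo hydrogenase's
ion-translocation investment changes the picture without sulfate.
"""

from syntherm import (
    Conditions, IonInvestment, PathwayScenario, apply_investment_to_ladder,
    build_ladder, evaluate_scenario,
)

# H2 held at the methanogen's minimum (0.2 Pa = 2e-6 bar)
cond = Conditions.physiological(h2_bar=2e-6)
ladder = build_ladder(None, cond)
print("Redox ladder (most negative = strongest electron donor):")
for entry in ladder.entries:
    print(f"  {entry.label:4s} {entry.potential * 1000:8.1f} mV")
print(f"  methanogen acceptance line: {ladder.reference_line * 1000:.0f} mV")
print("Electrons only flow downward on this list (toward more positive rungs).\n")

for sink, sulfate, inv in [("sulfate", True, None),
                           ("hydrogen-hyd", False, None),
                           ("hydrogen-coo", False, IonInvestment.from_delta_ph(1, 2))]:
    res = evaluate_scenario(PathwayScenario(sulfate, sink, inv), cond)
    print(f"sink={sink:13s} feasible={res.feasible!s:5s} ATP={res.atp_generating}")
print("\nWith sulfate the pathway runs; without it, plain hydrogenases cannot"
      "\naccept LDH electrons at syntrophic H₂ pressures — but the Coo route,"
      "\nsubsidised by one translocated ion per H₂, can, and keeps the"
      "\nATP-generating POR-PTA-ACK leg in play.")

shifted = apply_investment_to_ladder(ladder, IonInvestment.from_delta_ph(1, 2))
delta = (ladder.potential("COO") - shifted.potential("COO")) * 1000
print(f"\nLadder rendering: the invested energy displaces the COO rung by {delta:.0f} mV.")
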