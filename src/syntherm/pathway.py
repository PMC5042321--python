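"""The lactate-oxidation / sulfate-respiration network as a redox ladder.

Each enzyme of the *D. vulgaris* core catabolism is a rung placed at the
condition-dependent Nernst potential of the redox reaction it catalyses;
electrons can only flow from more negative rungs to more positive ones.
The module evaluates electron-sink scenarios (sulfate, ethanol, alanine,
hydrogen via the periplasmic hydrogenases or via the ion-translocating
Coo hydrogenase with a chemiosmotic energy investment) and the syntrophy
feasibility window: the highest H₂ pressure the producer tolerates
against the lowest a hydrogenotrophic methanogen requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .thermo import (
    CONSTANTS,
    Conditions,
    IonInvestment,
    LACTATE_FERMENTATION,
    METHANOGENESIS,
    Reaction,
    ThermoConstants,
    ThermoTable,
    default_table,
    equilibrium_h2_pressure,
    nernst_potential,
    potential_shift,
    standard_delta_g,
    tolerated_pressure_with_investment,
)

__all__ = [
    "EnzymeStep",
    "LadderEntry",
    "RedoxLadder",
    "PathwayScenario",
    "ScenarioResult",
    "SyntrophyWindow",
    "default_steps",
    "build_ladder",
    "electron_flow_feasible",
    "evaluate_scenario",
    "syntrophy_window",
    "apply_investment_to_ladder",
    "methanogenesis_threshold_pressure",
    "methanogen_reference_potential",
]

_ROLES = {"electron-donating", "electron-accepting", "substrate-level"}


@dataclass(frozen=True)
class EnzymeStep:
    """One enzyme of the network, tied to the half-couple it operates on."""

    label: str
    role: str
    couple: str | None = None   # name in the constants table; None for substrate-level
    atp_step: bool = False

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")


def default_steps() -> tuple[EnzymeStep, ...]:
    """The 13 enzymes of the lactate-oxidation and sulfate pathways.

    LDH lactate dehydrogenase, POR pyruvate-ferredoxin oxidoreductase,
    PTA phosphotransacetylase, ACK acetate kinase (the ATP-generating
    step), FDN formate dehydrogenase, HUP/HYD uptake/release
    hydrogenases, COO the membrane-bound ion-translocating Coo
    hydrogenase, SAT ATP-sulfurylase, APR APS reductase, DSV sulfite
    reductase, ALD alanine dehydrogenase, ADH ethanol dehydrogenase.
    """
    return (
        EnzymeStep("LDH", "electron-donating", "pyruvate/lactate"),
        EnzymeStep("POR", "electron-donating", "acetyl-CoA+CO2/pyruvate"),
        EnzymeStep("PTA", "substrate-level"),
        EnzymeStep("ACK", "substrate-level", atp_step=True),
        EnzymeStep("FDN", "electron-donating", "CO2/formate"),
        EnzymeStep("HUP", "electron-donating", "H+/H2"),
        EnzymeStep("HYD", "electron-accepting", "H+/H2"),
        EnzymeStep("COO", "electron-accepting", "H+/H2"),
        EnzymeStep("SAT", "substrate-level"),
        EnzymeStep("APR", "electron-accepting", "APS/AMP+sulfite"),
        EnzymeStep("DSV", "electron-accepting", "sulfite/HS-"),
        EnzymeStep("ALD", "electron-accepting", "pyruvate+NH4+/alanine"),
        EnzymeStep("ADH", "electron-accepting", "acetaldehyde/ethanol"),
    )


@dataclass(frozen=True)
class LadderEntry:
    label: str
    potential: float  # volts


@dataclass(frozen=True)
class RedoxLadder:
    """Redox-role enzymes ordered by potential, plus the methanogen
    electron-acceptance reference line (volts)."""

    entries: tuple[LadderEntry, ...]
    reference_line: float

    def potential(self, label: str) -> float:
        for e in self.entries:
            if e.label == label:
                return e.potential
        raise KeyError(f"no ladder entry labelled {label!r}")

    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)


def methanogenesis_threshold_pressure(conditions: Conditions | None = None,
                                      table: ThermoTable | None = None,
                                      dg0: float | None = None) -> float:
    """Minimum H₂ partial pressure (Pa) for 4H₂ + CO₂ → CH₄ + 2H₂O to be
    exergonic. Computed from the formation-energy table (≈ −131 kJ mol⁻¹
    at standard state) with CH₄ and CO₂ defaulting to 1 bar."""
    conditions = conditions or Conditions.standard()
    table = table or default_table()
    if dg0 is None:
        dg0 = standard_delta_g(METHANOGENESIS, table)
    return equilibrium_h2_pressure(METHANOGENESIS, dg0, conditions, table)


def methanogen_reference_potential(conditions: Conditions | None = None,
                                   table: ThermoTable | None = None,
                                   constants: ThermoConstants = CONSTANTS) -> float:
    """Potential (V) of the 2H⁺/H₂ couple at the methanogenesis threshold
    pressure: the line at which methanogens are taken to accept electrons
    (≈ −244 mV)."""
    conditions = conditions or Conditions.standard()
    table = table or default_table()
    p_bar = methanogenesis_threshold_pressure(conditions, table) / constants.pascals_per_bar
    at_threshold = conditions.with_activity("H2", p_bar)
    return nernst_potential(table.couple("H+/H2"), at_threshold, table, constants)


def build_ladder(steps: tuple[EnzymeStep, ...] | None = None,
                 conditions: Conditions | None = None,
                 table: ThermoTable | None = None,
                 reference_line: float | None = None) -> RedoxLadder:
    """Place every redox-role step at its Nernst potential under
    ``conditions``. Substrate-level steps carry no rung. Entries are
    sorted by potential, ties broken alphabetically by label."""
    steps = steps if steps is not None else default_steps()
    conditions = conditions or Conditions.standard()
    table = table or default_table()
    entries = []
    for step in steps:
        if step.role == "substrate-level":
            continue
        if step.couple is None:
            raise ValueError(f"redox step {step.label} has no half-couple")
        e = nernst_potential(table.couple(step.couple), conditions, table)
        entries.append(LadderEntry(step.label, e))
    entries.sort(key=lambda le: (le.potential, le.label))
    if reference_line is None:
        reference_line = methanogen_reference_potential(Conditions.standard(conditions.temperature), table)
    return RedoxLadder(tuple(entries), reference_line)


def electron_flow_feasible(donor: LadderEntry | float, acceptor: LadderEntry | float) -> bool:
    """True iff the acceptor potential is strictly more positive than the
    donor's — equality leaves no driving force."""
    e_don = donor.potential if isinstance(donor, LadderEntry) else float(donor)
    e_acc = acceptor.potential if isinstance(acceptor, LadderEntry) else float(acceptor)
    return e_acc > e_don


def apply_investment_to_ladder(ladder: RedoxLadder, investment: IonInvestment) -> RedoxLadder:
    """Redraw the ladder with the COO rung displaced by the invested
    chemiosmotic energy (|E_inv|/nF for the 2-electron H₂ couple).

    The rung is drawn shifted downwards — the energy investment is what
    lets the physically lower-potential proton reduction behave, for
    feasibility purposes, as if its acceptor potential were raised by the
    same magnitude (see :func:`evaluate_scenario`).
    """
    labels = ladder.labels()
    if "COO" not in labels:
        raise ValueError("ladder has no COO entry to shift")
    shift = potential_shift(investment, n_electrons=2)
    entries = [replace(e, potential=e.potential - shift) if e.label == "COO" else e
               for e in ladder.entries]
    entries.sort(key=lambda le: (le.potential, le.label))
    return RedoxLadder(tuple(entries), ladder.reference_line)


_SINKS = ("sulfate", "ethanol", "alanine", "hydrogen-hyd", "hydrogen-coo")


@dataclass(frozen=True)
class PathwayScenario:
    """A choice of terminal electron sink for lactate oxidation."""

    sulfate_present: bool
    electron_sink: str
    investment: IonInvestment | None = None

    def __post_init__(self) -> None:
        if self.electron_sink not in _SINKS:
            raise ValueError(f"unknown electron sink {self.electron_sink!r}; "
                             f"expected one of {_SINKS}")
        if self.electron_sink == "sulfate" and not self.sulfate_present:
            raise ValueError("sulfate sink requires sulfate_present=True")


@dataclass(frozen=True)
class ScenarioResult:
    total_delta_g: float          # kJ per mol lactate, sum over required transfers
    feasible: bool
    atp_generating: bool
    transfers: tuple[tuple[str, str, float], ...] = field(default=())  # (donor, acceptor, ΔE)


def _scenario_transfers(scenario: PathwayScenario) -> tuple[tuple[str, str], ...]:
    """Required donor→acceptor electron transfers, per lactate oxidised.

    The ethanol/alanine sinks re-oxidise the LDH electrons only and
    bypass pyruvate oxidation (hence the ATP-generating POR-PTA-ACK leg);
    the sulfate and hydrogen sinks carry both the LDH and POR electrons.
    """
    sink_acceptors = {
        "sulfate": ("APR", "DSV"),
        "ethanol": ("ADH",),
        "alanine": ("ALD",),
        "hydrogen-hyd": ("HYD",),
        "hydrogen-coo": ("COO",),
    }[scenario.electron_sink]
    donors = ("LDH",) if scenario.electron_sink in ("ethanol", "alanine") else ("LDH", "POR")
    return tuple((d, a) for d in donors for a in sink_acceptors)


def evaluate_scenario(scenario: PathwayScenario,
                      conditions: Conditions | None = None,
                      table: ThermoTable | None = None,
                      constants: ThermoConstants = CONSTANTS) -> ScenarioResult:
    """Judge a sink scenario: every required donor→acceptor coupling must
    pass the electron-flow rule after the investment (if any) raises the
    effective COO acceptor potential. ATP is generated only when the
    pathway traverses POR-PTA-ACK (sulfate and hydrogen sinks)."""
    conditions = conditions or Conditions.physiological()
    table = table or default_table()
    ladder = build_ladder(None, conditions, table)
    shift = 0.0
    if scenario.investment is not None:
        shift = potential_shift(scenario.investment, n_electrons=2, constants=constants)

    feasible = True
    total_dg = 0.0
    transfers = []
    for donor_label, acceptor_label in _scenario_transfers(scenario):
        e_don = ladder.potential(donor_label)
        e_acc = ladder.potential(acceptor_label)
        if acceptor_label == "COO":
            e_acc += shift  # investment relaxes the acceptance condition
        delta_e = e_acc - e_don
        transfers.append((donor_label, acceptor_label, delta_e))
        if not electron_flow_feasible(e_don, e_acc):
            feasible = False
    # energy per lactate: one 2-electron transfer per donor leg, each to its
    # least favourable required acceptor
    for donor_label in {d for d, _ in _scenario_transfers(scenario)}:
        worst = min(de for d, _, de in transfers if d == donor_label)
        total_dg += -2 * constants.faraday * worst / 1000.0
    atp = scenario.electron_sink in ("sulfate", "hydrogen-hyd", "hydrogen-coo") and feasible
    return ScenarioResult(total_dg, feasible, atp, tuple(transfers))


@dataclass(frozen=True)
class SyntrophyWindow:
    """(max H₂ the producer tolerates, min H₂ the methanogen needs), Pa."""

    max_h2_tolerated: float
    min_h2_required: float

    @property
    def overlap(self) -> bool:
        return self.max_h2_tolerated > self.min_h2_required


def syntrophy_window(conditions: Conditions | None = None,
                     investment: IonInvestment | None = None,
                     table: ThermoTable | None = None,
                     dg0_lactate: float | None = None,
                     dg0_methanogenesis: float | None = None) -> SyntrophyWindow:
    """The feasibility window for interspecies hydrogen transfer.

    Producer side: equilibrium H₂ pressure of lactate⁻ → pyruvate⁻ + H₂
    at the given lactate/pyruvate activities, raised by any
    ion-translocation investment. Consumer side: the methanogenesis
    threshold. Syntrophy is possible only when the two ranges overlap.
    """
    conditions = conditions or Conditions.physiological()
    table = table or default_table()
    if dg0_lactate is None:
        dg0_lactate = standard_delta_g(LACTATE_FERMENTATION, table)
    base = equilibrium_h2_pressure(LACTATE_FERMENTATION, dg0_lactate, conditions, table)
    if investment is not None and investment.n_ions > 0 and investment.fold > 1:
        max_h2 = tolerated_pressure_with_investment(
            base, investment, nu_h2=1.0, temperature=conditions.temperature)
    else:
        max_h2 = base
    min_h2 = methanogenesis_threshold_pressure(
        Conditions.standard(conditions.temperature), table, dg0=dg0_methanogenesis)
    return SyntrophyWindow(max_h2, min_h2)
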