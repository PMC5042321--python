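"""Transformed biochemical thermodynamics at pH 7.

Closed-form Gibbs energies, Nernst potentials, equilibrium hydrogen
pressures and chemiosmotic ion-translocation energies for anaerobic
lactate metabolism. All quantities follow the transformed (pH-7)
convention: the proton carries a fixed formation energy of
RT·ln(10⁻⁷) ≈ −39.96 kJ mol⁻¹ and, like water, never appears in a
reaction quotient. Energies are kJ mol⁻¹, potentials volts, pressures
bar internally (helpers convert to Pa for display).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "ThermoConstants",
    "CONSTANTS",
    "Compound",
    "HalfCouple",
    "Reaction",
    "Conditions",
    "IonInvestment",
    "ThermoTable",
    "load_thermo_table",
    "standard_delta_g",
    "delta_g_at_conditions",
    "nernst_potential",
    "couple_halves",
    "equilibrium_h2_pressure",
    "ion_translocation_energy",
    "tolerated_pressure_with_investment",
    "potential_shift",
    "LACTATE_FERMENTATION",
    "METHANOGENESIS",
]


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants (SI except where noted)."""

    gas_constant: float = 8.3145          # J mol⁻¹ K⁻¹
    faraday: float = 96485.0              # C mol⁻¹
    reference_pressure: float = 1.0       # bar
    pascals_per_bar: float = 1.0e5

    def __post_init__(self) -> None:
        for name in ("gas_constant", "faraday", "reference_pressure", "pascals_per_bar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def rt_kj(self, temperature: float) -> float:
        """RT in kJ mol⁻¹ at ``temperature`` (K)."""
        return self.gas_constant * temperature / 1000.0


CONSTANTS = ThermoConstants()

#: phases whose activity is fixed at 1 and excluded from every quotient
_UNIT_ACTIVITY_PHASES = frozenset({"water", "proton"})


@dataclass(frozen=True)
class Compound:
    """A chemical species with its standard transformed formation energy.

    ``delta_gf_prime`` is ΔGf°′ at pH 7, 298.15 K, in kJ mol⁻¹; ``None``
    when no self-consistent tabulated value exists (the species can then
    only appear in couples that store E°′ directly). Gas activities are
    partial pressure / 1 bar, solutes molar concentration / 1 M; water
    and the pH-7 proton have unit activity by convention.
    """

    id: str
    delta_gf_prime: float | None
    phase: str = "solute"
    charge: int = 0

    def __post_init__(self) -> None:
        if self.phase not in {"solute", "gas", "water", "proton"}:
            raise ValueError(f"unknown phase {self.phase!r} for {self.id}")


@dataclass(frozen=True)
class HalfCouple:
    """A reduction half-reaction: oxidized side + n e⁻ → reduced side.

    ``e0_prime`` is the standard transformed potential at pH 7 (volts).
    Side stoichiometries map compound ids to positive coefficients.
    """

    name: str
    oxidized_side: Mapping[str, float]
    reduced_side: Mapping[str, float]
    n_electrons: int
    e0_prime: float

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be ≥ 1")


@dataclass(frozen=True)
class Reaction:
    """A full reaction: compound id → signed stoichiometry ν (products > 0)."""

    name: str
    stoichiometry: Mapping[str, float]

    def charge_balance(self, table: "ThermoTable") -> float:
        """Net charge created by the reaction (0 for a balanced one)."""
        return sum(nu * table.compound(c).charge for c, nu in self.stoichiometry.items())

    def scaled(self, factor: float) -> "Reaction":
        return Reaction(self.name, {c: factor * nu for c, nu in self.stoichiometry.items()})


class Conditions:
    """Temperature and dimensionless activities (pH fixed at 7).

    Solute activities are concentration in M / 1 M, gas activities are
    partial pressure in bar / 1 bar. Unset compounds default to the
    standard state (activity 1). Water and H⁺ are forced to 1.
    """

    def __init__(self, temperature: float = 298.15,
                 activities: Mapping[str, float] | None = None) -> None:
        if temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        acts = dict(activities or {})
        for cid, a in acts.items():
            if a <= 0 or not math.isfinite(a):
                raise ValueError(f"activity of {cid} must be finite and > 0, got {a}")
        acts["H2O"] = 1.0
        acts["H+"] = 1.0
        self.temperature = temperature
        self.activities = acts

    def activity(self, compound_id: str) -> float:
        return self.activities.get(compound_id, 1.0)

    def with_activity(self, compound_id: str, value: float) -> "Conditions":
        acts = dict(self.activities)
        acts[compound_id] = value
        return Conditions(self.temperature, acts)

    @classmethod
    def standard(cls, temperature: float = 298.15) -> "Conditions":
        return cls(temperature)

    @classmethod
    def physiological(cls, temperature: float = 298.15, *,
                      lactate: float = 1e-3, pyruvate: float = 1e-4,
                      h2_bar: float | None = None) -> "Conditions":
        """The realistic concentration set used throughout the model:
        1 mM lactate, 0.1 mM pyruvate; H₂ optional (often the unknown)."""
        acts = {"lactate": lactate, "pyruvate": pyruvate}
        if h2_bar is not None:
            acts["H2"] = h2_bar
        return cls(temperature, acts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Conditions(T={self.temperature} K, activities={self.activities})"


@dataclass(frozen=True)
class IonInvestment:
    """Chemiosmotic energy invested by letting ``n_ions`` singly charged
    ions flow down a membrane concentration gradient, per H₂ produced.

    The gradient is a fold-ratio c_high/c_low, or equivalently ΔpH units
    (fold = 10^ΔpH). The energy term −m·RT·ln(fold) is ≤ 0: it is energy
    *added to* (invested in) the coupled reaction.
    """

    n_ions: float
    fold: float = 1.0
    temperature: float = 298.15
    constants: ThermoConstants = field(default=CONSTANTS, repr=False)

    def __post_init__(self) -> None:
        if self.n_ions < 0:
            raise ValueError("n_ions must be ≥ 0")
        if self.fold < 1:
            raise ValueError("gradient fold must be ≥ 1 (uphill gradients out of scope)")

    @classmethod
    def from_delta_ph(cls, n_ions: float, delta_ph: float,
                      temperature: float = 298.15) -> "IonInvestment":
        if delta_ph < 0:
            raise ValueError("ΔpH must be ≥ 0")
        return cls(n_ions, 10.0 ** delta_ph, temperature)

    @property
    def energy(self) -> float:
        """kJ mol⁻¹, ≤ 0."""
        return ion_translocation_energy(self.n_ions, self.fold, self.temperature,
                                        constants=self.constants)

    @classmethod
    def none(cls) -> "IonInvestment":
        return cls(0.0, 1.0)


# ---------------------------------------------------------------------------
# constants table

class ThermoTable:
    """Embedded compound/couple constants (Thauer-style pH-7 values)."""

    def __init__(self, compounds: Mapping[str, Compound],
                 couples: Mapping[str, HalfCouple]) -> None:
        self.compounds = dict(compounds)
        self.couples = dict(couples)

    def compound(self, cid: str) -> Compound:
        try:
            return self.compounds[cid]
        except KeyError:
            raise KeyError(f"compound {cid!r} not in thermodynamic table") from None

    def couple(self, name: str) -> HalfCouple:
        try:
            return self.couples[name]
        except KeyError:
            raise KeyError(f"half-couple {name!r} not in thermodynamic table") from None

    def couple_e0_from_formation(self, name: str,
                                 constants: ThermoConstants = CONSTANTS) -> float | None:
        """E°′ recomputed from formation energies, or None if any ΔGf°′
        on either side is untabulated. Used by the 1 mV consistency check."""
        cpl = self.couple(name)
        dg = 0.0
        for side, sign in ((cpl.reduced_side, +1.0), (cpl.oxidized_side, -1.0)):
            for cid, coeff in side.items():
                comp = self.compound(cid)
                if comp.delta_gf_prime is None:
                    return None
                dg += sign * coeff * comp.delta_gf_prime
        return -dg * 1000.0 / (cpl.n_electrons * constants.faraday)


def _parse_side(text: str) -> dict[str, float]:
    side: dict[str, float] = {}
    if not text or text != text:  # NaN guard
        return side
    for part in str(text).split(";"):
        cid, coeff = part.split(":")
        side[cid.strip()] = float(coeff)
    return side


def load_thermo_table(path: str | None = None) -> ThermoTable:
    """Load the packaged constants TSV (or a user override of the same shape)."""
    if path is None:
        ref = resources.files("syntherm.data").joinpath("thermo_constants.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    compounds: dict[str, Compound] = {}
    couples: dict[str, HalfCouple] = {}
    for row in df.itertuples(index=False):
        if row.kind == "compound":
            dgf = None if pd.isna(row.value) else float(row.value)
            compounds[row.name] = Compound(row.name, dgf, row.phase, int(row.charge))
        elif row.kind == "couple":
            couples[row.name] = HalfCouple(
                row.name,
                _parse_side(row.oxidized),
                _parse_side(row.reduced),
                int(row.n_electrons),
                float(row.value),
            )
        else:
            raise ValueError(f"unknown record kind {row.kind!r} in constants table")
    return ThermoTable(compounds, couples)


_DEFAULT_TABLE: ThermoTable | None = None


def default_table() -> ThermoTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_thermo_table()
    return _DEFAULT_TABLE


#: lactate⁻ → pyruvate⁻ + H₂ (the fermentative, hydrogen-producing step)
LACTATE_FERMENTATION = Reaction("lactate_fermentation",
                                {"lactate": -1.0, "pyruvate": 1.0, "H2": 1.0})

#: 4 H₂ + CO₂ → CH₄ + 2 H₂O (hydrogenotrophic methanogenesis)
METHANOGENESIS = Reaction("hydrogenotrophic_methanogenesis",
                          {"H2": -4.0, "CO2": -1.0, "CH4": 1.0, "H2O": 2.0})


# ---------------------------------------------------------------------------
# operations

def standard_delta_g(reaction: Reaction, table: ThermoTable | None = None) -> float:
    """ΔG°′ = Σ ν·ΔGf°′ over the reaction, kJ mol⁻¹ (condition independent)."""
    table = table or default_table()
    total = 0.0
    for cid, nu in reaction.stoichiometry.items():
        comp = table.compound(cid)
        if comp.delta_gf_prime is None:
            raise KeyError(f"compound {cid!r} has no tabulated ΔGf°′")
        total += nu * comp.delta_gf_prime
    return total


def _log_quotient(stoich: Mapping[str, float], conditions: Conditions,
                  table: ThermoTable, skip: frozenset[str] = frozenset()) -> float:
    """Σ ν·ln(activity), skipping unit-activity phases and ``skip`` ids."""
    total = 0.0
    for cid, nu in stoich.items():
        if cid in skip:
            continue
        comp = table.compounds.get(cid)
        if comp is not None and comp.phase in _UNIT_ACTIVITY_PHASES:
            continue
        a = conditions.activity(cid)
        if a <= 0:
            raise ValueError(f"non-positive activity for {cid}")
        total += nu * math.log(a)
    return total


def delta_g_at_conditions(reaction: Reaction, dg0: float, conditions: Conditions,
                          table: ThermoTable | None = None,
                          constants: ThermoConstants = CONSTANTS) -> float:
    """ΔG = ΔG°′ + RT·Σ ν·ln(a), kJ mol⁻¹; water and H⁺ excluded."""
    table = table or default_table()
    rt = constants.rt_kj(conditions.temperature)
    return dg0 + rt * _log_quotient(reaction.stoichiometry, conditions, table)


def nernst_potential(couple: HalfCouple, conditions: Conditions,
                     table: ThermoTable | None = None,
                     constants: ThermoConstants = CONSTANTS) -> float:
    """E = E°′ + (RT/nF)·ln(Π a_ox / Π a_red), volts."""
    table = table or default_table()
    rt_j = constants.gas_constant * conditions.temperature
    log_ox = _log_quotient(couple.oxidized_side, conditions, table)
    log_red = _log_quotient(couple.reduced_side, conditions, table)
    return couple.e0_prime + rt_j / (couple.n_electrons * constants.faraday) * (log_ox - log_red)


def couple_halves(donor: HalfCouple, acceptor: HalfCouple, conditions: Conditions,
                  table: ThermoTable | None = None, scale: bool = False,
                  constants: ThermoConstants = CONSTANTS) -> tuple[float, float]:
    """Combine a donor and an acceptor half-couple into the full redox
    reaction and return (ΔE volts, ΔG kJ mol⁻¹).

    ΔE = E_acceptor − E_donor and ΔG = −nFΔE, so electrons flow
    spontaneously (ΔG < 0) exactly when the acceptor sits at the more
    positive potential. Mismatched electron counts raise unless
    ``scale=True``, which applies least-common-multiple scaling (ΔE is
    intensive; ΔG refers to the scaled reaction).
    """
    if donor.n_electrons != acceptor.n_electrons:
        if not scale:
            raise ValueError(
                f"electron counts differ ({donor.n_electrons} vs {acceptor.n_electrons}); "
                "pass scale=True for least-common-multiple scaling")
        n = math.lcm(donor.n_electrons, acceptor.n_electrons)
    else:
        n = donor.n_electrons
    e_don = nernst_potential(donor, conditions, table, constants)
    e_acc = nernst_potential(acceptor, conditions, table, constants)
    delta_e = e_acc - e_don
    delta_g = -n * constants.faraday * delta_e / 1000.0
    return delta_e, delta_g


def equilibrium_h2_pressure(reaction: Reaction, dg0: float, conditions: Conditions,
                            table: ThermoTable | None = None,
                            constants: ThermoConstants = CONSTANTS) -> float:
    """The H₂ partial pressure (Pa) at which the reaction sits at ΔG = 0.

    All non-H₂ activities are taken from ``conditions``; any H₂ activity
    present there is ignored (H₂ is the unknown). For ν_H2 = +1 this is
    the closed form P* = exp(−(ΔG°′ + RT·Σ_other ν ln a)/RT) bar.
    """
    table = table or default_table()
    nu_h2 = reaction.stoichiometry.get("H2", 0.0)
    if nu_h2 == 0:
        raise ValueError(f"reaction {reaction.name!r} has no H2 term")
    rt = constants.rt_kj(conditions.temperature)
    other = _log_quotient(reaction.stoichiometry, conditions, table,
                          skip=frozenset({"H2"}))
    ln_p = -(dg0 + rt * other) / (rt * nu_h2)
    return math.exp(ln_p) * constants.pascals_per_bar


def ion_translocation_energy(m: float, fold: float | None = None,
                             temperature: float = 298.15, *,
                             delta_ph: float | None = None,
                             constants: ThermoConstants = CONSTANTS) -> float:
    """Energy −m·RT·ln(fold) (kJ mol⁻¹, ≤ 0) gained from m singly charged
    ions flowing down a ``fold``-ratio (or 10^ΔpH) membrane gradient."""
    if (fold is None) == (delta_ph is None):
        raise ValueError("give exactly one of fold or delta_ph")
    if delta_ph is not None:
        if delta_ph < 0:
            raise ValueError("ΔpH must be ≥ 0")
        fold = 10.0 ** delta_ph
    assert fold is not None
    if m < 0:
        raise ValueError("ion count must be ≥ 0")
    if fold < 1:
        raise ValueError("gradient fold must be ≥ 1")
    return -m * constants.rt_kj(temperature) * math.log(fold)


def tolerated_pressure_with_investment(base_pressure: float, investment: IonInvestment,
                                       nu_h2: float = 1.0,
                                       temperature: float = 298.15,
                                       constants: ThermoConstants = CONSTANTS) -> float:
    """Shift the equilibrium H₂ pressure (Pa) by the invested energy.

    The producer tolerates base × exp(|E_inv|/(ν_H2·RT)); for ν_H2 = 1
    the factor is exactly 10^(m·ΔpH) — a hundred-fold per ion over a
    2-pH-unit gradient.
    """
    if base_pressure <= 0:
        raise ValueError("base pressure must be > 0")
    rt = constants.rt_kj(temperature)
    return base_pressure * math.exp(abs(investment.energy) / (nu_h2 * rt))


def potential_shift(investment: IonInvestment, n_electrons: int,
                    constants: ThermoConstants = CONSTANTS) -> float:
    """|ΔE| = |E_inv|/(nF) in volts: how far the invested energy moves the
    effective potential of an n-electron acceptor couple."""
    if n_electrons < 1:
        raise ValueError("n_electrons must be ≥ 1")
    return abs(investment.energy) * 1000.0 / (n_electrons * constants.faraday)
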