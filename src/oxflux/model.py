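"""Steady-state oxygen-flux mass balance of small-mammal body water.

The model books every mole of oxygen entering and leaving the animal over
a measurement window (48 or 96 h), attaches to each flux the isotopic
composition of its source pool and any kinetic/equilibrium fractionation,
and solves the steady-state mixing ratio of body water:

    R_bw = Σ_inputs f_i · α_i · R(source_i)  /  Σ_outputs f_j · α_j

separately for ¹⁸O/¹⁶O and ¹⁷O/¹⁶O, where f are fractional contributions
within the input and output pools respectively.  δ¹⁸O_bw, δ¹⁷O_bw and
Δ′¹⁷O_bw follow from the two ratios.

Six inputs: drinking water, food free water, oxidase (metabolic) water
from inhaled O₂, inhaled water vapour, condensation water and
decarboxylation oxygen (both from food-bound oxygen).  Eight outputs:
faecal bound oxygen (zero by assumption), faecal water, transcutaneous
vapour, oral and nasal exhaled vapour, exhaled CO₂, urea-bound oxygen,
and urinary water — the last obtained as the residual that closes the
balance (steady state; the animal neither sweats nor pants).

Unit conventions are fixed package-wide: δ in ‰, Δ′¹⁷O in per meg,
α and θ dimensionless, fractions in [0, 1], temperatures in °C at the
interface (converted to K internally), amounts in moles of oxygen atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .iso import (
    FractionationFactor,
    IDENTITY_FRACTIONATION,
    ReferenceRatios,
    TripleOxygenComposition,
    composition_from_ratios,
    ratios_from_composition,
)

__all__ = [
    "ModelParameters",
    "MeasuredFluxTotals",
    "FluxComponent",
    "BodyWaterPrediction",
    "MassBalanceError",
    "base_model_parameters",
    "base_model_totals",
    "vapour_pressure_deficit",
    "fractionation_factors",
    "input_fluxes",
    "output_fluxes",
    "predict_body_water",
    "run_model",
    "co2_ml_to_mol",
]

# Bookkeeping constants, kept at the precision conventionally used in
# this class of model so that published parameter tables reproduce.
MOL_WATER_PER_KG = 55.56        # mol H2O (= mol O) per kg of water
WATER_G_PER_MOL = 18.0          # g/mol
O_ATOMS_PER_ML_O2 = 5.38e19     # O atoms per ml O2 at STP (2 per molecule)
AVOGADRO = 6.03e23              # atoms per mole, as used with the above
MOLAR_VOLUME_L = 22.4           # l/mol ideal gas at STP
O2_FRACTION_AIR = 0.21          # mole fraction of O2 in dry air
KPA_TO_MMHG = 7.50062
MOL_O_PER_KG_CARB = 11.12       # 2 of 6 glucose oxygens end up in water
ZERO_C_IN_K = 273.15

#: Default triple-isotope exponents per fractionating flux.
DEFAULT_THETAS = {
    "oxidase_water": 0.5179,
    "inhaled_vapour": 0.529,
    "bound_oxygen": 0.525,
    "transcutaneous": 0.5235,
    "oral_vapour": 0.529,
    "nasal_vapour": 0.529,
    "exhaled_co2": 0.5248,
}

INPUT_NAMES = (
    "drinking_water",
    "food_water",
    "oxidase_water",
    "inhaled_vapour",
    "condensation_water",
    "decarboxylation_oxygen",
)
OUTPUT_NAMES = (
    "faecal_bound",
    "faecal_water",
    "transcutaneous",
    "oral_vapour",
    "nasal_vapour",
    "exhaled_co2",
    "urea_oxygen",
    "urinary_water",
)


class MassBalanceError(ValueError):
    """Raised when the urinary residual that closes the balance is negative."""


@dataclass(frozen=True)
class MeasuredFluxTotals:
    """Windowed totals from the metabolic phenotyping system.

    ``water_ml`` is the drinking-water intake already corrected for
    nozzle leakage; ``o2_ml`` and ``co2_ml`` are STP gas volumes.
    """

    o2_ml: float
    co2_ml: float
    food_kg: float
    water_ml: float
    window_hours: float

    def __post_init__(self) -> None:
        for name in ("o2_ml", "co2_ml", "food_kg", "water_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.window_hours > 0:
            raise ValueError("window_hours must be positive")

    @classmethod
    def from_co2_mol(cls, o2_ml: float, co2_mol: float, food_kg: float,
                     water_ml: float, window_hours: float) -> "MeasuredFluxTotals":
        """Accept CO2 in moles (the unit some parameter tables print)."""
        return cls(o2_ml, co2_mol * MOLAR_VOLUME_L * 1000.0,
                   food_kg, water_ml, window_hours)

    @property
    def co2_mol(self) -> float:
        return self.co2_ml / 1000.0 / MOLAR_VOLUME_L

    @property
    def window_days(self) -> float:
        return self.window_hours / 24.0


def co2_ml_to_mol(co2_ml: float) -> float:
    return co2_ml / 1000.0 / MOLAR_VOLUME_L


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set for one model evaluation.

    Defaults are the deer-mouse base configuration (20 g animal at 25 °C,
    45 % relative humidity, standard low-salt rodent chow).  Fractions are
    in [0, 1]; ``ouf`` is the oxygen utilization fraction (O₂ extracted
    per breath); ``z_value_permil`` the empirical ¹⁸O depletion of
    respired O₂ used in the oxidase fractionation; ``meeh_k`` the
    allometric surface-area constant in cm²·kg^(−2/3);
    ``skin_evap_rate`` in mg/cm²/h/mmHg.
    """

    mass_kg: float = 0.02
    window_days: float = 4.0
    body_temp_C: float = 38.0
    ambient_temp_C: float = 25.0
    rel_humidity: float = 0.45
    ouf: float = 0.25
    z_value_permil: float = 10.5
    meeh_k: float = 1100.0
    skin_evap_rate: float = 0.025
    faecal_water_fraction: float = 0.55
    digestibility_D: float = 0.85
    energy_extraction_E: float = 1.0
    food_water_content_WC: float = 0.09
    f_carb: float = 0.672
    f_protein: float = 0.254
    f_fat: float = 0.074
    water_leakage_fraction: float = 0.10
    preformed_water: TripleOxygenComposition = field(
        default_factory=lambda: TripleOxygenComposition.from_cap17(-4.0, 20.0))
    atmospheric_O2: TripleOxygenComposition = field(
        default_factory=lambda: TripleOxygenComposition.from_cap17(24.046, -441.0))
    food_free_water: TripleOxygenComposition = field(
        default_factory=lambda: TripleOxygenComposition.from_cap17(-16.41, 30.0))
    cellulose_d18O_by_ingredient: dict = field(default_factory=lambda: {
        "corn": (26.0, 0.43),
        "wheat": (26.9, 0.37),
        "soybean": (25.9, 0.20),
    })
    theta_set: dict = field(default_factory=lambda: dict(DEFAULT_THETAS))
    alpha18_transcutaneous: float = 0.982
    oral_split: float = 0.50
    nasal_split: float = 0.50
    nasal_retention: float = 0.50
    #: source pool for inhaled vapour: "food_free_water" (ambient vapour,
    #: with which food water equilibrates) or "preformed_water".
    vapour_source: str = "food_free_water"
    #: direct overrides of computed α18 values, keyed by flux name
    #: (used by one-at-a-time sensitivity analysis).
    alpha18_overrides: dict = field(default_factory=dict)
    #: retain the literal Kelvin reading of the saturation-pressure
    #: exponent for inhaled vapour (audit only; physical default is °C).
    saturation_temp_in_kelvin: bool = False
    #: diagnostic mode for one-at-a-time sensitivity sweeps: permit a
    #: negative urinary residual instead of raising.  Because urinary
    #: water does not fractionate, the prediction stays well defined
    #: (redistribution among α = 1 outputs cancels exactly) even when a
    #: single perturbed parameter is jointly inconsistent with the
    #: measured totals.
    allow_negative_urinary: bool = False
    reference_ratios: ReferenceRatios = field(default_factory=ReferenceRatios)

    def __post_init__(self) -> None:
        for name in ("rel_humidity", "faecal_water_fraction",
                     "digestibility_D", "energy_extraction_E",
                     "food_water_content_WC", "f_carb", "f_protein", "f_fat",
                     "oral_split", "nasal_split", "nasal_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if not 0.0 < self.ouf < 1.0:
            raise ValueError(f"ouf = {self.ouf} must lie strictly in (0, 1)")
        if abs(self.oral_split + self.nasal_split - 1.0) > 1e-9:
            raise ValueError("oral_split + nasal_split must equal 1")
        if self.f_carb + self.f_protein + self.f_fat > 1.0 + 1e-9:
            raise ValueError("diet mass fractions exceed 1")
        if not 0.0 <= self.water_leakage_fraction < 1.0:
            raise ValueError("water_leakage_fraction must lie in [0, 1)")
        wsum = sum(w for _, w in self.cellulose_d18O_by_ingredient.values())
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"ingredient weight fractions sum to {wsum}, not 1")
        if self.vapour_source not in ("food_free_water", "preformed_water"):
            raise ValueError(f"unknown vapour_source {self.vapour_source!r}")

    def source_composition(self, key: str) -> TripleOxygenComposition:
        return {
            "preformed_water": self.preformed_water,
            "atmospheric_O2": self.atmospheric_O2,
            "food_free_water": self.food_free_water,
        }[key]


@dataclass(frozen=True)
class FluxComponent:
    """One named oxygen flux: moles of O atoms plus its fractionation.

    Inputs carry the key of the source pool they draw on; outputs draw
    on body water and carry no source.
    """

    name: str
    role: str                    # "input" | "output"
    moles_O: float
    frac_factor: FractionationFactor
    source: str | None = None

    def __post_init__(self) -> None:
        # urinary water may carry a negative residual in diagnostic mode
        if self.moles_O < -1e-12 and self.name != "urinary_water":
            raise ValueError(f"{self.name}: moles_O must be non-negative")
        if self.role == "input" and self.source is None:
            raise ValueError(f"input flux {self.name} needs a source pool")


@dataclass(frozen=True)
class BodyWaterPrediction:
    d18O_bw: float
    d17O_bw: float
    cap17O_bw: float
    input_fractions: dict
    output_fractions: dict
    urinary_moles: float


def base_model_parameters(**overrides) -> ModelParameters:
    """The deer-mouse base parameter set (25 °C, low-salt diet, 96 h)."""
    return replace(ModelParameters(), **overrides) if overrides else ModelParameters()


def base_model_totals() -> MeasuredFluxTotals:
    """Measured flux totals of the base model (96 h window)."""
    return MeasuredFluxTotals.from_co2_mol(
        o2_ml=5582.0, co2_mol=0.21417, food_kg=0.01297,
        water_ml=10.44, window_hours=96.0)


# --- fractionation machinery -------------------------------------------------

def _saturation_vp_mmhg(temp_C: float, in_kelvin: bool = False) -> float:
    """Saturation vapour pressure, mmHg, from the 10^(0.686 + 0.027·T) form.

    The empirical exponent only yields physical pressures with T in °C
    (≈ 23 mmHg at 25 °C); the Kelvin reading is retained behind a flag
    for auditing parameter files that quote it that way.
    """
    t = temp_C + ZERO_C_IN_K if in_kelvin else temp_C
    return 10.0 ** (0.686 + 0.027 * t)


def _liquid_vapour_alpha18(temp_K: float) -> float:
    """Equilibrium liquid–vapour ¹⁸/¹⁶α (>1) at temp_K."""
    return math.exp(
        (11.36e5 / temp_K**2 - 4.2e2 / temp_K - 2.07) / 1000.0)


def vapour_pressure_deficit(ambient_temp_C: float,
                            rel_humidity: float) -> tuple[float, float]:
    """Vapour pressure deficit as (kPa, mmHg), Tetens saturation form."""
    if not 0.0 <= rel_humidity <= 1.0:
        raise ValueError("rel_humidity must lie in [0, 1]")
    svp_kpa = 610.78 * math.exp(
        ambient_temp_C / (ambient_temp_C + 237.3) * 17.2694) / 1000.0
    vpd_kpa = svp_kpa * (1.0 - rel_humidity)
    return vpd_kpa, vpd_kpa * KPA_TO_MMHG


def _weighted_bound_oxygen_alpha(params: ModelParameters) -> FractionationFactor:
    """Ingredient-weighted cellulose/pre-formed-water fractionation.

    Per ingredient α18 = (1000 + δ¹⁸O_cellulose)/(1000 + δ¹⁸O_preformed);
    α17 follows per ingredient via θ before mass-weighted averaging, so
    the pair is the weighted mean of per-ingredient factors.
    """
    theta = params.theta_set["bound_oxygen"]
    pre = params.preformed_water.d18O
    a18 = a17 = 0.0
    for d18_cell, w in params.cellulose_d18O_by_ingredient.values():
        a = (1000.0 + d18_cell) / (1000.0 + pre)
        a18 += w * a
        a17 += w * FractionationFactor(a, theta).alpha17

    # Package the weighted pair: report the effective theta that maps
    # the weighted alpha18 onto the weighted alpha17.
    eff_theta = math.log(a17) / math.log(a18) if a18 != 1.0 else theta
    return FractionationFactor(a18, eff_theta)


def fractionation_factors(params: ModelParameters) -> dict:
    """α18/θ (hence α17) for every fractionating flux.

    Non-fractionating fluxes (drinking water, food water, faecal water,
    urea, urinary water) get the identity factor.  Entries in
    ``params.alpha18_overrides`` replace the computed α18 while keeping
    the flux's θ.
    """
    th = params.theta_set
    Tb = params.body_temp_C + ZERO_C_IN_K
    Ta = params.ambient_temp_C + ZERO_C_IN_K
    Tmean = (Tb + Ta) / 2.0

    d18_air = params.atmospheric_O2.d18O
    oxidase_a18 = (
        (1000.0 + (d18_air - params.z_value_permil) / (1.0 - params.ouf))
        / (1000.0 + d18_air))

    factors = {
        "oxidase_water": FractionationFactor(oxidase_a18, th["oxidase_water"]),
        "inhaled_vapour": FractionationFactor(
            _liquid_vapour_alpha18(Ta), th["inhaled_vapour"]),
        "bound_oxygen": _weighted_bound_oxygen_alpha(params),
        "transcutaneous": FractionationFactor(
            params.alpha18_transcutaneous, th["transcutaneous"]),
        "oral_vapour": FractionationFactor(
            1.0 / _liquid_vapour_alpha18(Tb), th["oral_vapour"]),
        "nasal_vapour": FractionationFactor(
            1.0 / _liquid_vapour_alpha18(Tmean), th["nasal_vapour"]),
        "exhaled_co2": FractionationFactor(
            math.exp((1.66e4 / Tb - 15.69) / 1000.0), th["exhaled_co2"]),
    }
    for name, a18 in params.alpha18_overrides.items():
        if name not in factors:
            raise KeyError(f"no fractionating flux named {name!r}")
        factors[name] = FractionationFactor(a18, factors[name].theta)
    return factors


# --- fluxes ------------------------------------------------------------------

def _lung_air_litres(params: ModelParameters, totals: MeasuredFluxTotals) -> float:
    """Litres of air fluxed through the lungs over the window."""
    mol_o2 = totals.o2_ml / (MOLAR_VOLUME_L * 1000.0)
    return mol_o2 / params.ouf / O2_FRACTION_AIR * MOLAR_VOLUME_L


def input_fluxes(params: ModelParameters,
                 totals: MeasuredFluxTotals) -> list[FluxComponent]:
    """The six oxygen inputs over the measurement window."""
    ff = fractionation_factors(params)
    ident = IDENTITY_FRACTIONATION

    drinking = totals.water_ml / WATER_G_PER_MOL

    food_water = (totals.food_kg * MOL_WATER_PER_KG
                  / (1.0 - params.food_water_content_WC)
                  * params.food_water_content_WC)

    oxidase = totals.o2_ml * O_ATOMS_PER_ML_O2 / AVOGADRO

    lair = _lung_air_litres(params, totals)
    psat = _saturation_vp_mmhg(params.ambient_temp_C,
                               params.saturation_temp_in_kelvin)
    inhaled = (params.rel_humidity * psat / 760.0 * lair / MOLAR_VOLUME_L)

    assimilated = (totals.food_kg * params.digestibility_D
                   * params.energy_extraction_E)
    condensation = assimilated * params.f_carb * MOL_O_PER_KG_CARB
    decarboxylation = assimilated * (
        params.f_carb * 2.0 * MOL_O_PER_KG_CARB
        + params.f_fat * 4.0 + params.f_protein * 6.0)

    return [
        FluxComponent("drinking_water", "input", drinking, ident,
                      "preformed_water"),
        FluxComponent("food_water", "input", food_water, ident,
                      "food_free_water"),
        FluxComponent("oxidase_water", "input", oxidase,
                      ff["oxidase_water"], "atmospheric_O2"),
        FluxComponent("inhaled_vapour", "input", inhaled,
                      ff["inhaled_vapour"], params.vapour_source),
        FluxComponent("condensation_water", "input", condensation,
                      ff["bound_oxygen"], "preformed_water"),
        FluxComponent("decarboxylation_oxygen", "input", decarboxylation,
                      ff["bound_oxygen"], "preformed_water"),
    ]


def output_fluxes(params: ModelParameters, totals: MeasuredFluxTotals,
                  total_input_moles: float) -> list[FluxComponent]:
    """The eight oxygen outputs; urinary water closes the balance."""
    ff = fractionation_factors(params)
    ident = IDENTITY_FRACTIONATION

    faecal_bound = 0.0  # dry faeces is undigested food: no exchange

    dry_faeces_kg = totals.food_kg * (1.0 - params.digestibility_D)
    faecal_water = (dry_faeces_kg / (1.0 - params.faecal_water_fraction)
                    * params.faecal_water_fraction * MOL_WATER_PER_KG)

    _, vpd_mmhg = vapour_pressure_deficit(params.ambient_temp_C,
                                          params.rel_humidity)
    transcut = (params.window_days * params.mass_kg ** (2.0 / 3.0)
                * (params.meeh_k * vpd_mmhg * params.skin_evap_rate / 1000.0)
                * 24.0 / WATER_G_PER_MOL)

    lair = _lung_air_litres(params, totals)
    exhaled_pool = (lair * _saturation_vp_mmhg(params.body_temp_C)
                    / 760.0 / MOLAR_VOLUME_L)
    oral = params.oral_split * exhaled_pool
    nasal = (params.nasal_split * (1.0 - params.nasal_retention)
             * exhaled_pool)

    co2_oxygen = totals.co2_mol * 2.0

    urea = 12.0 * totals.food_kg * params.f_protein \
        * params.digestibility_D * params.energy_extraction_E

    others = (faecal_bound + faecal_water + transcut + oral + nasal
              + co2_oxygen + urea)
    urinary = total_input_moles - others
    if urinary < 0 and not params.allow_negative_urinary:
        raise MassBalanceError(
            f"urinary residual is negative: inputs {total_input_moles:.5f} mol "
            f"< non-urinary outputs {others:.5f} mol "
            f"(faecal_water {faecal_water:.5f}, transcutaneous {transcut:.5f}, "
            f"oral {oral:.5f}, nasal {nasal:.5f}, co2 {co2_oxygen:.5f}, "
            f"urea {urea:.5f})")

    return [
        FluxComponent("faecal_bound", "output", faecal_bound, ident),
        FluxComponent("faecal_water", "output", faecal_water, ident),
        FluxComponent("transcutaneous", "output", transcut,
                      ff["transcutaneous"]),
        FluxComponent("oral_vapour", "output", oral, ff["oral_vapour"]),
        FluxComponent("nasal_vapour", "output", nasal, ff["nasal_vapour"]),
        FluxComponent("exhaled_co2", "output", co2_oxygen, ff["exhaled_co2"]),
        FluxComponent("urea_oxygen", "output", urea, ident),
        FluxComponent("urinary_water", "output", urinary, ident),
    ]


def predict_body_water(inputs: list[FluxComponent],
                       outputs: list[FluxComponent],
                       params: ModelParameters) -> BodyWaterPrediction:
    """Solve the steady-state mixing balance for body-water isotopes."""
    tin = sum(c.moles_O for c in inputs)
    tout = sum(c.moles_O for c in outputs)
    if tin <= 0:
        raise ValueError("total input moles must be positive")
    if abs(tin - tout) > 1e-9 * max(tin, tout):
        raise MassBalanceError(
            f"inputs ({tin}) and outputs ({tout}) are not closed")

    ref = params.reference_ratios
    num18 = num17 = 0.0
    for c in inputs:
        r18, r17 = ratios_from_composition(
            params.source_composition(c.source), ref)
        f = c.moles_O / tin
        num18 += f * c.frac_factor.alpha18 * r18
        num17 += f * c.frac_factor.alpha17 * r17

    den18 = den17 = 0.0
    for c in outputs:
        f = c.moles_O / tout
        den18 += f * c.frac_factor.alpha18
        den17 += f * c.frac_factor.alpha17

    bw = composition_from_ratios(num18 / den18, num17 / den17, ref)
    urinary = next(c.moles_O for c in outputs if c.name == "urinary_water")
    return BodyWaterPrediction(
        d18O_bw=bw.d18O,
        d17O_bw=bw.d17O,
        cap17O_bw=bw.cap17O,
        input_fractions={c.name: c.moles_O / tin for c in inputs},
        output_fractions={c.name: c.moles_O / tout for c in outputs},
        urinary_moles=urinary,
    )


def run_model(params: ModelParameters,
              totals: MeasuredFluxTotals) -> BodyWaterPrediction:
    """Chain input fluxes → fractionation → output fluxes → prediction."""
    inputs = input_fluxes(params, totals)
    total_in = sum(c.moles_O for c in inputs)
    outputs = output_fluxes(params, totals, total_in)
    return predict_body_water(inputs, outputs, params)
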