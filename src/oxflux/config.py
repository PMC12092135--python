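"""Treatment configurations and parameter-file (de)serialization.

The packaged ``treatments.yaml`` carries the four housing-temperature ×
dietary-salt treatment cells of the captive deer-mouse design — group
mean ± SD metabolic rates, window lengths (96 h for the low-salt diet,
48 h for the high-salt diet, matching body-water turnover) and the diet
compositions — so treatment-level models and the synthetic-data
generator share one source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import yaml

from .model import MeasuredFluxTotals, ModelParameters
from .iso import TripleOxygenComposition

__all__ = ["TreatmentSpec", "load_treatments", "params_to_dict",
           "params_from_dict"]


@dataclass(frozen=True)
class TreatmentSpec:
    """One treatment cell: environment, diet, window and metabolic means."""

    label: str
    diet: str
    ambient_temp_C: float
    rel_humidity: float
    window_hours: float
    food_d18O: float
    n_mice: int
    o2_ml_min: tuple[float, float]       # (mean, SD)
    rq: tuple[float, float]
    food_g_day: tuple[float, float]
    water_ml_day: tuple[float, float]
    body_mass_g: tuple[float, float]
    f_carb: float = 0.672
    f_protein: float = 0.254
    f_fat: float = 0.074
    ingredients: dict | None = None

    def model_parameters(self, mass_g: float | None = None,
                         **overrides) -> ModelParameters:
        """ModelParameters for this treatment (optionally per-mouse mass)."""
        mass = (mass_g if mass_g is not None else self.body_mass_g[0]) / 1000.0
        base = ModelParameters(
            mass_kg=mass,
            window_days=self.window_hours / 24.0,
            ambient_temp_C=self.ambient_temp_C,
            rel_humidity=self.rel_humidity,
            f_carb=self.f_carb,
            f_protein=self.f_protein,
            f_fat=self.f_fat,
            food_free_water=TripleOxygenComposition.from_cap17(
                self.food_d18O, 30.0),
            cellulose_d18O_by_ingredient=(
                {k: tuple(v) for k, v in self.ingredients.items()}
                if self.ingredients else
                ModelParameters().cellulose_d18O_by_ingredient),
        )
        return replace(base, **overrides) if overrides else base

    def mean_totals(self) -> MeasuredFluxTotals:
        """Window totals implied by the group-mean rates."""
        hours = self.window_hours
        days = hours / 24.0
        o2 = self.o2_ml_min[0] * 60.0 * hours
        return MeasuredFluxTotals(
            o2_ml=o2,
            co2_ml=o2 * self.rq[0],
            food_kg=self.food_g_day[0] * days / 1000.0,
            water_ml=self.water_ml_day[0] * days,
            window_hours=hours,
        )


def _load_yaml() -> dict:
    ref = resources.files("oxflux.data") / "treatments.yaml"
    with resources.as_file(ref) as path:
        with open(path) as fh:
            return yaml.safe_load(fh)


def load_treatments(path: str | None = None) -> dict[str, TreatmentSpec]:
    """Load treatment cells from ``path`` or the packaged defaults."""
    if path is None:
        raw = _load_yaml()
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    diets = raw.get("diets", {})
    out: dict[str, TreatmentSpec] = {}
    for label, cell in raw["treatments"].items():
        diet = diets.get(cell["diet"], {})
        out[label] = TreatmentSpec(
            label=label,
            diet=cell["diet"],
            ambient_temp_C=float(cell["ambient_temp_C"]),
            rel_humidity=float(cell["rel_humidity"]),
            window_hours=float(cell["window_hours"]),
            food_d18O=float(cell["food_d18O"]),
            n_mice=int(cell["n_mice"]),
            o2_ml_min=tuple(cell["o2_ml_min"]),
            rq=tuple(cell["rq"]),
            food_g_day=tuple(cell["food_g_day"]),
            water_ml_day=tuple(cell["water_ml_day"]),
            body_mass_g=tuple(cell["body_mass_g"]),
            f_carb=float(diet.get("f_carb", 0.672)),
            f_protein=float(diet.get("f_protein", 0.254)),
            f_fat=float(diet.get("f_fat", 0.074)),
            ingredients=diet.get("ingredients"),
        )
    return out


_COMPOSITION_FIELDS = ("preformed_water", "atmospheric_O2", "food_free_water")


def params_to_dict(params: ModelParameters) -> dict:
    """Plain-dict form of ModelParameters for YAML/JSON round-tripping."""
    out: dict = {}
    for name in params.__dataclass_fields__:
        value = getattr(params, name)
        if name in _COMPOSITION_FIELDS:
            out[name] = {"d18O_permil": value.d18O,
                         "cap17O_permeg": value.cap17O}
        elif name == "reference_ratios":
            out[name] = {"r18_vsmow": value.r18_vsmow,
                         "r17_vsmow": value.r17_vsmow}
        elif name == "cellulose_d18O_by_ingredient":
            out[name] = {k: list(v) for k, v in value.items()}
        elif name == "theta_set" or name == "alpha18_overrides":
            out[name] = dict(value)
        else:
            out[name] = value
    return out


def params_from_dict(data: dict) -> ModelParameters:
    """Inverse of :func:`params_to_dict`; unknown keys are rejected."""
    from .iso import ReferenceRatios

    kwargs = dict(data)
    for name in _COMPOSITION_FIELDS:
        if name in kwargs and isinstance(kwargs[name], dict):
            d = kwargs[name]
            kwargs[name] = TripleOxygenComposition.from_cap17(
                d["d18O_permil"], d["cap17O_permeg"])
    if "reference_ratios" in kwargs and isinstance(
            kwargs["reference_ratios"], dict):
        kwargs["reference_ratios"] = ReferenceRatios(
            **kwargs["reference_ratios"])
    if "cellulose_d18O_by_ingredient" in kwargs:
        kwargs["cellulose_d18O_by_ingredient"] = {
            k: tuple(v) for k, v in
            kwargs["cellulose_d18O_by_ingredient"].items()}
    return ModelParameters(**kwargs)
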