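"""Synthetic metabolic-phenotyping and isotope-run data with known truth.

The generator emulates the captive deer-mouse study design so every
pipeline stage is testable without real data:

* per-cage 5-min gas-exchange traces — first-order autoregressive noise
  around a per-mouse daily mean drawn from the treatment group's
  mean ± SD, with a mild sinusoidal diel cycle (nocturnal peak);
* hopper mass traces — monotone downward step functions at Poisson
  event times with lognormal event sizes scaled to the daily total;
* the QC pathologies of real deployments, injected at known locations:
  sensor gaps (short, fillable and long), a 10 % drinker-leakage bias
  (hopper steps overstate intake), and rare gross spill/caching days;
* "measured" body-water isotope values — the flux model's prediction
  for each mouse's true totals plus correlated measurement noise
  (σ(δ¹⁸O) = 0.1 ‰ with σ(Δ′¹⁷O) = 8 per meg, inside the replicate
  precision of the distillation workflow);
* analyzer runs — injections of standards, controls and samples with a
  known stretching/offset and Gaussian injection noise.

All randomness flows from a single integer seed; regeneration is
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TreatmentSpec, load_treatments
from .iso import TripleOxygenComposition, d17O_from_cap
from .model import MeasuredFluxTotals, run_model
from .runcorr import StandardDefinition

__all__ = [
    "PathologyConfig",
    "GroundTruth",
    "simulate_phenotyping",
    "simulate_body_water",
    "simulate_analysis_run",
    "default_standards",
    "default_controls",
]

CADENCE_MIN = 5
SLOTS_PER_DAY = 24 * 60 // CADENCE_MIN


@dataclass(frozen=True)
class PathologyConfig:
    """Rates/magnitudes of injected data pathologies."""

    leakage_fraction: float = 0.10       # hopper steps = intake/(1−leak)
    n_short_gaps: int = 1                # 35–60 min, fillable from 3 h
    n_long_gaps: int = 1                 # 61–335 min, fillable from 24 h
    n_tiny_gaps: int = 1                 # <35 min, left missing
    spill_probability: float = 0.0       # per mouse-day: ~25 ml water day
    caching_probability: float = 0.0     # per mouse-day: ~30 g food day
    spill_ml: float = 25.0
    caching_g: float = 30.0


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    treatment: str
    seed: int
    mice: pd.DataFrame            # per-mouse true daily means and mass
    daily: pd.DataFrame           # per mouse-day true water/food
    window_totals: dict           # cage_id -> MeasuredFluxTotals (true)
    pathologies: pd.DataFrame     # injected gap/spill/caching events
    body_water: pd.DataFrame | None = None   # filled by simulate_body_water
    run_correction: dict = field(default_factory=dict)


def _diel_ar1(rng: np.random.Generator, mean: float, n_slots: int,
              diel_amplitude: float = 0.2, phi: float = 0.9,
              noise_sd_frac: float = 0.05) -> np.ndarray:
    """Mean-reverting gas-rate trace with a diel cycle, clipped at 0."""
    t = np.arange(n_slots) * CADENCE_MIN / 60.0      # hours
    diel = 1.0 + diel_amplitude * np.sin(2 * np.pi * (t - 18.0) / 24.0)
    eps = rng.normal(0.0, noise_sd_frac * mean, n_slots)
    ar = np.empty(n_slots)
    acc = 0.0
    for i in range(n_slots):
        acc = phi * acc + eps[i]
        ar[i] = acc
    return np.clip(mean * diel + ar, 0.0, None)


def _hopper_trace(rng: np.random.Generator, times: pd.DatetimeIndex,
                  daily_amounts: dict, start_mass: float,
                  events_per_day: float) -> np.ndarray:
    """Monotone hopper-mass trace from Poisson events, lognormal sizes."""
    mass = np.full(len(times), start_mass)
    t0 = times[0].normalize()
    drop = np.zeros(len(times))
    for day, amount in daily_amounts.items():
        if amount <= 0:
            continue
        n_events = max(1, rng.poisson(events_per_day))
        offsets = np.sort(rng.uniform(0, 24 * 60, n_events))
        sizes = rng.lognormal(0.0, 0.5, n_events)
        sizes *= amount / sizes.sum()
        day_start = t0 + pd.Timedelta(days=day)
        for off, size in zip(offsets, sizes):
            idx = np.searchsorted(times, day_start + pd.Timedelta(minutes=off))
            if idx < len(times):
                drop[idx:] += size
    return mass - drop


def _inject_gaps(rng: np.random.Generator, grp: pd.DataFrame,
                 cfg: PathologyConfig, events: list, cage: str,
                 n_days: float) -> pd.DataFrame:
    """Drop contiguous slots; gaps are placed after the first day so the
    3 h/24 h lookbacks exist, and before the final day so windows that
    end at the trace end stay coverable after filling."""
    spans = ([("short", rng.integers(40, 61)) for _ in range(cfg.n_short_gaps)]
             + [("long", rng.integers(65, 336)) for _ in range(cfg.n_long_gaps)]
             + [("tiny", rng.integers(10, 31)) for _ in range(cfg.n_tiny_gaps)])
    keep = np.ones(len(grp), dtype=bool)
    for kind, minutes in spans:
        n_slots = int(minutes) // CADENCE_MIN
        lo = SLOTS_PER_DAY
        hi = len(grp) - n_slots - 2
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        keep[start + 1:start + n_slots] = False
        events.append({"cage_id": cage, "kind": f"gap_{kind}",
                       "start": grp["timestamp"].iloc[start + 1],
                       "minutes": int(minutes)})
    return grp[keep]


def simulate_phenotyping(
    treatment: str | TreatmentSpec = "lowsalt_25C",
    n_days: int = 6,
    n_mice: int | None = None,
    seed: int = 0,
    pathologies: PathologyConfig = PathologyConfig(),
    diel_amplitude: float = 0.2,
    gas_noise_frac: float = 0.05,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cohort's phenotyping series plus its ground truth."""
    spec = (treatment if isinstance(treatment, TreatmentSpec)
            else load_treatments()[treatment])
    rng = np.random.default_rng(seed)
    n = n_mice if n_mice is not None else spec.n_mice
    n_slots = n_days * SLOTS_PER_DAY
    t0 = pd.Timestamp("2023-06-01")
    times = pd.date_range(t0, periods=n_slots, freq=f"{CADENCE_MIN}min")

    def draw(ms: tuple[float, float], floor: float) -> float:
        return max(floor, rng.normal(*ms))

    mice_rows, frames, daily_rows, events = [], [], [], []
    totals = {}
    for i in range(n):
        cage = f"cage{i + 1:02d}"
        o2 = draw(spec.o2_ml_min, 0.2)
        rq = min(1.0, max(0.7, rng.normal(*spec.rq)))
        mass = draw(spec.body_mass_g, 14.0)
        water_days, food_days = {}, {}
        spill_days, caching_days = set(), set()
        for day in range(n_days):
            water = draw(spec.water_ml_day, 0.3)
            food = draw(spec.food_g_day, 0.5)
            spill = rng.random() < pathologies.spill_probability
            caching = rng.random() < pathologies.caching_probability
            water_days[day] = water
            food_days[day] = food
            if spill:
                spill_days.add(day)
            if caching:
                caching_days.add(day)
            daily_rows.append({
                "cage_id": cage, "day": day,
                "date": (t0 + pd.Timedelta(days=day)),
                "water_ml": water, "food_g": food,
                "spill": spill, "caching": caching,
            })
            if spill:
                events.append({"cage_id": cage, "kind": "spill",
                               "start": t0 + pd.Timedelta(days=day),
                               "minutes": 0})
            if caching:
                events.append({"cage_id": cage, "kind": "caching",
                               "start": t0 + pd.Timedelta(days=day),
                               "minutes": 0})

        o2_trace = _diel_ar1(rng, o2, n_slots, diel_amplitude,
                             noise_sd_frac=gas_noise_frac)
        co2_trace = o2_trace * rq

        # hopper steps overstate drinking by the leakage factor; gross
        # spill/caching artefacts add on top of the true consumption
        leak = 1.0 / (1.0 - pathologies.leakage_fraction)
        water_recorded = {
            d: w * leak + (pathologies.spill_ml if d in spill_days else 0.0)
            for d, w in water_days.items()}
        food_recorded = {
            d: f + (pathologies.caching_g if d in caching_days else 0.0)
            for d, f in food_days.items()}
        water_trace = _hopper_trace(rng, times, water_recorded, 150.0, 30.0)
        food_trace = _hopper_trace(rng, times, food_recorded, 200.0, 12.0)

        grp = pd.DataFrame({
            "timestamp": times, "cage_id": cage,
            "o2_ml_min": o2_trace, "co2_ml_min": co2_trace,
            "water_g": water_trace, "food_g": food_trace,
            "body_mass_g": mass,
        })

        # true window totals for the treatment's window, ending at trace
        # end (clamped to the simulated span for short simulations)
        hours = min(spec.window_hours, n_days * 24.0)
        win_slots = int(hours * 60 // CADENCE_MIN)
        days_in = int(hours // 24)
        totals[cage] = MeasuredFluxTotals(
            o2_ml=float(o2_trace[-win_slots:].sum()) * CADENCE_MIN,
            co2_ml=float(co2_trace[-win_slots:].sum()) * CADENCE_MIN,
            food_kg=sum(food_days[d] for d in range(n_days - days_in, n_days))
            / 1000.0,
            water_ml=sum(water_days[d]
                         for d in range(n_days - days_in, n_days)),
            window_hours=hours,
        )

        grp = _inject_gaps(rng, grp, pathologies, events, cage, n_days)
        frames.append(grp)
        mice_rows.append({"cage_id": cage, "o2_ml_min": o2, "rq": rq,
                          "body_mass_g": mass})

    series = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        treatment=spec.label, seed=seed,
        mice=pd.DataFrame(mice_rows),
        daily=pd.DataFrame(daily_rows),
        window_totals=totals,
        pathologies=pd.DataFrame(events,
                                 columns=["cage_id", "kind", "start",
                                          "minutes"]),
    )
    return series, truth


def simulate_body_water(
    spec: TreatmentSpec,
    truth: GroundTruth,
    seed: int = 0,
    noise_d18O: float = 0.1,
    noise_cap17O: float = 8.0,
) -> pd.DataFrame:
    """True and noisy "measured" body-water compositions per mouse.

    Truth is the flux model run on each mouse's true window totals with
    its own body mass.  Measurement noise is applied as independent
    Gaussians on δ¹⁸O (‰) and on Δ′¹⁷O (per meg); δ¹⁷O then follows, so
    the δ noise is strongly correlated between the two isotopes — the
    realistic structure for a dual-isotope analyzer, where Δ′¹⁷O noise
    is far smaller than independent δ noise would imply.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, mouse in truth.mice.iterrows():
        cage = mouse["cage_id"]
        params = spec.model_parameters(mass_g=mouse["body_mass_g"])
        pred = run_model(params, truth.window_totals[cage])
        d18_meas = pred.d18O_bw + rng.normal(0.0, noise_d18O)
        cap_meas = pred.cap17O_bw + rng.normal(0.0, noise_cap17O)
        rows.append({
            "cage_id": cage,
            "true_d18O": pred.d18O_bw, "true_d17O": pred.d17O_bw,
            "true_cap17O": pred.cap17O_bw,
            "meas_d18O": d18_meas,
            "meas_d17O": d17O_from_cap(d18_meas, cap_meas),
            "meas_cap17O": cap_meas,
        })
    df = pd.DataFrame(rows)
    truth.body_water = df
    return df


def default_standards() -> dict[str, StandardDefinition]:
    """Bracketing reference waters (synthetic stand-ins for the USGS50/
    USGS47 pair: one enriched, one strongly depleted)."""
    return {
        "USGS50": StandardDefinition(
            "USGS50", d17O_from_cap(4.95, 5.0), 4.95, 32.8),
        "USGS47": StandardDefinition(
            "USGS47", d17O_from_cap(-19.80, 40.0), -19.80, -150.2),
    }


def default_controls() -> dict[str, StandardDefinition]:
    """Five control waters spanning the sample δ¹⁸O range (synthetic)."""
    out = {}
    for i, (d18, cap) in enumerate(
            [(-15.0, 25.0), (-10.0, 30.0), (-6.0, 15.0),
             (-2.0, 0.0), (2.0, -20.0)], start=1):
        name = f"CTRL{i}"
        out[name] = StandardDefinition(name, d17O_from_cap(d18, cap), d18,
                                       8 * d18 + 10)
    return out


def simulate_analysis_run(
    sample_compositions: dict[str, TripleOxygenComposition],
    stretch: dict | float = 1.0,
    offset: dict | float = 0.0,
    noise_d18O: float = 0.0,
    noise_correlation: float = 0.9,
    seed: int = 0,
    run_id: str = "run01",
    standards: dict[str, StandardDefinition] | None = None,
    controls: dict[str, StandardDefinition] | None = None,
    n_injections: tuple[int, int] = (5, 11),
    n_replicates: int = 1,
    n_failing_controls: int = 0,
    control_fault_permil: float = 1.0,
    outlier_injections: int = 0,
) -> pd.DataFrame:
    """Emit an injection table whose correction/truth is known exactly.

    ``raw = (true − offset)/stretch + noise`` per isotope, so fitting
    the correction recovers (stretch, offset).  Optionally plant
    failing controls (true value shifted by ``control_fault_permil`` in
    δ¹⁸O) and isolated outlier injections (+10 SD)."""
    rng = np.random.default_rng(seed)
    standards = standards if standards is not None else default_standards()
    controls = controls if controls is not None else default_controls()
    if len(standards) < 2:
        raise ValueError("need two reference waters")
    if len(controls) < 5:
        raise ValueError("need at least five control waters")

    def _per_iso(value, iso):
        return value[iso] if isinstance(value, dict) else value

    # δ17O noise rides on the δ18O noise with the stated correlation and
    # a mass-dependent amplitude (0.528·σ18), so per-injection Δ′¹⁷O
    # noise ≈ 528·σ18·sqrt(2(1−ρ)) per meg — small, as on a real analyzer
    rho = noise_correlation
    sd17 = 0.528 * noise_d18O
    rows = []
    faulted = set(list(controls)[:n_failing_controls])

    def emit(water_id, role, comp: dict, replicate_id):
        n_inj = int(rng.integers(n_injections[0], n_injections[1] + 1))
        for j in range(n_inj):
            row = {"run_id": run_id, "water_id": water_id,
                   "water_role": role, "replicate_id": replicate_id}
            z1, z2, z3 = rng.normal(size=3)
            noise = {
                "d18O": noise_d18O * z1,
                "d17O": sd17 * (rho * z1 + math.sqrt(1 - rho**2) * z2),
                "d2H": 8.0 * noise_d18O * z3,
            }
            for iso in ("d17O", "d18O", "d2H"):
                true = comp.get(iso)
                if true is None:
                    row[f"raw_{iso}"] = np.nan
                    continue
                raw = ((true - _per_iso(offset, iso))
                       / _per_iso(stretch, iso))
                row[f"raw_{iso}"] = raw + noise[iso]
            rows.append(row)

    for name, std in standards.items():
        emit(name, "standard",
             {"d17O": std.known_d17O, "d18O": std.known_d18O,
              "d2H": std.known_d2H}, "rep1")
    for name, ctl in controls.items():
        shift = control_fault_permil if name in faulted else 0.0
        emit(name, "control",
             {"d17O": ctl.known_d17O + shift, "d18O": ctl.known_d18O + shift,
              "d2H": ctl.known_d2H}, "rep1")
    for water_id, comp in sample_compositions.items():
        for r in range(1, n_replicates + 1):
            emit(water_id, "sample",
                 {"d17O": comp.d17O, "d18O": comp.d18O, "d2H": comp.d2H},
                 f"rep{r}")

    df = pd.DataFrame(rows)
    if outlier_injections:
        sd = max(noise["d18O"], 0.05)
        idx = rng.choice(df.index[df["water_role"] == "sample"],
                         size=outlier_injections, replace=False)
        df.loc[idx, "raw_d18O"] += 10 * sd
        df.loc[idx, "raw_d17O"] += 10 * sd * 0.53
    return df
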