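"""QC and aggregation of metabolic-phenotyping time series.

The phenotyping system samples each cage once per 5 min (gas exchange)
and logs food- and water-hopper masses continuously; consumption shows
up as downward steps in hopper mass.  Real deployments suffer three
pathologies handled here:

* sensor gaps of 35–335 min from reboots/maintenance — filled at the
  nominal cadence with the mean rate of the preceding 3 h (gaps of
  35–60 min) or the preceding 24 h (longer gaps, when researcher
  presence likely elevated rates);  gaps shorter than 35 min are left
  missing and integrate as zero-length;
* drinker-nozzle leakage overstating water intake — a bulk 10 %
  reduction of daily totals;
* gross spillage or food-caching days (e.g. 25 ml "intake" for an 18 g
  mouse) — replaced by the mean of the cage's clean days.

All functions take and return long-format :class:`pandas.DataFrame`s;
observed records are never altered, and every synthetic or corrected
value carries a flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import MeasuredFluxTotals

__all__ = [
    "CADENCE_MIN",
    "fill_gaps",
    "daily_intakes",
    "correct_water_intake",
    "replace_unrealistic",
    "window_totals",
    "qc_pipeline",
]

CADENCE_MIN = 5
GAP_SHORT_MIN = 35     # gaps below this are left missing
GAP_MEDIUM_MIN = 60    # 35–60 min: fill from previous 3 h
LOOKBACK_SHORT = pd.Timedelta(hours=3)
LOOKBACK_LONG = pd.Timedelta(hours=24)

GAS_COLUMNS = ("o2_ml_min", "co2_ml_min")

REQUIRED_COLUMNS = ("timestamp", "cage_id", "o2_ml_min", "co2_ml_min")


def _prepare(series: pd.DataFrame) -> pd.DataFrame:
    df = series.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotyping frame lacks columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values(["cage_id", "timestamp"], kind="mergesort")
    dup = df.duplicated(["cage_id", "timestamp"])
    if dup.any():
        raise ValueError("duplicate (cage, timestamp) records")
    return df.reset_index(drop=True)


def fill_gaps(series: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill 35–335+ min sensor gaps at nominal cadence.

    Returns the augmented frame (new boolean column ``filled``, string
    column ``fill_kind`` in {"", "short", "long"}) and a gap report with
    one row per detected gap.  Hopper masses of synthetic records are
    left missing; only gas rates are imputed.  Fills are computed from
    observed records only, so earlier fills never feed later ones.
    """
    df = _prepare(series)
    if "filled" not in df.columns:
        df["filled"] = False
        df["fill_kind"] = ""

    new_rows: list[pd.DataFrame] = []
    report: list[dict] = []
    for cage, grp in df.groupby("cage_id", sort=False):
        ts = grp["timestamp"]
        gaps = ts.diff()
        for i in np.flatnonzero(gaps.dt.total_seconds() / 60 > CADENCE_MIN * 1.5):
            start = ts.iloc[i - 1]
            end = ts.iloc[i]
            gap_min = (end - start).total_seconds() / 60
            entry = {"cage_id": cage, "gap_start": start, "gap_end": end,
                     "gap_min": gap_min, "action": "left_missing"}
            if gap_min < GAP_SHORT_MIN:
                report.append(entry)
                continue
            lookback = (LOOKBACK_SHORT if gap_min <= GAP_MEDIUM_MIN
                        else LOOKBACK_LONG)
            kind = "short" if gap_min <= GAP_MEDIUM_MIN else "long"
            window = grp[(ts > start - lookback) & (ts <= start)
                         & ~grp["filled"]]
            if len(window) < 2:
                warnings.warn(
                    f"cage {cage}: gap at {start} has no lookback data; "
                    "left unfilled", stacklevel=2)
                report.append(entry)
                continue
            means = {c: window[c].mean() for c in GAS_COLUMNS}
            slots = pd.date_range(start, end, freq=f"{CADENCE_MIN}min",
                                  inclusive="neither")
            fill = pd.DataFrame({
                "timestamp": slots, "cage_id": cage,
                "o2_ml_min": means["o2_ml_min"],
                "co2_ml_min": means["co2_ml_min"],
                "filled": True, "fill_kind": kind,
            })
            new_rows.append(fill)
            entry["action"] = f"filled_{kind}"
            entry["n_filled"] = len(slots)
            report.append(entry)

    out = pd.concat([df, *new_rows], ignore_index=True) if new_rows else df
    out = out.sort_values(["cage_id", "timestamp"],
                          kind="mergesort").reset_index(drop=True)
    report_df = pd.DataFrame(
        report, columns=["cage_id", "gap_start", "gap_end", "gap_min",
                         "action", "n_filled"])
    return out, report_df


def _step_consumption(masses: pd.Series) -> float:
    """Total hopper-mass decline, ignoring refills (positive steps)."""
    d = masses.dropna().diff()
    return float(-d[d < 0].sum())


def daily_intakes(series: pd.DataFrame) -> pd.DataFrame:
    """Per-cage daily water (ml ≡ g) and food (g) from hopper steps."""
    df = _prepare(series)
    df["date"] = df["timestamp"].dt.normalize()
    rows = []
    for (cage, date), grp in df.groupby(["cage_id", "date"], sort=True):
        rows.append({
            "cage_id": cage, "date": date,
            "water_ml": _step_consumption(grp["water_g"])
            if "water_g" in grp else np.nan,
            "food_g": _step_consumption(grp["food_g"])
            if "food_g" in grp else np.nan,
            "flags": "",
        })
    return pd.DataFrame(rows)


def correct_water_intake(daily: pd.DataFrame,
                         leakage_fraction: float = 0.10) -> pd.DataFrame:
    """Bulk drinker-leakage correction of daily water totals.

    Idempotent: rows already flagged ``leak_corrected`` are untouched.
    """
    if not 0.0 <= leakage_fraction < 1.0:
        raise ValueError("leakage_fraction must lie in [0, 1)")
    if np.isscalar(daily):
        if daily < 0:
            raise ValueError("water_ml must be non-negative")
        return daily * (1.0 - leakage_fraction)
    out = daily.copy()
    todo = ~out["flags"].str.contains("leak_corrected")
    out.loc[todo, "water_ml"] = out.loc[todo, "water_ml"] * (1.0 - leakage_fraction)
    out.loc[todo, "flags"] = (out.loc[todo, "flags"]
                              .apply(lambda f: _add_flag(f, "leak_corrected")))
    return out


def _add_flag(flags: str, new: str) -> str:
    parts = [p for p in flags.split("|") if p]
    if new not in parts:
        parts.append(new)
    return "|".join(parts)


def replace_unrealistic(daily: pd.DataFrame,
                        water_threshold_ml: float = 12.0,
                        food_threshold_g: float = 8.0) -> pd.DataFrame:
    """Replace spillage/caching days with the cage's clean-day mean.

    Thresholds default to values far above observed intake maxima but
    well below the gross artefacts they target (tens of ml/g).
    """
    out = daily.copy()
    for cage, grp in out.groupby("cage_id", sort=False):
        for col, thr, flag in (("water_ml", water_threshold_ml, "replaced_outlier_water"),
                               ("food_g", food_threshold_g, "replaced_outlier_food")):
            vals = grp[col]
            bad = vals > thr
            if not bad.any():
                continue
            clean = vals[~bad]
            if clean.empty:
                raise ValueError(
                    f"cage {cage}: every day exceeds the {col} threshold; "
                    "no replacement basis")
            out.loc[bad[bad].index, col] = clean.mean()
            for idx in bad[bad].index:
                out.loc[idx, "flags"] = _add_flag(out.loc[idx, "flags"], flag)
    return out


def window_totals(series: pd.DataFrame, daily: pd.DataFrame,
                  cage_id, end_time, window_hours: float) -> MeasuredFluxTotals:
    """Integrate gas rates and sum daily intakes over a trailing window.

    Gas records (observed or gap-filled) each represent one nominal
    5-min slot; slots missing after gap filling (short gaps) integrate
    as zero-length.  The window is [end − window, end); daily intakes
    are included for dates starting inside the window, so windows that
    align to whole days are exactly additive.
    """
    df = _prepare(series)
    df = df[df["cage_id"] == cage_id]
    end = pd.Timestamp(end_time)
    start = end - pd.Timedelta(hours=window_hours)
    in_win = df[(df["timestamp"] >= start) & (df["timestamp"] < end)]
    if in_win.empty:
        raise ValueError(
            f"cage {cage_id}: window {start}–{end} contains no records")

    ts = in_win["timestamp"]
    bounds = pd.Series([start, *ts, end])
    spans = bounds.diff().dropna().dt.total_seconds() / 60
    long_missing = spans[spans > GAP_SHORT_MIN + CADENCE_MIN]
    if not long_missing.empty:
        raise ValueError(
            f"cage {cage_id}: window {start}–{end} has uncovered spans of "
            f"{sorted(long_missing.round(1).tolist(), reverse=True)} min; "
            "run gap filling first")

    o2 = float(in_win["o2_ml_min"].sum()) * CADENCE_MIN
    co2 = float(in_win["co2_ml_min"].sum()) * CADENCE_MIN

    d = daily[daily["cage_id"] == cage_id]
    dates = pd.to_datetime(d["date"])
    in_days = d[(dates >= start.normalize()) & (dates < end)]
    water = float(in_days["water_ml"].sum())
    food_kg = float(in_days["food_g"].sum()) / 1000.0

    return MeasuredFluxTotals(o2_ml=o2, co2_ml=co2, food_kg=food_kg,
                              water_ml=water, window_hours=window_hours)


def qc_pipeline(series: pd.DataFrame,
                leakage_fraction: float = 0.10,
                water_threshold_ml: float = 12.0,
                food_threshold_g: float = 8.0,
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full QC chain: gap fill → daily intakes → leak and outlier fixes.

    Returns (filled gas series, QC'd daily intakes, gap report).
    """
    filled, report = fill_gaps(series)
    daily = daily_intakes(filled)
    daily = correct_water_intake(daily, leakage_fraction)
    daily = replace_unrealistic(daily, water_threshold_ml, food_threshold_g)
    return filled, daily, report
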