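"""VSMOW-SLAP normalization of water-isotope analyzer runs.

A cavity ring-down analysis run interleaves repeated injections of
samples, two bracketing reference waters of known composition (e.g.
USGS50/USGS47) and several control waters.  Raw analyzer deltas are put
on the VSMOW-SLAP scale with a two-point stretching/offset correction
per isotope (corrected = stretching × raw + offset), fitted so that the
reference waters' outlier-screened mean raw values map exactly onto
their known values.  Injection outliers are removed per quantity by a
single 2-SD pass (never more than 20 % of injections).  Runs are gated
on control-water accuracy; per-sample grand means average distillation
replicates without weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iso import TripleOxygenComposition, cap_delta17

__all__ = [
    "StandardDefinition",
    "CorrectionModel",
    "RunQCResult",
    "WaterSummary",
    "QCThresholds",
    "outlier_mask",
    "fit_correction",
    "summarize_water",
    "qc_run",
    "grand_mean",
    "process_runs",
]

RAW_COLUMNS = ("raw_d17O", "raw_d18O", "raw_d2H")
ISOTOPES = ("d17O", "d18O", "d2H")


@dataclass(frozen=True)
class StandardDefinition:
    """Known VSMOW-SLAP composition of a reference or control water."""

    name: str
    known_d17O: float
    known_d18O: float
    known_d2H: float | None = None

    def known(self, isotope: str) -> float | None:
        return getattr(self, f"known_{isotope}")

    @property
    def known_cap17O(self) -> float:
        return cap_delta17(self.known_d17O, self.known_d18O)


@dataclass(frozen=True)
class QCThresholds:
    """A control water fails when any deviation reaches a threshold."""

    d17O_permil: float = 0.15
    d18O_permil: float = 0.30
    cap17O_permeg: float = 15.0
    max_failing: int = 2       # run rejected when MORE than this fail


@dataclass(frozen=True)
class CorrectionModel:
    """Per-isotope stretching/offset: corrected = stretch·raw + offset."""

    stretch: dict = field(default_factory=dict)
    offset: dict = field(default_factory=dict)

    def apply(self, injections: pd.DataFrame) -> pd.DataFrame:
        out = injections.copy()
        for iso in ISOTOPES:
            raw_col = f"raw_{iso}"
            if raw_col not in out.columns or iso not in self.stretch:
                continue
            out[iso] = self.stretch[iso] * out[raw_col] + self.offset[iso]
        if {"d17O", "d18O"} <= set(out.columns):
            out["cap17O"] = [
                cap_delta17(a, b) for a, b in zip(out["d17O"], out["d18O"])]
        return out


@dataclass(frozen=True)
class WaterSummary:
    water_id: str
    mean: dict                 # quantity -> mean
    sd: dict                   # quantity -> SD (ddof=1; 0 for n=1)
    n_used: dict               # quantity -> injections retained

    @property
    def composition(self) -> TripleOxygenComposition:
        return TripleOxygenComposition(self.mean["d17O"], self.mean["d18O"])


@dataclass(frozen=True)
class RunQCResult:
    run_id: str
    n_controls: int
    n_failing: int
    accepted: bool
    deviations: pd.DataFrame   # per control: d17O/d18O/cap17O deviation


def outlier_mask(values: np.ndarray, n_sd: float = 2.0,
                 max_fraction: float = 0.2) -> np.ndarray:
    """True for injections kept by a single-pass z-score screen.

    Deviations beyond ``n_sd`` standard deviations of the initial mean
    are dropped, most extreme first, but never more than
    ``max_fraction`` of the injections.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        return np.ones(n, dtype=bool)
    sd = values.std(ddof=1)
    if sd == 0:
        return np.ones(n, dtype=bool)
    dev = np.abs(values - values.mean())
    flagged = np.flatnonzero(dev > n_sd * sd)
    limit = int(np.floor(max_fraction * n))
    if len(flagged) > limit:
        flagged = flagged[np.argsort(dev[flagged])[::-1][:limit]]
    keep = np.ones(n, dtype=bool)
    keep[flagged] = False
    return keep


def _screened_mean(values: pd.Series) -> float:
    v = values.dropna().to_numpy()
    return float(v[outlier_mask(v)].mean())


def fit_correction(run: pd.DataFrame,
                   standards: dict[str, StandardDefinition]) -> CorrectionModel:
    """Two-point VSMOW-SLAP fit from the run's reference-water injections."""
    if len(standards) != 2:
        raise ValueError("exactly two reference waters are required")
    (name_a, std_a), (name_b, std_b) = standards.items()
    stretch: dict = {}
    offset: dict = {}
    groups = {}
    for name in (name_a, name_b):
        grp = run[run["water_id"] == name]
        if len(grp) < 2:
            raise ValueError(
                f"reference water {name!r} needs ≥2 injections, "
                f"found {len(grp)}")
        groups[name] = grp
    for iso in ISOTOPES:
        known_a, known_b = (s.known(iso) for s in (std_a, std_b))
        if known_a is None or known_b is None:
            continue
        raw_a = _screened_mean(groups[name_a][f"raw_{iso}"])
        raw_b = _screened_mean(groups[name_b][f"raw_{iso}"])
        if raw_a == raw_b:
            raise ZeroDivisionError(
                f"degenerate fit for {iso}: both reference waters measured "
                f"at {raw_a}")
        s = (known_a - known_b) / (raw_a - raw_b)
        stretch[iso] = s
        offset[iso] = known_a - s * raw_a
    return CorrectionModel(stretch, offset)


def summarize_water(injections: pd.DataFrame,
                    correction: CorrectionModel) -> WaterSummary:
    """Mean ± SD of one water in one run after correction and screening.

    Δ′¹⁷O is computed per corrected injection and screened independently
    of the deltas, so its summary reflects the correlated part of the
    injection noise.
    """
    if len(injections) < 3:
        raise ValueError(
            f"need ≥3 injections to summarize, got {len(injections)}")
    water_ids = injections["water_id"].unique()
    if len(water_ids) != 1:
        raise ValueError("summarize_water expects a single water")
    corrected = correction.apply(injections)
    mean: dict = {}
    sd: dict = {}
    n_used: dict = {}
    for q in (*ISOTOPES, "cap17O"):
        if q not in corrected.columns:
            continue
        v = corrected[q].dropna().to_numpy()
        if len(v) == 0:
            continue
        keep = outlier_mask(v)
        kept = v[keep]
        mean[q] = float(kept.mean())
        sd[q] = float(kept.std(ddof=1)) if len(kept) > 1 else 0.0
        n_used[q] = int(keep.sum())
    return WaterSummary(str(water_ids[0]), mean, sd, n_used)


def qc_run(run: pd.DataFrame,
           controls: dict[str, StandardDefinition],
           correction: CorrectionModel,
           thresholds: QCThresholds = QCThresholds()) -> RunQCResult:
    """Gate a run on control-water accuracy (> max_failing ⇒ rejected)."""
    if not controls:
        raise ValueError("at least one control water is required")
    run_id = str(run["run_id"].iloc[0]) if "run_id" in run.columns else ""
    rows = []
    n_failing = 0
    for name, defn in controls.items():
        grp = run[run["water_id"] == name]
        if grp.empty:
            continue
        summ = summarize_water(grp, correction)
        dev17 = summ.mean["d17O"] - defn.known_d17O
        dev18 = summ.mean["d18O"] - defn.known_d18O
        devcap = summ.mean["cap17O"] - defn.known_cap17O
        failed = (abs(dev17) >= thresholds.d17O_permil
                  or abs(dev18) >= thresholds.d18O_permil
                  or abs(devcap) >= thresholds.cap17O_permeg)
        n_failing += failed
        rows.append({"control": name, "dev_d17O": dev17, "dev_d18O": dev18,
                     "dev_cap17O": devcap, "failed": failed})
    deviations = pd.DataFrame(rows)
    return RunQCResult(
        run_id=run_id,
        n_controls=len(rows),
        n_failing=n_failing,
        accepted=n_failing <= thresholds.max_failing,
        deviations=deviations,
    )


def grand_mean(replicate_summaries: list[WaterSummary]) -> WaterSummary | None:
    """Unweighted mean over distillation replicates of one sample.

    Δ′¹⁷O is recomputed from the grand-mean deltas.  Replicates whose
    spread exceeds the distillation-precision expectation (0.3 ‰ range
    in δ¹⁸O or 15 per meg in Δ′¹⁷O) trigger a warning, not removal.
    Returns ``None`` (with a warning) when no accepted replicate exists.
    """
    if not replicate_summaries:
        warnings.warn("sample dropped: no accepted replicates", stacklevel=2)
        return None
    ids = {s.water_id for s in replicate_summaries}
    if len(ids) != 1:
        raise ValueError(f"replicates belong to different waters: {ids}")
    d17 = [s.mean["d17O"] for s in replicate_summaries]
    d18 = [s.mean["d18O"] for s in replicate_summaries]
    cap = [s.mean["cap17O"] for s in replicate_summaries]
    if len(d18) > 1:
        if (max(d18) - min(d18) > 0.3) or (max(cap) - min(cap) > 15.0):
            warnings.warn(
                f"{replicate_summaries[0].water_id}: "
                "replicate spread exceeds distillation precision "
                f"(δ18O range {max(d18) - min(d18):.3f} ‰, "
                f"Δ′17O range {max(cap) - min(cap):.1f} per meg)",
                stacklevel=2)
    mean = {
        "d17O": float(np.mean(d17)),
        "d18O": float(np.mean(d18)),
    }
    mean["cap17O"] = cap_delta17(mean["d17O"], mean["d18O"])
    sd = {
        "d17O": float(np.std(d17, ddof=1)) if len(d17) > 1 else 0.0,
        "d18O": float(np.std(d18, ddof=1)) if len(d18) > 1 else 0.0,
        "cap17O": float(np.std(cap, ddof=1)) if len(cap) > 1 else 0.0,
    }
    n = {"replicates": len(replicate_summaries)}
    return WaterSummary(replicate_summaries[0].water_id, mean, sd, n)


def process_runs(injections: pd.DataFrame,
                 standards: dict[str, StandardDefinition],
                 controls: dict[str, StandardDefinition],
                 thresholds: QCThresholds = QCThresholds(),
                 ) -> tuple[pd.DataFrame, pd.DataFrame, list[RunQCResult]]:
    """Correct, gate and average a table of runs to per-sample grand means.

    Returns (per-water per-run summary table, per-sample grand-mean
    table over accepted runs, per-run QC results).
    """
    summaries = []
    qc_results = []
    by_sample: dict[str, list[WaterSummary]] = {}
    for run_id, run in injections.groupby("run_id", sort=True):
        correction = fit_correction(run, standards)
        qc = qc_run(run, controls, correction, thresholds)
        qc_results.append(qc)
        for water_id, grp in run.groupby("water_id", sort=True):
            for rep_id, rep in grp.groupby("replicate_id", sort=True):
                summ = summarize_water(rep, correction)
                role = rep["water_role"].iloc[0]
                summaries.append({
                    "run_id": run_id, "water_id": water_id,
                    "replicate_id": rep_id, "water_role": role,
                    "accepted_run": qc.accepted,
                    **{f"{q}_mean": summ.mean.get(q)
                       for q in ("d17O", "d18O", "cap17O")},
                    **{f"{q}_sd": summ.sd.get(q)
                       for q in ("d17O", "d18O", "cap17O")},
                    "n_used": summ.n_used.get("d18O"),
                })
                if role == "sample" and qc.accepted:
                    by_sample.setdefault(str(water_id), []).append(summ)

    grand_rows = []
    for water_id, reps in by_sample.items():
        gm = grand_mean(reps)
        if gm is None:
            continue
        grand_rows.append({
            "water_id": water_id,
            "d17O": gm.mean["d17O"], "d18O": gm.mean["d18O"],
            "cap17O": gm.mean["cap17O"],
            "d18O_sd": gm.sd["d18O"], "cap17O_sd": gm.sd["cap17O"],
            "n_replicates": gm.n_used["replicates"],
        })
    return (pd.DataFrame(summaries), pd.DataFrame(grand_rows), qc_results)
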