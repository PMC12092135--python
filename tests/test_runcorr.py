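"""Analyzer-run correction: two-point fit, outlier screen, QC gate."""

import numpy as np
import pandas as pd
import pytest

from oxflux.iso import TripleOxygenComposition, d17O_from_cap
from oxflux.runcorr import (
    CorrectionModel,
    QCThresholds,
    StandardDefinition,
    fit_correction,
    grand_mean,
    outlier_mask,
    process_runs,
    qc_run,
    summarize_water,
)
from oxflux.synth import (
    default_controls,
    default_standards,
    simulate_analysis_run,
)


def injections_for(water_id, d17, d18, n=5, role="standard", run="r1",
                   rep="rep1"):
    d17 = list(np.atleast_1d(d17)) * (n if np.isscalar(d17) else 1)
    d18 = list(np.atleast_1d(d18)) * (n if np.isscalar(d18) else 1)
    return pd.DataFrame({
        "run_id": run, "water_id": water_id, "water_role": role,
        "replicate_id": rep,
        "raw_d17O": d17,
        "raw_d18O": d18,
        "raw_d2H": [8.0 * v + 10.0 for v in d18],  # distinct per water
    })


STD_A = StandardDefinition("A", known_d17O=-0.85, known_d18O=-1.60,
                           known_d2H=-5.0)
STD_B = StandardDefinition("B", known_d17O=-14.15, known_d18O=-26.78,
                           known_d2H=-190.0)


class TestFitCorrection:
    def test_precalibrated_instrument(self):
        run = pd.concat([
            injections_for("A", STD_A.known_d17O, STD_A.known_d18O),
            injections_for("B", STD_B.known_d17O, STD_B.known_d18O)])
        model = fit_correction(run, {"A": STD_A, "B": STD_B})
        assert model.stretch["d18O"] == pytest.approx(1.0, abs=1e-12)
        assert model.offset["d18O"] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_solution(self):
        # raw means (−1.00, −26.00) against knowns (−1.60, −26.78)
        run = pd.concat([injections_for("A", -0.5, -1.00),
                         injections_for("B", -13.5, -26.00)])
        model = fit_correction(run, {"A": STD_A, "B": STD_B})
        assert model.stretch["d18O"] == pytest.approx(25.18 / 25.0, abs=1e-9)
        assert model.offset["d18O"] == pytest.approx(
            -1.60 - (25.18 / 25.0) * (-1.00), abs=1e-9)

    def test_exact_on_standards(self):
        run = pd.concat([injections_for("A", -0.5, -1.00),
                         injections_for("B", -13.5, -26.00)])
        model = fit_correction(run, {"A": STD_A, "B": STD_B})
        corrected = model.apply(run)
        a = corrected[corrected.water_id == "A"]
        assert np.allclose(a["d18O"], STD_A.known_d18O, atol=1e-12)
        assert np.allclose(a["d17O"], STD_A.known_d17O, atol=1e-12)

    def test_synthetic_round_trip_is_exact(self):
        run = simulate_analysis_run({}, stretch=1.02, offset=0.3,
                                    noise_d18O=0.0, seed=5)
        model = fit_correction(run, default_standards())
        for iso in ("d17O", "d18O"):
            assert model.stretch[iso] == pytest.approx(1.02, abs=1e-10)
            assert model.offset[iso] == pytest.approx(0.3, abs=1e-10)

    def test_degenerate_fit(self):
        run = pd.concat([injections_for("A", -0.5, -1.0),
                         injections_for("B", -13.5, -1.0)])
        with pytest.raises(ZeroDivisionError):
            fit_correction(run, {"A": STD_A, "B": STD_B})

    def test_missing_standard(self):
        run = injections_for("A", -0.5, -1.0)
        with pytest.raises(ValueError, match="B"):
            fit_correction(run, {"A": STD_A, "B": STD_B})


class TestOutlierScreen:
    def test_no_outliers_all_kept(self):
        assert outlier_mask(np.array([1.0, 1.1, 0.9, 1.05, 0.95])).all()

    def test_single_gross_outlier_removed(self):
        v = np.array([1.0, 1.01, 0.99, 1.02, 0.98, 1.0, 5.0])
        keep = outlier_mask(v)
        assert keep.sum() == 6
        assert not keep[-1]

    def test_never_removes_more_than_a_fifth(self):
        v = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0, 10.0, 10.0, 10.0,
                      10.0])
        assert outlier_mask(v).sum() >= 8


class TestSummarize:
    IDENT = CorrectionModel({"d17O": 1.0, "d18O": 1.0},
                            {"d17O": 0.0, "d18O": 0.0})

    def test_identical_injections(self):
        inj = injections_for("w", -1.0, -2.0, n=6, role="sample")
        s = summarize_water(inj, self.IDENT)
        assert s.mean["d18O"] == -2.0
        assert s.sd["d18O"] == 0.0
        assert s.n_used["d18O"] == 6

    def test_displaced_injection_removed(self):
        d18 = [-2.00, -2.01, -1.99, -2.02, -1.98, -2.00, -1.0]
        inj = injections_for("w", [x * 0.53 for x in d18], d18,
                             role="sample")
        s = summarize_water(inj, self.IDENT)
        assert s.n_used["d18O"] == 6
        assert s.mean["d18O"] == pytest.approx(np.mean(d18[:-1]))

    def test_too_few_injections(self):
        inj = injections_for("w", -1.0, -2.0, n=2)
        with pytest.raises(ValueError, match="≥3"):
            summarize_water(inj, self.IDENT)

    def test_cap17_computed_per_injection(self):
        inj = injections_for("w", d17O_from_cap(-4.0, 20.0), -4.0, n=5)
        s = summarize_water(inj, self.IDENT)
        assert s.mean["cap17O"] == pytest.approx(20.0, abs=1e-9)


def make_gate_run(n_bad, shift=1.0):
    """Five controls, n_bad of them displaced beyond every threshold."""
    controls = default_controls()
    frames = []
    for i, (name, c) in enumerate(controls.items()):
        off = shift if i < n_bad else 0.0
        frames.append(injections_for(
            name, c.known_d17O + off, c.known_d18O + off, role="control"))
    return pd.concat(frames, ignore_index=True), controls


class TestQCGate:
    IDENT = TestSummarize.IDENT

    @pytest.mark.parametrize("n_bad, accepted", [
        (0, True), (1, True), (2, True), (3, False), (5, False)])
    def test_gate_boundary(self, n_bad, accepted):
        run, controls = make_gate_run(n_bad)
        res = qc_run(run, controls, self.IDENT)
        assert res.n_controls == 5
        assert res.n_failing == n_bad
        assert res.accepted is accepted

    def test_gate_is_monotone_in_deviations(self):
        run, controls = make_gate_run(3, shift=0.5)
        rejected = qc_run(run, controls, self.IDENT)
        assert not rejected.accepted
        worse, _ = make_gate_run(3, shift=2.0)
        assert not qc_run(worse, controls, self.IDENT).accepted

    def test_threshold_is_inclusive(self):
        # a deviation of exactly 0.30 permil in d18O fails ("≥")
        run, controls = make_gate_run(0)
        name = list(controls)[0]
        run.loc[run.water_id == name, "raw_d18O"] += 0.30
        res = qc_run(run, controls, self.IDENT,
                     QCThresholds(d17O_permil=99, cap17O_permeg=9999))
        assert res.n_failing == 1

    def test_requires_controls(self):
        run, _ = make_gate_run(0)
        with pytest.raises(ValueError):
            qc_run(run, {}, self.IDENT)


class TestGrandMean:
    @staticmethod
    def _summary(d18, cap):
        inj = injections_for("s", d17O_from_cap(d18, cap), d18, n=5,
                             role="sample")
        return summarize_water(inj, TestSummarize.IDENT)

    def test_single_replicate_is_itself(self):
        s = self._summary(-2.0, 10.0)
        gm = grand_mean([s])
        assert gm.mean["d18O"] == s.mean["d18O"]
        assert gm.mean["cap17O"] == pytest.approx(10.0, abs=1e-9)

    def test_unweighted_mean(self):
        reps = [self._summary(d, 0.0) for d in (-2.0, -2.2, -2.4)]
        # 0.4 permil replicate spread also exercises the precision warning
        with pytest.warns(UserWarning, match="replicate spread"):
            gm = grand_mean(reps)
        assert gm.mean["d18O"] == pytest.approx(-2.2, abs=1e-12)

    def test_permutation_invariance(self):
        reps = [self._summary(d, c) for d, c in
                [(-2.0, 5.0), (-2.2, 12.0), (-2.1, 9.0)]]
        a = grand_mean(reps)
        b = grand_mean(reps[::-1])
        assert a.mean == b.mean

    def test_consistent_replicates_do_not_warn(self, recwarn):
        reps = [self._summary(d, c) for d, c in
                [(-2.0, 5.0), (-2.2, 12.0)]]  # within 0.3 permil / 15 per meg
        grand_mean(reps)
        assert not [w for w in recwarn.list
                    if "replicate spread" in str(w.message)]

    def test_inconsistent_replicates_warn(self):
        reps = [self._summary(-2.0, 0.0), self._summary(-2.5, 0.0)]
        with pytest.warns(UserWarning, match="replicate spread"):
            grand_mean(reps)

    def test_no_replicates_drops_sample(self):
        with pytest.warns(UserWarning, match="dropped"):
            assert grand_mean([]) is None


class TestEndToEnd:
    def test_noisy_recovery(self):
        rng_truth = {
            f"s{i}": TripleOxygenComposition.from_cap17(d18, cap)
            for i, (d18, cap) in enumerate(
                [(-2.1, -90.0), (-2.4, -60.0), (-1.8, -75.0)])}
        inj = simulate_analysis_run(rng_truth, stretch=1.02, offset=0.3,
                                    noise_d18O=0.05, seed=21,
                                    n_replicates=3)
        summary, grand, qc_results = process_runs(
            inj, default_standards(), default_controls())
        assert all(r.accepted for r in qc_results)
        assert len(grand) == 3
        for sid, truth in rng_truth.items():
            row = grand[grand.water_id == sid].iloc[0]
            # bias below the per-replicate noise scale
            assert row.d18O == pytest.approx(truth.d18O, abs=0.05)
            # correlated injection noise keeps cap17O tight
            assert row.cap17O == pytest.approx(truth.cap17O, abs=15.0)

    def test_correction_recovered_under_noise(self):
        inj = simulate_analysis_run({}, stretch=1.02, offset=0.3,
                                    noise_d18O=0.05, seed=22)
        model = fit_correction(inj, default_standards())
        assert model.stretch["d18O"] == pytest.approx(1.02, abs=2e-3)
        assert model.offset["d18O"] == pytest.approx(0.3, abs=0.05)

    def test_planted_failing_controls_reject_run(self):
        inj = simulate_analysis_run({}, n_failing_controls=3,
                                    control_fault_permil=1.0, seed=23)
        model = fit_correction(inj, default_standards())
        res = qc_run(inj, default_controls(), model)
        assert res.n_failing == 3
        assert not res.accepted
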