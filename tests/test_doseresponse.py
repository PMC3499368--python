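"""Reporter normalization, 4PL fitting, fold preferences, recognition rules."""

import numpy as np
import pytest

from minspec import simulate_assay
from minspec.doseresponse import (
    AssayTable,
    FoldPreference,
    NormalizedResponse,
    fit_dose_response,
    fit_inhibition,
    fold_preference,
    four_parameter_logistic,
    infer_recognition_rules,
    normalize_reporter,
    read_assay_tables,
)


def toy_table(firefly, renilla, vehicle_f, vehicle_r, doses=(1e-9, 1e-8)):
    return AssayTable(
        receptor="R", ligand="L", doses=np.array(doses),
        firefly=np.array(firefly, float), renilla=np.array(renilla, float),
        vehicle_firefly=np.array(vehicle_f, float),
        vehicle_renilla=np.array(vehicle_r, float),
    )


class TestNormalization:
    def test_vehicle_level_wells_give_fold_one(self):
        t = toy_table([[10, 10, 10]] * 2, [[5, 5, 5]] * 2, [10, 10, 10], [5, 5, 5])
        n = normalize_reporter(t)
        assert np.allclose(n.fold, 1.0)

    def test_firefly_scales_and_renilla_cancels(self):
        t = toy_table([[10, 12, 14], [20, 22, 24]], [[5, 6, 7], [5, 6, 7]],
                      [10, 10, 10], [5, 5, 5])
        base = normalize_reporter(t).fold
        doubled_f = toy_table([[20, 24, 28], [40, 44, 48]], [[5, 6, 7], [5, 6, 7]],
                              [10, 10, 10], [5, 5, 5])
        assert np.allclose(normalize_reporter(doubled_f).fold, 2 * base)
        doubled_r = toy_table([[10, 12, 14], [20, 22, 24]],
                              [[10, 12, 14], [10, 12, 14]],
                              [10, 10, 10], [10, 10, 10])
        assert np.allclose(normalize_reporter(doubled_r).fold, base)

    def test_hand_computed_two_dose_table(self):
        # vehicle ratio mean = (8/4 + 12/4)/2 = 2.5
        t = toy_table([[10, 20, 30], [40, 50, 60]], [[10, 10, 10], [20, 20, 20]],
                      [8, 12], [4, 4])
        n = normalize_reporter(t)
        expected = np.array([[1.0, 2.0, 3.0], [2.0, 2.5, 3.0]]) / 2.5
        assert np.abs(n.fold - expected).max() < 1e-12

    def test_zero_renilla_rejected_with_well_location(self):
        with pytest.raises(ValueError, match="dose index 1, replicate 2"):
            toy_table([[1, 1, 1]] * 2, [[1, 1, 1], [1, 1, 0]], [1], [1])

    def test_missing_vehicle_rejected(self):
        with pytest.raises(ValueError, match="vehicle"):
            toy_table([[1, 1, 1]] * 2, [[1, 1, 1]] * 2, [], [])


class TestDoseResponseFit:
    def test_noiseless_parameters_recovered(self):
        sim = simulate_assay(basal=1.0, maximum=10.0, ec50=1e-9, hill=1.0, cv=0.0)
        fit = fit_dose_response(normalize_reporter(sim.table))
        assert fit.ec50 == pytest.approx(1e-9, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.basal == pytest.approx(1.0, rel=1e-6)
        assert fit.max_response == pytest.approx(10.0, rel=1e-6)

    def test_ec50_equals_half_maximum_dose(self):
        sim = simulate_assay(basal=1.0, maximum=9.0, ec50=3e-9, hill=1.4, cv=0.0)
        fit = fit_dose_response(normalize_reporter(sim.table))
        dense = np.logspace(-12, -5, 200001)
        curve = four_parameter_logistic(
            np.log10(dense), fit.basal, fit.max_response,
            np.log10(fit.ec50), fit.hill,
        )
        half = fit.basal + (fit.max_response - fit.basal) / 2
        crossing = dense[int(np.argmin(np.abs(curve - half)))]
        assert crossing == pytest.approx(fit.ec50, rel=1e-3)

    def test_ci_coverage_at_ten_percent_noise(self):
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            sim = simulate_assay(basal=1, maximum=10, ec50=1e-9, hill=1.0,
                                 cv=0.1, seed=seed)
            fit = fit_dose_response(normalize_reporter(sim.table))
            assert fit.determined
            lo, hi = fit.ec50_ci
            hits += lo <= 1e-9 <= hi
        assert abs(hits / n_runs - 0.95) <= 0.04

    def test_flat_data_flagged_no_activation(self):
        sim = simulate_assay(basal=1.0, maximum=1.0, cv=0.1, seed=3)
        fit = fit_dose_response(normalize_reporter(sim.table))
        assert fit.no_activation and fit.ec50 is None and not fit.determined

    def test_dose_scale_equivariance(self):
        sim = simulate_assay(basal=1, maximum=8, ec50=2e-9, hill=1.2, cv=0.1, seed=4)
        n = normalize_reporter(sim.table)
        fit = fit_dose_response(n)
        scaled = NormalizedResponse(doses=n.doses * 100, fold=n.fold,
                                    mean=n.mean, sem=n.sem)
        fit_scaled = fit_dose_response(scaled)
        assert fit_scaled.ec50 == pytest.approx(fit.ec50 * 100, rel=1e-6)

    def test_median_log_ec50_error_small_at_study_noise(self):
        errs = []
        for seed in range(60):
            sim = simulate_assay(basal=1, maximum=10, ec50=1e-9, hill=1.0,
                                 cv=0.1, seed=1000 + seed)
            fit = fit_dose_response(normalize_reporter(sim.table))
            errs.append(abs(np.log10(fit.ec50 / 1e-9)))
        assert np.median(errs) < 0.1


class TestInhibition:
    @staticmethod
    def descending(ic50, top=8.0, bottom=1.0, hill=1.2):
        doses = np.logspace(-12, -5, 8)
        resp = bottom + (top - bottom) / (
            1 + 10 ** ((np.log10(doses) - np.log10(ic50)) * hill)
        )
        return NormalizedResponse(doses=doses, fold=np.tile(resp[:, None], (1, 3)),
                                  mean=resp, sem=np.zeros_like(resp))

    def test_noiseless_ic50_recovered(self):
        inh = fit_inhibition(self.descending(2e-8), "estradiol", 2e-7)
        assert inh.ic50 == pytest.approx(2e-8, rel=1e-6)
        assert not inh.no_inhibition

    def test_mirror_symmetry_of_midpoint(self):
        nr = self.descending(5e-9)
        mirrored = NormalizedResponse(
            doses=nr.doses, fold=nr.fold[::-1], mean=nr.mean[::-1], sem=nr.sem,
        )
        inh = fit_inhibition(nr, "estradiol", 2e-7)
        # reflected curve read against the reversed log-dose axis has the
        # same midpoint distance from the grid ends
        lo, hi = np.log10(nr.doses[0]), np.log10(nr.doses[-1])
        reflected_mid = lo + hi - np.log10(inh.ic50)
        agonist = fit_dose_response(mirrored)
        assert np.log10(agonist.ec50) == pytest.approx(reflected_mid, abs=1e-6)

    def test_flat_data_flagged_no_inhibition(self):
        doses = np.logspace(-12, -5, 8)
        flat = np.full(8, 5.0)
        nr = NormalizedResponse(doses=doses, fold=np.tile(flat[:, None], (1, 3)),
                                mean=flat, sem=np.zeros(8))
        inh = fit_inhibition(nr, "estradiol", 2e-7)
        assert inh.no_inhibition and inh.ic50 is None


class TestFoldPreference:
    @staticmethod
    def fit_for(ec50, seed=0, cv=0.0):
        sim = simulate_assay(ec50=ec50, cv=cv, seed=seed)
        return fit_dose_response(normalize_reporter(sim.table))

    def test_identical_fits_give_fold_one(self):
        f = self.fit_for(1e-9)
        assert fold_preference(f, f, "m").fold == pytest.approx(1.0)

    def test_twentyone_fold_pair(self):
        fa = self.fit_for(1e-9)
        fb = self.fit_for(2.1e-8)
        assert fold_preference(fa, fb, "17beta-acetyl").fold == pytest.approx(21.0, rel=1e-6)

    def test_antisymmetry_is_exact(self):
        fa = self.fit_for(1e-9, seed=5, cv=0.1)
        fb = self.fit_for(8e-8, seed=6, cv=0.1)
        fwd = fold_preference(fa, fb, "m")
        rev = fold_preference(fb, fa, "m")
        assert fwd.fold * rev.fold == pytest.approx(1.0, rel=1e-12)

    def test_undetermined_ec50_becomes_censored_bound(self):
        fa = self.fit_for(1e-9)
        flat = simulate_assay(basal=1, maximum=1, cv=0.05, seed=7)
        fb = fit_dose_response(normalize_reporter(flat.table))
        fp = fold_preference(fa, fb, "aromatized A-ring")
        assert fp.censored and fp.fold == pytest.approx(1e-5 / 1e-9)
        with pytest.raises(ValueError):
            fold_preference(fb, fb, "m")


class TestRecognitionRules:
    @staticmethod
    def pref(fold, moiety):
        return FoldPreference("a", "b", moiety, fold, None)

    def test_strong_requirement_from_large_folds(self):
        rules = infer_recognition_rules(
            [self.pref(150.0, "aromatized A-ring"), self.pref(400.0, "aromatized A-ring")]
        )
        (rule,) = rules
        assert rule.direction == "required" and rule.strength == "strong"
        assert rule.min_fold == 150.0
        assert rule.bracket() == "[aromatized A-ring]"

    def test_strong_exclusion_from_small_folds(self):
        rules = infer_recognition_rules(
            [self.pref(0.002, "aromatized A-ring"), self.pref(0.01, "aromatized A-ring")]
        )
        (rule,) = rules
        assert rule.direction == "excluded" and rule.strength == "strong"
        assert rule.bracket() == "[not aromatized A-ring]"

    def test_near_unity_folds_give_weak_rule(self):
        rules = infer_recognition_rules(
            [self.pref(1.5, "11-hydroxyl"), self.pref(2.0, "11-hydroxyl")]
        )
        (rule,) = rules
        assert rule.strength == "weak"

    def test_threshold_boundary_counts_as_strong(self):
        (rule,) = infer_recognition_rules([self.pref(10.0, "m")], strong_threshold=10.0)
        assert rule.strength == "strong"

    def test_conflicting_directions_marked_inconsistent(self):
        rules = infer_recognition_rules([self.pref(30.0, "m"), self.pref(0.03, "m")])
        (rule,) = rules
        assert rule.direction == "inconsistent"


class TestAssayTableIO:
    def test_tsv_round_trip(self, tmp_path):
        sim = simulate_assay(cv=0.05, seed=9)
        t = sim.table
        p = tmp_path / "assays.tsv"
        with open(p, "w") as fh:
            fh.write("receptor\tligand\tdose_M\tfirefly\trenilla\tis_vehicle\n")
            for f, r in zip(t.vehicle_firefly, t.vehicle_renilla):
                fh.write(f"R\tvehicle\t{t.doses[0]:g}\t{f}\t{r}\t1\n")
            for d, frow, rrow in zip(t.doses, t.firefly, t.renilla):
                for f, r in zip(frow, rrow):
                    fh.write(f"R\tE2\t{d:g}\t{f}\t{r}\t0\n")
        (table,) = read_assay_tables(p)
        assert table.receptor == "R" and table.ligand == "E2"
        assert np.allclose(table.doses, t.doses)
        fit = fit_dose_response(normalize_reporter(table))
        assert fit.determined
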