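"""Peak-to-matrix engine: MDL filter, recalibration, assignment, isotope
verification, blank subtraction and duplicate merging."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from cryodom import synthetic as syn
from cryodom.engine import (
    EngineParams,
    assign_formulas,
    merge_duplicates,
    mdl_filter,
    process_peaks,
    recalibrate,
    remove_blank_peaks,
    verify_isotopes,
)
from cryodom.formulas import (
    C13_ABUNDANCE,
    C13_DELTA,
    ElementConstraints,
    MolecularFormula,
)

F = MolecularFormula.from_string


def spectrum_from(formulas, ppm_shift=0.0):
    mz = np.array([f.mz_neg for f in formulas]) * (1 + ppm_shift * 1e-6)
    return pd.DataFrame({"mz": mz, "intensity": np.full(len(mz), 1e5)})


class TestMdlFilter:
    def test_threshold_retains_expected_peaks(self):
        peaks = pd.DataFrame({"mz": [100., 200., 300.],
                              "intensity": [1., 10., 100.]})
        out, mdl = mdl_filter(peaks, mdl_factor=2.0, noise_level=4.0)
        assert mdl == 8.0
        assert list(out["intensity"]) == [10., 100.]

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            mdl_filter(pd.DataFrame({"mz": [1.], "intensity": [1.]}), 0.0)

    def test_empty_input_passes_through(self):
        out, _ = mdl_filter(pd.DataFrame({"mz": [], "intensity": []}))
        assert out.empty

    def test_estimated_floor_matches_direct_threshold(self):
        rng = np.random.default_rng(0)
        signal = rng.uniform(5e4, 1e5, 90)
        floor = rng.uniform(9., 11., 10)
        peaks = pd.DataFrame({"mz": np.arange(100.),
                              "intensity": np.concatenate([signal, floor])})
        out, mdl = mdl_filter(peaks, mdl_factor=2.0)
        # noise level = median of lowest decile = median(floor)
        expect = peaks[peaks["intensity"] >= 2 * np.median(floor)]
        pd.testing.assert_frame_equal(out, expect)


class TestRecalibration:
    def _calibrants(self, formulas):
        return [(f, f.mz_neg) for f in formulas]

    def test_constant_shift_removed(self):
        pool = syn.sample_formula_pool(30, seed=1)
        peaks = spectrum_from(pool, ppm_shift=0.3)
        out = recalibrate(peaks, self._calibrants(pool[:10]))
        residual = (out["mz"].to_numpy()
                    - np.array([f.mz_neg for f in pool]))
        residual_ppm = residual / out["mz"].to_numpy() * 1e6
        assert np.abs(residual_ppm).max() < 1e-4

    def test_zero_shift_is_identity(self):
        pool = syn.sample_formula_pool(20, seed=2)
        peaks = spectrum_from(pool)
        out = recalibrate(peaks, self._calibrants(pool[:5]))
        assert np.allclose(out["mz"], peaks["mz"], rtol=1e-12)

    def test_idempotence(self):
        pool = syn.sample_formula_pool(20, seed=3)
        peaks = spectrum_from(pool, ppm_shift=0.25)
        cal = self._calibrants(pool[:8])
        once = recalibrate(peaks, cal)
        twice = recalibrate(once, cal)
        delta_ppm = ((twice["mz"] - once["mz"]) / once["mz"] * 1e6).abs()
        assert delta_ppm.max() < 1e-6

    def test_too_few_calibrants_is_an_explicit_error(self):
        pool = syn.sample_formula_pool(20, seed=4)
        peaks = spectrum_from(pool)
        with pytest.raises(ValueError, match="skip recalibration"):
            recalibrate(peaks, self._calibrants(pool[:2]))

    def test_weak_calibrants_excluded_by_signal_ratio(self):
        pool = syn.sample_formula_pool(10, seed=5)
        peaks = spectrum_from(pool)
        peaks.loc[:7, "intensity"] = 3.0  # below 5 x MDL; 2 calibrants left
        with pytest.raises(ValueError):
            recalibrate(peaks, self._calibrants(pool), mdl=1.0)


class TestAssignment:
    def test_noiseless_spectrum_fully_correct(self):
        pool = syn.sample_formula_pool(300, seed=6)
        peaks = spectrum_from(pool)
        out = assign_formulas(peaks)
        assert list(out["formula"]) == [f.hill() for f in pool]
        assert out["mass_error_ppm"].abs().max() < 1e-5
        assert (out["series_support"] >= 1).all()

    def test_zero_tolerance_still_exact(self):
        pool = syn.sample_formula_pool(50, seed=7)
        out = assign_formulas(spectrum_from(pool), tolerance_ppm=0.0)
        assert list(out["formula"]) == [f.hill() for f in pool]

    def test_lone_peak_without_series_partner_unassigned(self):
        peaks = spectrum_from([F("C6H10O5")])
        out = assign_formulas(peaks, min_series_links=1)
        assert out["formula"].iloc[0] == ""

    def test_min_links_zero_accepts_lone_peak(self):
        peaks = spectrum_from([F("C6H10O5")])
        out = assign_formulas(peaks, min_series_links=0)
        assert out["formula"].iloc[0] == "C6H10O5"

    def test_noisy_spectrum_high_accuracy(self):
        pool = syn.sample_formula_pool(300, seed=8)
        rng = np.random.default_rng(0)
        mz = np.array([f.mz_neg for f in pool])
        mz = mz * (1 + rng.normal(0, 0.1, len(mz)) * 1e-6)
        peaks = pd.DataFrame({"mz": mz, "intensity": np.full(len(mz), 1e5)})
        out = assign_formulas(peaks)
        correct = (out["formula"] == [f.hill() for f in pool]).mean()
        assert correct >= 0.99


class TestIsotopeVerification:
    def _with_isotope(self, f: MolecularFormula, ratio_factor=1.0):
        base = 1e5
        peaks = pd.DataFrame({
            "mz": [f.mz_neg, f.mz_neg + C13_DELTA],
            "intensity": [base, base * C13_ABUNDANCE * f.c * ratio_factor],
        })
        assignments = pd.DataFrame({
            "mz": [f.mz_neg], "intensity": [base],
            "formula": [f.hill()], "mass_error_ppm": [0.0],
            "series_support": [1],
        })
        return assignments, peaks

    def test_consistent_ratio_retained(self):
        a, p = self._with_isotope(F("C20H24O10"))
        out = verify_isotopes(a, p, mdl=1.0)
        assert out["isotope_check"].iloc[0] == "ok"

    def test_threefold_ratio_removed(self):
        # deviation 2000 permil exceeds the 1000 permil tolerance
        a, p = self._with_isotope(F("C20H24O10"), ratio_factor=3.0)
        out = verify_isotopes(a, p, mdl=1.0)
        assert out["isotope_check"].iloc[0] == "mismatch"

    def test_missing_isotope_peak_retained(self):
        f = F("C20H24O10")
        a, p = self._with_isotope(f)
        out = verify_isotopes(a, p.iloc[:1], mdl=1.0)
        assert out["isotope_check"].iloc[0] == "no_isotope"

    def test_weak_isotope_signal_not_judged(self):
        a, p = self._with_isotope(F("C20H24O10"), ratio_factor=3.0)
        out = verify_isotopes(a, p, mdl=p["intensity"].iloc[1])
        assert out["isotope_check"].iloc[0] == "no_isotope"


class TestBlankRemoval:
    def _long(self):
        return pd.DataFrame({
            "sample_id": ["s1", "s1", "s2", "b1"],
            "formula": ["C6H10O5", "C16H10", "C6H10O5", "C16H10"],
            "intensity": [1., 2., 3., 4.],
        })

    def test_blank_formula_removed_everywhere(self):
        out, n = remove_blank_peaks(self._long(), ["b1"])
        assert n == 1
        assert "C16H10" not in set(out["formula"])
        assert set(out["sample_id"]) == {"s1", "s2"}

    def test_disjoint_blank_is_identity(self):
        long = self._long().replace({"formula": {"C16H10": "C5H8O4"}})
        long.loc[long["sample_id"] == "b1", "formula"] = "C30H50O1"
        out, n = remove_blank_peaks(long, ["b1"])
        assert n == 1  # the blank-only contaminant itself
        assert set(out.loc[out["sample_id"] != "b1", "formula"]) == \
            {"C6H10O5", "C5H8O4"}

    def test_no_blanks_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="no blank"):
            out, n = remove_blank_peaks(self._long(), [])
        assert n == 0 and len(out) == 4


class TestDuplicateMerging:
    def _manifest(self, n_samples=1):
        rows = []
        for i in range(n_samples):
            for r in (1, 2):
                rows.append({"sample_id": f"H_DOM_light_T{i}_R{r}",
                             "habitat": "H", "pool": "DOM",
                             "condition": "light", "time_days": float(i),
                             "replicate": r, "is_blank": False})
        return pd.DataFrame(rows)

    def test_single_replicate_formula_dropped(self):
        long = pd.DataFrame({
            "sample_id": ["H_DOM_light_T0_R1"] * 2 + ["H_DOM_light_T0_R2"],
            "formula": ["C6H10O5", "C16H10", "C6H10O5"],
            "intensity": [10., 5., 20.],
        })
        m = merge_duplicates(long, self._manifest())
        assert list(m.data.index) == ["C6H10O5"]
        assert m.duplicate_dropped == 1
        assert m.data.iloc[0, 0] == pytest.approx(1.0)

    def test_identical_replicates_merge_to_normalized_copy(self):
        long = pd.DataFrame({
            "sample_id": ["H_DOM_light_T0_R1"] * 2 + ["H_DOM_light_T0_R2"] * 2,
            "formula": ["C6H10O5", "C16H10"] * 2,
            "intensity": [30., 10.] * 2,
        })
        m = merge_duplicates(long, self._manifest())
        assert m.data["H_DOM_light_T0"].to_dict() == pytest.approx(
            {"C16H10": 0.25, "C6H10O5": 0.75})

    def test_missing_replicate_error_names_sample(self):
        manifest = self._manifest().iloc[:1]
        long = pd.DataFrame({"sample_id": ["H_DOM_light_T0_R1"],
                             "formula": ["C6H10O5"], "intensity": [1.]})
        with pytest.raises(ValueError, match="H_DOM_light_T0"):
            merge_duplicates(long, manifest)

    def test_columns_sum_to_one(self, noisy_run):
        sums = noisy_run.matrix.data.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestPipelineHygiene:
    def test_blank_and_merge_commute_at_zero_noise(self, small_experiment):
        """Removing blank formulae before or after merging yields the same
        matrix once columns are re-normalized."""
        exp = small_experiment
        params = EngineParams(noise_level=1.0)
        matrix, audit = process_peaks(exp.peaks, exp.manifest, params)

        # rebuild the long table from the engine's own audit, then apply
        # the two steps in the opposite order
        long = audit[(audit["formula"] != "")
                     & audit["isotope_check"].isin(("ok", "no_isotope"))]
        long = long[["sample_id", "formula", "intensity"]]
        blank_ids = set(exp.manifest.loc[exp.manifest["is_blank"],
                                         "sample_id"])
        contaminated = set(long.loc[long["sample_id"].isin(blank_ids),
                                    "formula"])
        merged_first = merge_duplicates(long, exp.manifest)
        alt = merged_first.data.drop(
            index=[f for f in contaminated if f in merged_first.data.index])
        alt = alt / alt.sum(axis=0)

        pd.testing.assert_frame_equal(
            matrix.data.sort_index(), alt.sort_index(),
            check_exact=False, atol=1e-12)

    def test_no_contaminant_survives(self, noisy_run):
        surviving = set(noisy_run.matrix.data.index) & set(
            noisy_run.exp.contaminants)
        assert not surviving

    def test_dropped_formulas_absent_from_their_sample(self, noisy_run):
        exp = noisy_run.exp
        data = noisy_run.matrix.data
        for formula, mid in exp.dropped:
            base = mid.rsplit("_R", 1)[0]
            if formula in data.index and base in data.columns:
                assert data.at[formula, base] == 0.0
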