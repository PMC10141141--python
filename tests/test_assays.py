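import numpy as np
import pandas as pd
import pytest

import txrescue as tx
from txrescue import DataError, assays


class TestPercentInhibition:
    def test_endpoint_cases(self):
        # signal equal to the media blank: fully inhibited
        assert assays.percent_inhibition(0.2, 0.2, 1.0) == pytest.approx(100.0)
        # signal a full untransfected-control above the blank: fully viable
        assert assays.percent_inhibition(1.2, 0.2, 1.0) == pytest.approx(0.0)
        # half-signal: the TC50 crossing level
        assert assays.percent_inhibition(0.7, 0.2, 1.0) == pytest.approx(50.0)

    def test_affine_with_expected_slope(self):
        mean_untransfected = 0.8
        grid = np.linspace(0.0, 2.0, 9)
        values = assays.percent_inhibition(grid, 0.1, mean_untransfected)
        slopes = np.diff(values) / np.diff(grid)
        assert np.allclose(slopes, -100.0 / mean_untransfected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DataError):
            assays.percent_inhibition(0.5, 0.1, 0.0)


class TestFitTc50:
    def test_noise_free_recovery_to_four_significant_figures(self):
        curve = tx.generate_dose_response(150.0, hill=1.3, noise_sd=0.0, seed=0)
        fit = assays.fit_tc50(curve["dose_nm"], curve["response_pct"])
        assert fit.converged and not fit.degenerate
        assert fit.tc50_nm == pytest.approx(150.0, rel=1e-4)
        assert fit.hill == pytest.approx(1.3, rel=1e-4)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(100.0, rel=1e-6)

    def test_free_asymptote_fit_also_exact_on_clean_data(self):
        curve = tx.generate_dose_response(150.0, hill=1.0, noise_sd=0.0, seed=0)
        fit = assays.fit_tc50(curve["dose_nm"], curve["response_pct"], free_asymptotes=True)
        assert fit.tc50_nm == pytest.approx(150.0, rel=1e-4)
        assert fit.bottom == pytest.approx(0.0, abs=1e-3)
        assert fit.top == pytest.approx(100.0, rel=1e-3)

    def test_flat_data_flagged_degenerate(self):
        doses = [2.0, 10.0, 50.0, 200.0]
        fit = assays.fit_tc50(doses, [40.0, 40.0, 40.0, 40.0])
        assert fit.degenerate and not fit.converged
        assert np.isnan(fit.tc50_nm)

    def test_too_few_doses_rejected(self):
        with pytest.raises(DataError, match="4 distinct"):
            assays.fit_tc50([1.0, 10.0, 100.0], [5.0, 50.0, 95.0])

    def test_tc50_is_on_the_concentration_scale(self):
        curve = tx.generate_dose_response(500.0, noise_sd=0.0, seed=0)
        fit = assays.fit_tc50(curve["dose_nm"], curve["response_pct"])
        assert fit.tc50_nm == pytest.approx(10.0 ** fit.log_tc50)


class TestDdct:
    def _records(self, groups):
        rows = []
        for group, samples in groups.items():
            for name, (ct_t, ct_r) in samples.items():
                rows.append({"group": group, "sample": name, "ct_target": ct_t, "ct_reference": ct_r})
        return pd.DataFrame(rows)

    def test_calibrator_is_exactly_one(self):
        records = self._records(
            {"Scramble": {"s1": (24.0, 18.0), "s2": (24.3, 18.2)},
             "Treated": {"t1": (23.0, 18.1), "t2": (23.2, 18.0)}}
        )
        out = assays.relative_expression_ddct(records, "Scramble")
        assert out.loc["Scramble", "rel_expression"] == 1.0

    def test_one_cycle_shift_doubles_expression(self):
        records = self._records(
            {"Scramble": {"s1": (24.0, 18.0)}, "Treated": {"t1": (23.0, 18.0)}}
        )
        out = assays.relative_expression_ddct(records, "Scramble")
        assert out.loc["Treated", "rel_expression"] == pytest.approx(2.0)

    def test_matches_spreadsheet_style_recomputation(self, rng):
        groups = {
            g: {f"{g}{i}": (float(rng.uniform(20, 30)), float(rng.uniform(15, 20))) for i in range(4)}
            for g in ("Scramble", "A", "B")
        }
        out = assays.relative_expression_ddct(self._records(groups), "Scramble")
        # oracle: average dCt per group, subtract calibrator, 2^-ddCt
        dct = {g: np.mean([t - r for t, r in samples.values()]) for g, samples in groups.items()}
        for g in groups:
            expected = 2.0 ** (-(dct[g] - dct["Scramble"]))
            assert out.loc[g, "rel_expression"] == pytest.approx(expected)

    def test_invariant_to_constant_ct_shift(self, rng):
        records = self._records(
            {"Scramble": {"s1": (24.0, 18.0), "s2": (25.0, 18.5)},
             "Treated": {"t1": (22.0, 18.3), "t2": (22.5, 18.1)}}
        )
        shifted = records.copy()
        shifted[["ct_target", "ct_reference"]] += 3.0
        a = assays.relative_expression_ddct(records, "Scramble")
        b = assays.relative_expression_ddct(shifted, "Scramble")
        assert np.allclose(a["rel_expression"], b["rel_expression"])

    def test_technical_replicates_averaged_per_sample_first(self):
        records = pd.DataFrame(
            {
                "group": ["Scramble", "Scramble", "Treated", "Treated"],
                "sample": ["s1", "s1", "t1", "t1"],
                "ct_target": [24.0, 26.0, 23.0, 25.0],
                "ct_reference": [18.0, 18.0, 18.0, 18.0],
            }
        )
        out = assays.relative_expression_ddct(records, "Scramble")
        assert out.loc["Treated", "rel_expression"] == pytest.approx(2.0)
        assert (out["n_samples"] == 1).all()

    def test_missing_ct_rejected(self):
        records = self._records({"Scramble": {"s1": (24.0, float("nan"))}})
        with pytest.raises(DataError, match="missing Ct"):
            assays.relative_expression_ddct(records, "Scramble")


class TestImaging:
    def test_sum_over_area(self):
        assert assays.mean_pixel_intensity(1000.0, 100.0) == pytest.approx(10.0)
        assert assays.mean_pixel_intensity(0.0, 50.0) == 0.0
        with pytest.raises(DataError):
            assays.mean_pixel_intensity(10.0, 0.0)

    def test_image_helper_matches_pixel_loop_oracle(self, rng):
        image = rng.uniform(0, 60, size=(20, 25))
        threshold = 10.0
        total, area = 0.0, 0
        for value in image.ravel():
            if value >= threshold:
                total += value
                area += 1
        expected = total / area
        assert assays.mean_pixel_intensity_from_image(image, threshold) == pytest.approx(expected)


class TestGripAndFibers:
    def test_percent_normal_force_direct_cases(self):
        assert assays.percent_normal_force([100, 100, 100], [100, 100, 100], 25.0) == pytest.approx(4.0)
        assert assays.percent_normal_force([100, 100, 100], [200, 200, 200], 25.0) == pytest.approx(8.0)

    def test_matches_brute_force_on_random_trials(self, rng):
        pre = rng.uniform(80, 120, 3)
        post = rng.uniform(80, 160, 3)
        weight = float(rng.uniform(20, 30))
        expected = 100.0 * (sum(post) / 3) / (sum(pre) / 3) / weight
        assert assays.percent_normal_force(pre, post, weight) == pytest.approx(expected)

    def test_degenerate_grip_inputs_rejected(self):
        with pytest.raises(DataError):
            assays.percent_normal_force([0.0, 0.0, 0.0], [50.0, 60.0, 70.0], 25.0)
        with pytest.raises(DataError):
            assays.percent_normal_force([100.0], [100.0], 0.0)

    def test_central_nuclei_percent(self):
        assert assays.central_nuclei_percent(50, 500) == pytest.approx(10.0)
        assert assays.central_nuclei_percent(0, 500) == 0.0
        with pytest.raises(DataError):
            assays.central_nuclei_percent(501, 500)
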