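import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aspdyn.isotopes import (
    CalibrationCurve,
    IsotopologueDistribution,
    convolve_natural_abundance,
    correct_natural_abundance,
    denovo_fraction_via_aspartate,
    fit_calibration,
    fold_change,
    guanine_salvage_fraction,
    purine_salvage_fraction_atp,
    quantify,
)
from aspdyn.synth import GeneratorSpec, gen_calibration, gen_isotopologues


def dist(fractions, compound="GTP", tracer="amide-15N-Gln"):
    return IsotopologueDistribution(compound=compound, tracer=tracer, fractions=fractions)


class TestNaturalAbundanceCorrection:
    def test_zero_abundance_is_identity(self):
        raw = np.array([3.0, 1.0, 0.5, 0.25, 0.25])
        out = correct_natural_abundance(raw, n_atoms=4, abundance=0.0)
        assert np.allclose(out.fractions, raw / raw.sum(), atol=1e-12)

    def test_pure_unlabeled_round_trip(self):
        true = np.array([1.0, 0, 0, 0, 0])
        measured = convolve_natural_abundance(true, n_atoms=4)
        out = correct_natural_abundance(measured, n_atoms=4)
        assert np.allclose(out.fractions, true, atol=1e-6)

    @given(
        weights=st.lists(st.floats(0, 1), min_size=7, max_size=7).filter(
            lambda w: sum(w) > 1e-6
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_over_simplex(self, weights):
        true = np.asarray(weights) / np.sum(weights)
        measured = convolve_natural_abundance(true, n_atoms=6)
        out = correct_natural_abundance(measured, n_atoms=6)
        assert np.allclose(out.fractions, true, atol=1e-6)

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            correct_natural_abundance([0.0, 0.0, 0.0], n_atoms=2)

    def test_too_many_atoms_rejected(self):
        with pytest.raises(ValueError, match="ill-conditioned"):
            correct_natural_abundance(np.ones(62), n_atoms=61)

    def test_distributions_normalize_to_one(self):
        out = correct_natural_abundance([5.0, 2.0, 1.0], n_atoms=2)
        assert out.fractions.sum() == pytest.approx(1.0, abs=1e-9)


class TestSalvageFractions:
    @pytest.mark.parametrize(
        "fractions, expected",
        [([0, 0, 0, 1.0], 0.0), ([1.0, 0, 0, 0], 1.0), ([0.25, 0, 0, 0.75], 0.25)],
    )
    def test_guanine_salvage_from_gtp(self, fractions, expected):
        assert guanine_salvage_fraction(dist(fractions)) == pytest.approx(expected)

    def test_guanine_salvage_mixing_oracle(self):
        # mixing pure-salvage and pure-de-novo pools at weight w gives
        # exactly m0 = w, m3 = 1 - w, so the estimator recovers w
        for w in (0.1, 0.4, 0.8):
            mixture = w * np.array([1.0, 0, 0, 0]) + (1 - w) * np.array([0, 0, 0, 1.0])
            assert guanine_salvage_fraction(dist(mixture)) == pytest.approx(w, rel=1e-12)

    def test_guanine_salvage_requires_informative_signal(self):
        with pytest.raises(ValueError, match="no informative signal"):
            guanine_salvage_fraction(dist([0, 1.0, 1.0, 0]))

    def test_wrong_tracer_rejected(self):
        with pytest.raises(ValueError, match="amide"):
            guanine_salvage_fraction(dist([1, 0, 0, 0], tracer="U-13C-Gln"))

    @pytest.mark.parametrize(
        "fractions, expected", [([0, 0, 1.0], 0.0), ([0.5, 0, 0.5], 0.5)]
    )
    def test_purine_salvage_from_atp(self, fractions, expected):
        assert purine_salvage_fraction_atp(dist(fractions, "ATP")) == pytest.approx(expected)

    def test_purine_salvage_strict_m0_variant(self):
        d = dist([0.3, 0.4, 0.3], "ATP")
        assert purine_salvage_fraction_atp(d, strict_m0=True) == pytest.approx(0.3)
        assert purine_salvage_fraction_atp(d) == pytest.approx(0.5)

    def test_purine_salvage_multinomial_recovery(self):
        d = gen_isotopologues(0.3, "amide-15N-Gln", "ATP", 10**5, GeneratorSpec(seed=5))
        assert purine_salvage_fraction_atp(d) == pytest.approx(0.30, abs=0.01)

    def test_estimator_consistency_with_ion_count(self):
        errs = {}
        for n_ions in (10**3, 10**6):
            estimates = [
                guanine_salvage_fraction(
                    gen_isotopologues(0.25, "amide-15N-Gln", "GTP", n_ions,
                                      GeneratorSpec(seed=100 + i))
                )
                for i in range(20)
            ]
            errs[n_ions] = np.sqrt(np.mean((np.array(estimates) - 0.25) ** 2))
        assert errs[10**6] < errs[10**3]

    @pytest.mark.parametrize(
        "product_m1, precursor_m1, expected",
        [(0.5, 0.5, 1.0), (0.25, 0.5, 0.5), (0.0, 0.5, 0.0)],
    )
    def test_denovo_fraction_ratio(self, product_m1, precursor_m1, expected):
        assert denovo_fraction_via_aspartate(product_m1, precursor_m1) == pytest.approx(expected)

    def test_denovo_fraction_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            assert denovo_fraction_via_aspartate(0.6, 0.5) == 1.0

    def test_denovo_fraction_zero_precursor_rejected(self):
        with pytest.raises(ValueError):
            denovo_fraction_via_aspartate(0.1, 0.0)


class TestCalibration:
    def dilution(self, n=12, top=500.0):
        return top / 2.0 ** np.arange(n)

    def test_noiseless_linear_selected_with_exact_slope(self):
        x = self.dilution()
        curve = fit_calibration(x, 0.1 * x)
        assert curve.model == "linear"
        assert curve.params[0] == pytest.approx(0.1, rel=1e-9)
        assert curve.valid_range == (pytest.approx(500 / 2**11), 500.0)

    def test_noiseless_power_selected_with_exact_exponent(self):
        x = self.dilution()
        curve = fit_calibration(x, 0.02 * x**0.9)
        assert curve.model == "power"
        assert curve.params[1] == pytest.approx(0.9, abs=1e-6)

    def test_noiseless_quadratic_selected(self):
        x = self.dilution()
        curve = fit_calibration(x, 1e-4 * x**2 + 0.05 * x + 0.01)
        assert curve.model == "quadratic"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_calibration([1, 2, 4], [0.1, 0.2, 0.4])

    def test_non_monotonic_candidates_rejected(self):
        # symmetric rise-and-fall: the OLS line is exactly flat, the
        # quadratic has its vertex mid-range, and the zero responses rule
        # out the power family — no invertible candidate remains
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="monotonic"):
            fit_calibration(x, y)

    @pytest.mark.parametrize(
        "truth",
        [
            CalibrationCurve("linear", (0.1, 0.0), (0.24, 500.0)),
            CalibrationCurve("power", (0.02, 0.9), (0.24, 500.0)),
            CalibrationCurve("quadratic", (1e-4, 0.05, 0.01), (0.24, 500.0)),
        ],
        ids=["linear", "power", "quadratic"],
    )
    def test_noisy_recovery_within_5pct(self, truth):
        table = gen_calibration(truth, GeneratorSpec(seed=3, noise_cv=0.03, n_replicates=3))
        curve = fit_calibration(table["concentration_uM"], table["response_ratio"])
        # compare predicted responses across the range, not raw coefficients
        grid = np.geomspace(1.0, 500.0, 20)
        assert np.allclose(curve.predict(grid), truth.predict(grid), rtol=0.05)


class TestQuantify:
    linear = CalibrationCurve("linear", (0.1, 0.0), (0.244140625, 500.0))

    def test_closed_form_chain(self):
        res = quantify(50.0, 100.0, self.linear, reconstitution_volume_uL=40.0,
                       total_cell_volume_uL=1.0)
        assert res.in_range
        assert res.vial_concentration_uM == pytest.approx(5.0, rel=1e-9)
        assert res.intracellular_mM == pytest.approx(0.2, rel=1e-9)

    def test_ratio_above_top_standard_discarded(self):
        res = quantify(60.0, 1.0, self.linear, 40.0, 1.0)
        assert not res.in_range
        assert np.isnan(res.intracellular_mM)

    def test_zero_area_below_range_discarded(self):
        res = quantify(0.0, 100.0, self.linear, 40.0, 1.0)
        assert not res.in_range

    def test_round_trip_through_fitted_curve(self):
        x = 500.0 / 2 ** np.arange(12)
        curve = fit_calibration(x, 0.02 * x**0.9)
        target_vial = 20.0
        res = quantify(float(curve.predict(target_vial)), 1.0, curve, 40.0, 2.0)
        assert res.vial_concentration_uM == pytest.approx(target_vial, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            quantify(1.0, 0.0, self.linear, 40.0, 1.0)
        with pytest.raises(ValueError):
            quantify(1.0, 1.0, self.linear, 0.0, 1.0)


class TestFoldChange:
    def test_succinate_accumulation_is_70_fold(self):
        assert fold_change(14.0, 0.2) == pytest.approx(70.0)

    def test_equal_concentrations(self):
        assert fold_change(3.3, 3.3) == 1.0

    def test_zero_treated(self):
        assert fold_change(0.0, 1.0) == 0.0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)
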