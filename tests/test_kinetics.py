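"""Standard curves, initial rates, MM / substrate-inhibition fits,
efficiency propagation and mutant normalization."""

import numpy as np
import pytest

from fkpkit.kinetics import (
    efficiency,
    fit_mm,
    fit_standard_curve,
    fit_substrate_inhibition,
    initial_rate,
    normalize_mutant,
    pi_to_ppi_rate,
    round_sig,
)
from fkpkit.simulate import KineticTruth, gen_rate_data, mm_rate

# NADH extinction at 340 nm, 6220 /M/cm with a 1 cm path: 0.00622 AU/uM
NADH_CURVE = fit_standard_curve([0.0, 100.0], [0.0, 0.622])


class TestStandardCurve:
    def test_two_point_slope(self):
        assert NADH_CURVE.slope == pytest.approx(0.00622)
        assert NADH_CURVE.intercept == pytest.approx(0.0)

    def test_perfect_line_r_squared(self):
        c = np.array([0, 25, 50, 100.0])
        curve = fit_standard_curve(c, 0.004 * c + 0.01)
        assert curve.r_squared == pytest.approx(1.0)

    def test_inverse_round_trip(self):
        for conc in (0.0, 12.5, 300.0):
            assert NADH_CURVE.inverse(NADH_CURVE.predict(conc)) == pytest.approx(conc)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([5.0, 5.0], [0.1, 0.1])


class TestInitialRate:
    def test_falling_a340_gives_positive_rate(self):
        t = np.arange(0, 60, 10.0)
        A = 1.0 - 0.00622 * t  # 1 uM/s of NADH consumption
        rate = initial_rate(t, A, NADH_CURVE, wavelength_nm=340)
        assert rate == pytest.approx(1.0)

    def test_rising_a635_gives_positive_rate(self):
        t = np.arange(0, 60, 10.0)
        curve = fit_standard_curve([0, 100.0], [0.0, 0.4])
        rate = initial_rate(t, 0.004 * t, curve, wavelength_nm=635)
        assert rate == pytest.approx(1.0)

    def test_flat_trace_zero(self):
        t = np.arange(0, 60, 10.0)
        assert initial_rate(t, np.full_like(t, 0.5), NADH_CURVE) == 0.0

    def test_two_point_window_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            initial_rate([0, 10], [1.0, 0.9], NADH_CURVE)

    def test_nonlinear_window_warns(self, caplog):
        t = np.arange(0, 60, 5.0)
        A = 1.0 / (1.0 + t)  # strongly curved
        with caplog.at_level("WARNING"):
            initial_rate(t, A, NADH_CURVE)
        assert "nonlinear" in caplog.text


class TestFitMM:
    def test_noiseless_recovery(self):
        truth = KineticTruth(KM=77.0, kcat=0.90, E0=0.277, noise_cv=0.0)
        concs = 77.0 * np.array([0.25, 0.5, 1, 2, 3, 5, 8, 10])
        data = gen_rate_data(truth, concs, n_reps=3)
        fit = fit_mm(data, 0.277)
        assert fit.KM == pytest.approx(77.0, rel=1e-6)
        assert fit.kcat == pytest.approx(0.90, rel=1e-6)
        assert fit.model == "mm"

    def test_single_substrate_level_unidentifiable(self):
        truth = KineticTruth(KM=77.0, kcat=0.90, E0=0.277, noise_cv=0.0)
        data = gen_rate_data(truth, [77.0] * 6, n_reps=1)
        with pytest.raises(ValueError, match="distinct substrate"):
            fit_mm(data, 0.277)

    def test_efficiency_consistent_with_parameters(self):
        truth = KineticTruth(KM=50.0, kcat=2.0, E0=0.1, noise_cv=0.0)
        data = gen_rate_data(truth, [10, 25, 50, 100, 250.0], n_reps=2)
        fit = fit_mm(data, 0.1)
        eff, _ = fit.efficiency
        assert eff == pytest.approx(fit.kcat / (fit.KM * 1e-6))


class TestFitSubstrateInhibition:
    TRUTH = KineticTruth(KM=1000.0, kcat=0.74, E0=0.277, Ki=9000.0, noise_cv=0.0)
    CONCS = [100, 300, 700, 1500, 3000, 5000, 8000, 12000, 20000.0]

    def test_noiseless_exact_recovery(self):
        data = gen_rate_data(self.TRUTH, self.CONCS, n_reps=2,
                             model="substrate_inhibition")
        fit = fit_substrate_inhibition(data, 0.277)
        assert fit.KM == pytest.approx(1000.0, rel=1e-5)
        assert fit.kcat == pytest.approx(0.74, rel=1e-5)
        assert fit.Ki == pytest.approx(9000.0, rel=1e-5)
        assert fit.peak_substrate == pytest.approx(3000.0, rel=1e-5)
        assert fit.model == "substrate_inhibition"

    def test_monotone_mm_data_prefers_mm(self):
        truth = KineticTruth(KM=77.0, kcat=0.9, E0=0.277, noise_cv=0.02)
        data = gen_rate_data(truth, 77.0 * np.array([0.25, 0.5, 1, 2, 5, 10]),
                             n_reps=3, seed=4)
        fit = fit_substrate_inhibition(data, 0.277)
        assert "mm_preferred" in fit.model
        assert fit.Ki > 100 * 770.0

    def test_noisy_peak_within_ten_percent(self):
        truth = KineticTruth(KM=1000.0, kcat=0.74, E0=0.277, Ki=9000.0,
                             noise_cv=0.05)
        data = gen_rate_data(truth, self.CONCS, n_reps=3,
                             model="substrate_inhibition", seed=8)
        fit = fit_substrate_inhibition(data, 0.277)
        assert fit.peak_substrate == pytest.approx(3000.0, rel=0.10)

    def test_too_few_levels_rejected(self):
        data = gen_rate_data(self.TRUTH, [100, 300, 1000, 3000.0], n_reps=1,
                             model="substrate_inhibition")
        with pytest.raises(ValueError, match="5 substrate"):
            fit_substrate_inhibition(data, 0.277)


class TestEfficiency:
    @pytest.mark.parametrize(
        "kcat, kcat_sd, km, km_sd, eff_expect, sd_expect, sd_sig",
        [
            (0.90, 0.07, 77.0, 19.0, 1.2e4, 0.3e4, 1),
            (8.0, 1.1, 27.0, 11.0, 3.0e5, 1.3e5, 2),
        ],
    )
    def test_printed_table_values(self, kcat, kcat_sd, km, km_sd,
                                  eff_expect, sd_expect, sd_sig):
        eff, sd = efficiency(kcat, kcat_sd, km, km_sd)
        assert round_sig(eff, 2) == pytest.approx(eff_expect)
        assert round_sig(sd, sd_sig) == pytest.approx(sd_expect)

    def test_zero_uncertainty(self):
        eff, sd = efficiency(1.0, 0.0, 100.0, 0.0)
        assert eff == pytest.approx(1e4) and sd == 0.0

    def test_invalid_central_values(self):
        with pytest.raises(ValueError):
            efficiency(1.0, 0.1, 0.0, 0.1)


class TestNormalizeMutant:
    def test_identical_to_wildtype_is_100(self):
        pct, sd, nd = normalize_mutant([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert pct == 100.0 and not nd

    def test_half_activity_scaled_sd(self):
        wt = [1.8, 2.0, 2.2]  # mean 2.0
        mut = [0.9, 1.0, 1.1]  # mean 1.0, sd 0.1
        pct, sd, nd = normalize_mutant(wt, mut)
        assert pct == pytest.approx(50.0)
        assert sd == pytest.approx(5.0)

    def test_below_floor_not_detected(self):
        pct, sd, nd = normalize_mutant([2.0, 2.0, 2.0], [0.001, 0.0, 0.002],
                                       detection_floor=0.01)
        assert nd and pct is None

    def test_too_few_replicates(self):
        with pytest.raises(ValueError, match="3 replicates"):
            normalize_mutant([1.0, 1.0], [1.0, 1.0, 1.0])

    def test_nonpositive_wildtype(self):
        with pytest.raises(ValueError):
            normalize_mutant([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])


class TestPiToPPi:
    def test_factor_two_halves(self):
        assert pi_to_ppi_rate(2.0) == 1.0

    def test_factor_one_identity(self):
        assert pi_to_ppi_rate(3.5, 1.0) == 3.5

    def test_saturating_pyrophosphorylase_stoichiometry(self):
        # kcat 8.0/s at 40 nM enzyme, saturating substrate: v = 0.32 uM/s,
        # hence 0.64 uM/s of phosphate appears after PPi hydrolysis
        v = float(mm_rate(np.array([1e7]), 27.0, 8.0, 0.040)[0])
        assert v == pytest.approx(0.32, rel=1e-3)
        assert pi_to_ppi_rate(2 * v) == pytest.approx(v)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            pi_to_ppi_rate(1.0, 0.0)
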