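"""Hydrodynamic calibration, peak location and molecular-weight inference."""

import numpy as np
import pytest

from kifquant import synthgen as sg
from kifquant.hydro import (
    CalibrationError,
    CalibrationLine,
    CalibrationStandard,
    ElutionProfile,
    NonPhysicalError,
    NoPeakError,
    analyze_sample,
    fit_calibration,
    frictional_ratio,
    invert_calibration,
    locate_peak,
    molecular_weight,
    s_max,
)


def _standards_on_line(line, anchors, transform):
    out = []
    for i, a in enumerate(anchors):
        y = np.log10(a) if transform == "log10_anchor" else a
        v = (y - line.intercept) / line.slope
        out.append(CalibrationStandard(f"std{i}", a, v))
    return out


class TestFitCalibration:
    def test_exact_interpolation_sec_line(self):
        stds = _standards_on_line(sg.SEC_LINE, [8.5, 3.48], "log10_anchor")
        line = fit_calibration(stds, "log10_anchor")
        assert line.slope == pytest.approx(-0.014, abs=1e-12)
        assert line.intercept == pytest.approx(0.97, abs=1e-10)

    def test_gradient_standards_on_printed_line(self):
        stds = _standards_on_line(
            sg.GRADIENT_LINE, [17.6, 11.3, 8.0, 4.6], "identity_anchor"
        )
        line = fit_calibration(stds, "identity_anchor")
        assert line.slope == pytest.approx(5.66, abs=1e-9)
        assert line.intercept == pytest.approx(-3.92, abs=1e-9)
        assert line.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_order_invariance(self):
        stds = _standards_on_line(
            sg.GRADIENT_LINE, [17.6, 11.3, 8.0, 4.6], "identity_anchor"
        )
        a = fit_calibration(stds, "identity_anchor")
        b = fit_calibration(stds[::-1], "identity_anchor")
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(CalibrationError):
            fit_calibration([CalibrationStandard("one", 5.0, 1.0)])
        with pytest.raises(CalibrationError):
            fit_calibration(
                [CalibrationStandard("a", 5.0, 1.0), CalibrationStandard("b", 6.0, 1.0)]
            )

    def test_se_shrinks_with_replication(self):
        rng = np.random.default_rng(0)
        base = _standards_on_line(
            sg.GRADIENT_LINE, [17.6, 11.3, 8.0, 4.6], "identity_anchor"
        )

        def replicated(n_rep, rng):
            stds = []
            for _ in range(n_rep):
                for s in base:
                    stds.append(
                        CalibrationStandard(
                            s.name, s.anchor_value,
                            s.elution_volume + rng.normal(0, 0.05),
                        )
                    )
            return fit_calibration(stds, "identity_anchor").slope_se

        se2 = np.mean([replicated(2, np.random.default_rng(i)) for i in range(30)])
        se8 = np.mean([replicated(8, np.random.default_rng(i)) for i in range(30)])
        assert se8 < se2


class TestLocatePeak:
    def test_noiseless_gaussian_centre(self):
        v = np.arange(0, 5, 0.2)
        y = 100 * np.exp(-0.5 * ((v - 2.1) / 0.3) ** 2)
        centre, err = locate_peak(ElutionProfile(v, y))
        assert centre == pytest.approx(2.1, abs=1e-6)
        assert err == pytest.approx(0.1, abs=1e-9)  # half of 0.2 ml fractions

    def test_two_point_tie_returns_midpoint(self):
        v = np.arange(0, 2, 0.2)
        y = np.array([0, 1, 5, 5, 1, 0, 0, 0, 0, 0], dtype=float)
        centre, _ = locate_peak(ElutionProfile(v, y))
        assert centre == pytest.approx(0.5, abs=1e-6)

    def test_monotone_profile_raises(self):
        v = np.arange(0, 2, 0.2)
        with pytest.raises(NoPeakError):
            locate_peak(ElutionProfile(v, np.arange(10.0)))

    def test_noisy_localisation_within_fraction(self):
        hits = 0
        for s in range(100):
            profiles, centres = sg.sim_elution(
                sg.GRADIENT_LINE, sg.GRADIENT_STANDARDS, 11.0,
                noise_sd=5.0, seed=s,
            )
            est, _ = locate_peak(profiles["sample"])
            hits += abs(est - centres["sample"]) < 0.2
        assert hits >= 95


class TestInversionAndFormulas:
    def test_sec_inversion_printed_line(self):
        rs, _ = invert_calibration(sg.SEC_LINE, 20.0)
        assert rs == pytest.approx(10**0.69, rel=1e-9)
        assert rs == pytest.approx(4.90, abs=0.01)

    def test_gradient_inversion_printed_line(self):
        s, _ = invert_calibration(sg.GRADIENT_LINE, 2.0)
        assert s == pytest.approx(7.40, abs=1e-9)

    def test_non_physical_gradient_value(self):
        with pytest.raises(NonPhysicalError):
            invert_calibration(sg.GRADIENT_LINE, 0.0)

    @pytest.mark.parametrize(
        "rs,s,expected",
        [(3.48, 4.6, 67_313.64), (5.2, 11.3, 247_085.8)],
    )
    def test_molecular_weight(self, rs, s, expected):
        assert molecular_weight(rs, s) == pytest.approx(expected, rel=1e-6)
        # BSA anchors land within 5% of its sequence mass
        assert molecular_weight(3.48, 4.6) == pytest.approx(66_500, rel=0.05)

    def test_molecular_weight_monotone(self):
        assert molecular_weight(5.0, 10.0) < molecular_weight(5.1, 10.0)
        assert molecular_weight(5.0, 10.0) < molecular_weight(5.0, 10.1)

    def test_frictional_ratio_values(self):
        assert frictional_ratio(s_max(308_000), 308_000) == pytest.approx(1.0, abs=1e-12)
        assert frictional_ratio(10.97, 308_000) == pytest.approx(1.50, abs=0.005)
        assert frictional_ratio(8.66, 308_000) == pytest.approx(1.90, abs=0.005)

    def test_frictional_ratio_decreasing_in_s(self):
        assert frictional_ratio(10.0, 308_000) > frictional_ratio(11.0, 308_000)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            molecular_weight(0.0, 4.6)
        with pytest.raises(ValueError):
            frictional_ratio(-1.0, 308_000)


class TestRoundTrip:
    def test_zero_noise_recovers_mw(self):
        """Full pipeline on noiseless synthetic elutions recovers the
        generative molecular weight to better than 0.5%."""
        rs_true, s_true = 5.8, 11.0
        sec, _ = sg.sim_elution(sg.SEC_LINE, sg.SEC_STANDARDS, rs_true, seed=0)
        grad, _ = sg.sim_elution(
            sg.GRADIENT_LINE, sg.GRADIENT_STANDARDS, s_true, seed=0
        )
        sec_line = fit_calibration(
            [CalibrationStandard(s.name, s.anchor_value, locate_peak(sec[s.name])[0])
             for s in sg.SEC_STANDARDS],
            "log10_anchor",
        )
        grad_line = fit_calibration(
            [CalibrationStandard(s.name, s.anchor_value, locate_peak(grad[s.name])[0])
             for s in sg.GRADIENT_STANDARDS],
            "identity_anchor",
        )
        res = analyze_sample(sec_line, sec["sample"], grad_line, grad["sample"],
                             expected_mass_da=308_000)
        truth = molecular_weight(rs_true, s_true)
        assert abs(res.mw_da - truth) / truth < 0.005
        assert not res.flags

    def test_noisy_recovery_within_2_sigma(self):
        rs_true, s_true = 5.8, 11.0
        truth = molecular_weight(rs_true, s_true)
        within = 0
        n_seeds = 100
        for s in range(n_seeds):
            sec, _ = sg.sim_elution(sg.SEC_LINE, sg.SEC_STANDARDS, rs_true,
                                    noise_sd=5.0, seed=2 * s)
            grad, _ = sg.sim_elution(sg.GRADIENT_LINE, sg.GRADIENT_STANDARDS,
                                     s_true, noise_sd=5.0, seed=2 * s + 1)
            sec_line = fit_calibration(
                [CalibrationStandard(x.name, x.anchor_value,
                                     locate_peak(sec[x.name])[0])
                 for x in sg.SEC_STANDARDS], "log10_anchor")
            grad_line = fit_calibration(
                [CalibrationStandard(x.name, x.anchor_value,
                                     locate_peak(grad[x.name])[0])
                 for x in sg.GRADIENT_STANDARDS], "identity_anchor")
            res = analyze_sample(sec_line, sec["sample"], grad_line, grad["sample"])
            within += abs(res.mw_da - truth) <= 2 * res.mw_se
        assert within / n_seeds >= 0.90
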