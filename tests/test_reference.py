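import numpy as np
import pytest
from scipy.optimize import least_squares

from petkin._conv import UniformGrid, exp_conv
from petkin.compartment import MicroParams, model_tac
from petkin.reference import FRTM, SRTM, SRTM2C, fit_frtm, fit_srtm, fit_srtm_2c


@pytest.fixture(scope="module")
def one_tissue_pair(schedule, plasma, blood):
    """Target and reference with pure 1T kinetics sharing K1/k2 (true BP_ND=2).

    Both regions share the non-displaceable volume K1/k2; the target's
    apparent efflux is k2/(1+BP_ND), the textbook construction under which
    SRTM is exact.
    """
    k2, bp = 0.6, 2.0
    ref = model_tac(MicroParams(K1=0.9, k2=k2, vB=0.0), plasma, blood, schedule)
    tgt = model_tac(MicroParams(K1=0.9, k2=k2 / (1 + bp), vB=0.0),
                    plasma, blood, schedule)
    return tgt, ref, bp


class TestIdentityCases:
    def test_all_models_return_zero_bpnd_for_self_reference(self, schedule,
                                                            reference_tac):
        srtm = fit_srtm(reference_tac, reference_tac, schedule)
        assert srtm.R1 == pytest.approx(1.0, abs=1e-6)
        assert srtm.BPND == pytest.approx(0.0, abs=1e-6)
        frtm = fit_frtm(reference_tac, reference_tac, schedule)
        assert frtm.BPND == pytest.approx(0.0, abs=5e-3)
        s2c = fit_srtm_2c(reference_tac, reference_tac, schedule)
        assert s2c.BPND == pytest.approx(0.0, abs=5e-3)


class TestSRTM:
    def test_generative_recovery(self, schedule, one_tissue_pair):
        tgt, ref, bp = one_tissue_pair
        res = fit_srtm(tgt, ref, schedule)
        assert abs(res.BPND - bp) / bp < 0.01
        assert abs(res.R1 - 1.0) < 0.01

    def test_underestimates_when_reference_binds(self, schedule, noiseless_tacs,
                                                 reference_tac, grid):
        res = fit_srtm(noiseless_tacs[-1], reference_tac, schedule)
        assert res.BPND < grid.macros[-1].DVRminus1

    def test_basis_solution_matches_direct_nonlinear_fit(self, schedule, plasma,
                                                         blood):
        # independent oracle: raw 3-parameter nonlinear least squares on the
        # same objective
        rng = np.random.default_rng(11)
        grid = UniformGrid(schedule, 0.5)
        for _ in range(10):
            k2 = float(rng.uniform(0.3, 1.5))
            bp = float(rng.uniform(0.5, 4.0))
            r1_true = float(rng.uniform(0.7, 1.3))
            ref = model_tac(MicroParams(K1=0.9, k2=k2, vB=0.0), plasma, blood, schedule)
            tgt = model_tac(MicroParams(K1=0.9 * r1_true, k2=k2 / (1 + bp), vB=0.0),
                            plasma, blood, schedule)
            res = fit_srtm(tgt, ref, schedule)
            cr_grid = grid.frame_consistent(ref.values)
            cr = ref.values
            sw = np.sqrt(schedule.durations_min / schedule.durations_min.mean())

            def resid(x):
                r1, kk2, bpnd = x
                theta = kk2 / (1 + bpnd)
                conv = grid.frame_average(exp_conv(cr_grid, grid.dt_min, theta))
                return sw * (r1 * cr + (kk2 - r1 * theta) * conv - tgt.values)

            sol = least_squares(resid, [1.0, 0.5, 1.0],
                                bounds=([0.01, 0.01, -0.9], [10, 10, 30]),
                                xtol=1e-14, ftol=1e-14)
            assert abs(res.BPND - sol.x[2]) / max(abs(sol.x[2]), 0.1) < 0.005


class TestFRTM:
    def test_self_recovery(self, schedule, plasma, blood):
        r1, k2, k3, bp = 0.9, 0.3, 0.2, 2.0
        k4 = k3 / bp
        ref = model_tac(MicroParams(K1=0.5, k2=0.3 / 0.9, vB=0.0),
                        plasma, blood, schedule)
        est = FRTM(random_state=0)
        grid = UniformGrid(schedule, 0.5)
        target_frames = est._predict_frames(np.array([r1, k2, k3, k4]),
                                            ref.values,
                                            grid.frame_consistent(ref.values),
                                            grid)
        tgt = schedule.frame_curve(target_frames)
        res = est.fit(tgt, ref, schedule).result_()
        assert abs(res.R1 - r1) / r1 < 0.02
        assert abs(res.BPND - bp) / bp < 0.02

    def test_underestimates_when_reference_binds(self, schedule, noiseless_tacs,
                                                 reference_tac, grid):
        res = fit_frtm(noiseless_tacs[-1], reference_tac, schedule)
        assert res.BPND < grid.macros[-1].DVRminus1


class TestSRTM2C:
    def test_collapses_to_srtm_for_one_tissue_reference(self, schedule,
                                                        one_tissue_pair):
        tgt, ref, bp = one_tissue_pair
        srtm = fit_srtm(tgt, ref, schedule)
        s2c = fit_srtm_2c(tgt, ref, schedule)
        assert abs(s2c.BPND - srtm.BPND) / srtm.BPND < 0.02

    def test_closer_than_srtm_for_high_binding_target(self, schedule,
                                                      noiseless_tacs,
                                                      reference_tac, grid):
        truth = grid.macros[-1].DVRminus1
        srtm = fit_srtm(noiseless_tacs[-1], reference_tac, schedule)
        s2c = fit_srtm_2c(noiseless_tacs[-1], reference_tac, schedule)
        assert s2c.BPND < truth
        assert abs(s2c.BPND - truth) < abs(srtm.BPND - truth)

    def test_reports_reference_micro_parameters(self, schedule, noiseless_tacs,
                                                reference_tac):
        res = fit_srtm_2c(noiseless_tacs[8], reference_tac, schedule)
        assert set(res.ref_params) == {"k2r", "k3r", "k4r"}
        assert all(v >= 0 for v in res.ref_params.values())


class TestBiasDirection:
    @pytest.mark.parametrize("idx", [4, 10, 16])
    def test_all_models_below_theoretical_dvr_minus_one(self, schedule,
                                                        noiseless_tacs,
                                                        reference_tac, grid, idx):
        truth = grid.macros[idx].DVRminus1
        for fitter in (fit_srtm, fit_frtm, fit_srtm_2c):
            res = fitter(noiseless_tacs[idx], reference_tac, schedule)
            assert res.BPND < truth
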