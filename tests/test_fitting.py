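import numpy as np
import pytest

from petkin.compartment import MicroParams, macro_from_micro, model_tac
from petkin.curves import SampledCurve
from petkin.fitting import (OneTissueModel, TwoTissueModel, aic,
                            estimate_blood_delay, fit_compartment_model,
                            model_preference)


class TestAic:
    def test_log_term_vanishes_when_rss_equals_n(self):
        assert aic(rss=21.0, n_frames=21, n_free=2) == pytest.approx(4.0)

    def test_deterministic_in_inputs(self):
        assert aic(0.42, 21, 4) == aic(0.42, 21, 4)

    def test_formula_oracle(self):
        n, rss, k = 21, 0.42, 4
        assert aic(rss, n, k) == pytest.approx(n * np.log(rss / n) + 2 * k, abs=1e-12)

    def test_perfect_fit_sentinel(self):
        assert aic(0.0, 21, 2) == -np.inf

    def test_requires_more_frames_than_parameters(self):
        with pytest.raises(ValueError):
            aic(1.0, 3, 3)


class TestSelfRecovery:
    def test_one_tissue_noiseless(self, schedule, plasma, blood):
        truth = MicroParams(K1=0.8, k2=2.25)
        tac = model_tac(truth, plasma, blood, schedule)
        res = fit_compartment_model(tac, plasma, blood, schedule, "1T")
        assert abs(res.params.K1 - 0.8) / 0.8 < 1e-3
        assert abs(res.params.k2 - 2.25) / 2.25 < 1e-3
        assert res.rss <= 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_randomized_two_tissue_vt_recovery(self, schedule, plasma, blood, seed):
        rng = np.random.default_rng(seed)
        truth = MicroParams(K1=float(rng.uniform(0.3, 1.5)),
                            k2=float(rng.uniform(0.5, 3.0)),
                            k3=float(rng.uniform(0.05, 1.5)),
                            k4=float(rng.uniform(0.05, 0.5)))
        tac = model_tac(truth, plasma, blood, schedule)
        res = fit_compartment_model(tac, plasma, blood, schedule, "2T",
                                    random_state=seed)
        vt_true = macro_from_micro(truth).VT
        assert res.rss < 1e-6
        assert abs(res.macro.VT - vt_true) / vt_true < 0.005

    def test_two_tissue_preferred_on_three_tissue_tac(self, schedule, plasma,
                                                      blood, noiseless_tacs):
        tac = noiseless_tacs[0]
        r1 = fit_compartment_model(tac, plasma, blood, schedule, "1T")
        r2 = fit_compartment_model(tac, plasma, blood, schedule, "2T")
        assert r2.aic < r1.aic

    def test_nested_model_never_increases_rss(self, schedule, plasma, blood,
                                              noiseless_tacs):
        for tac in noiseless_tacs[::8]:
            r1 = fit_compartment_model(tac, plasma, blood, schedule, "1T")
            r2 = fit_compartment_model(tac, plasma, blood, schedule, "2T")
            assert r2.rss <= r1.rss * (1 + 1e-9)

    def test_one_tissue_underestimates_vt_at_low_binding(self, schedule, plasma,
                                                         blood, noiseless_tacs, grid):
        r1 = fit_compartment_model(noiseless_tacs[0], plasma, blood, schedule, "1T")
        r2 = fit_compartment_model(noiseless_tacs[0], plasma, blood, schedule, "2T")
        assert r1.macro.VT < r2.macro.VT <= grid.macros[0].VT * 1.01


class TestBloodDelay:
    def test_zero_shift_recovered(self, schedule, plasma, blood, noiseless_tacs):
        d = estimate_blood_delay(noiseless_tacs[4], plasma, blood, schedule,
                                 search_min=0.2, step_min=0.02)
        assert abs(d) <= 0.02

    def test_known_shift_recovered(self, schedule, plasma, blood, grid):
        # simulate with the input arriving 0.1 min later than the curves say
        tac = model_tac(grid.configs[4], plasma, blood, schedule, delay=0.1)
        d = estimate_blood_delay(tac, plasma, blood, schedule,
                                 search_min=0.2, step_min=0.02)
        assert abs(d - 0.1) <= 0.01

    def test_fixed_delay_is_propagated_to_regional_fits(self, schedule, plasma,
                                                        blood, noiseless_tacs):
        delay = 0.07
        fits = [fit_compartment_model(t, plasma, blood, schedule, "2T", delay=delay)
                for t in (noiseless_tacs[1], noiseless_tacs[9])]
        assert fits[0].delay == fits[1].delay == delay


class TestModelPreference:
    def _pair(self, aic1, aic2, n_free1=2, n_free2=4):
        def mk(kind, a, k):
            from petkin.fitting import FitResult
            from petkin.compartment import MacroParams
            curve = SampledCurve([1.0], [1.0])
            return FitResult(kind, MicroParams(K1=1, k2=1), 0.0, 1.0, 21, k, a,
                             MacroParams(VT=1.0), curve)
        return mk("1T", aic1, n_free1), mk("2T", aic2, n_free2)

    def test_unanimous(self):
        tally = model_preference([self._pair(10, 5)] * 4)
        assert tally["percent"]["2T"] == 100.0

    def test_seven_of_ten(self):
        pairs = [self._pair(1, 2)] * 7 + [self._pair(3, 1)] * 3
        tally = model_preference(pairs)
        assert tally["percent"]["1T"] == 70.0
        assert tally["percent"]["2T"] == 30.0

    def test_counting_oracle(self):
        rng = np.random.default_rng(1)
        a1 = rng.normal(size=40)
        a2 = rng.normal(size=40)
        tally = model_preference([self._pair(x, y) for x, y in zip(a1, a2)])
        assert tally["percent"]["1T"] == pytest.approx(100.0 * np.mean(a1 < a2))

    def test_tie_goes_to_simpler_model(self):
        tally = model_preference([self._pair(5.0, 5.0)])
        assert tally["counts"]["1T"] == 1

    def test_mismatched_frames_rejected(self):
        a, b = self._pair(1, 2)
        b = b.__class__(**{**b.__dict__, "n_frames": 20})
        with pytest.raises(ValueError):
            model_preference([(a, b)])
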