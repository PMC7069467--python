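import numpy as np
import pytest
from scipy import integrate

from dynconn.erp import (N1, P3A, ComponentDefinition, average_erp,
                         fdr_correct, mass_univariate_ttest,
                         measure_component)
from dynconn.errors import SelectionError, StatisticsError
from oracle_helpers import bh_mask_bruteforce


def waveform_set(data_list, rate=500.0, window=(-200.0, 1000.0),
                 labels=("Fz",)):
    from dynconn.erp import ERPWaveform
    return [ERPWaveform(data=np.atleast_2d(d), rate=rate, window_ms=window,
                        condition="deviant", channel_labels=labels)
            for d in data_list]


class TestAverageErp:
    def test_single_trial_is_identity(self, epoch_factory, rng):
        ep = epoch_factory(rng.standard_normal((1, 2, 600)))
        assert np.allclose(average_erp(ep, "deviant").data, ep.data[0])

    def test_opposite_trials_cancel(self, epoch_factory, rng):
        x = rng.standard_normal((1, 2, 600))
        ep = epoch_factory(np.concatenate([x, -x]))
        assert np.allclose(average_erp(ep, "deviant").data, 0.0)

    def test_rmse_shrinks_like_sqrt_n(self, epoch_factory):
        rng = np.random.default_rng(11)
        template = np.sin(np.linspace(0, 6 * np.pi, 600))[None]
        trials = template[None] + rng.standard_normal((100, 1, 600))
        ep = epoch_factory(trials)
        erp = average_erp(ep, "deviant")
        rmse_avg = np.sqrt(np.mean((erp.data - template) ** 2))
        rmse_single = np.sqrt(np.mean((trials[0] - template) ** 2))
        assert rmse_avg == pytest.approx(rmse_single / 10, rel=0.5)

    def test_no_matching_trials_is_selection_error(self, epoch_factory, rng):
        ep = epoch_factory(rng.standard_normal((2, 1, 600)))
        with pytest.raises(SelectionError):
            average_erp(ep, "standard")


class TestMassUnivariate:
    def test_identical_paired_groups_give_t0_p1(self, rng):
        a = waveform_set(rng.standard_normal((6, 1, 600)))
        res = mass_univariate_ttest(a, a, paired=True)
        assert np.allclose(res.t_values, 0.0)
        assert np.allclose(res.p_values, 1.0)
        assert not res.fdr_mask.any()

    def test_constant_paired_shift_is_everywhere_significant(self, rng):
        base = [rng.standard_normal((1, 600)) for _ in range(10)]
        a = waveform_set([b + 5.0 + 1e-3 * rng.standard_normal((1, 600))
                          for b in base])
        b = waveform_set(base)
        res = mass_univariate_ttest(a, b, paired=True)
        assert (res.p_values < 1e-6).all()
        assert res.fdr_mask.all()

    def test_identical_unpaired_samples_give_t0(self):
        vals = [np.full((1, 600), v) for v in (1.0, 2.0, 3.0)]
        res = mass_univariate_ttest(waveform_set(vals), waveform_set(vals),
                                    paired=False)
        assert np.allclose(res.t_values, 0.0)
        assert np.allclose(res.p_values, 1.0)

    def test_zero_variance_points_yield_p1_not_nan(self):
        a = waveform_set([np.full((1, 600), 1.0) for _ in range(4)])
        b = waveform_set([np.full((1, 600), 1.0) for _ in range(4)])
        res = mass_univariate_ttest(a, b, paired=False)
        assert np.isfinite(res.p_values).all()
        assert (res.p_values == 1.0).all()

    def test_window_restricts_time_axis(self, rng):
        a = waveform_set(rng.standard_normal((4, 1, 600)))
        res = mass_univariate_ttest(a, a, paired=True, window_ms=(0, 1000))
        assert res.times_ms.min() >= 0.0
        assert res.t_values.shape == (1, len(res.times_ms))

    def test_mismatched_paired_lists_rejected(self, rng):
        a = waveform_set(rng.standard_normal((4, 1, 600)))
        with pytest.raises(StatisticsError):
            mass_univariate_ttest(a, a[:3], paired=True)


class TestFdr:
    def test_all_ones_give_empty_mask(self):
        assert not fdr_correct(np.ones(50)).any()

    def test_worked_example_rejects_first_four(self):
        p = np.array([0.001, 0.01, 0.02, 0.03, 0.5])
        assert fdr_correct(p, q=0.05).tolist() == [True] * 4 + [False]

    def test_single_p_reduces_to_raw_threshold(self):
        assert fdr_correct(np.array([0.04]), q=0.05).all()
        assert not fdr_correct(np.array([0.06]), q=0.05).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_mask_equals_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 1000))
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        got = fdr_correct(p, q=0.05)
        assert np.array_equal(got, bh_mask_bruteforce(p, 0.05))

    def test_mask_shape_follows_input(self, rng):
        p = rng.random((4, 30))
        assert fdr_correct(p).shape == (4, 30)


class TestMeasureComponent:
    def test_zero_waveform_measures_zero(self):
        w = waveform_set([np.zeros((1, 600))])[0]
        assert measure_component(w, N1) == 0.0

    def test_constant_negative_waveform(self):
        w = waveform_set([np.full((1, 600), -5.0)])[0]
        assert measure_component(w, N1) == pytest.approx(-5.0)

    def test_gaussian_bump_matches_quadrature_oracle(self):
        lat, sig, peak = 300.0, 50.0 / 2.355, 3.0   # 50 ms FWHM
        t = -200.0 + np.arange(600) * 2.0
        data = peak * np.exp(-0.5 * ((t - lat) / sig) ** 2)[None]
        w = waveform_set([data])[0]
        got = measure_component(w, P3A)
        f = lambda x: peak * np.exp(-0.5 * ((x - lat) / sig) ** 2)
        lo, hi = P3A.window_ms
        expected = integrate.quad(f, lo, hi)[0] / (hi - lo)
        assert got == pytest.approx(expected, rel=0.02)


class TestErrorCalibration:
    def test_pointwise_type_I_error_is_5_percent(self):
        """Null Welch tests at alpha=.05 reject at 0.05 +- 0.01."""
        rng = np.random.default_rng(2024)
        a = waveform_set(list(rng.standard_normal((16, 1, 600))))
        b = waveform_set(list(rng.standard_normal((16, 1, 600))))
        reps = [mass_univariate_ttest(a, b, paired=False, window_ms=(-200, 998))]
        for s in range(16):
            aa = waveform_set(list(np.random.default_rng(s).standard_normal((16, 1, 600))))
            bb = waveform_set(list(np.random.default_rng(1000 + s).standard_normal((16, 1, 600))))
            reps.append(mass_univariate_ttest(aa, bb, paired=False,
                                              window_ms=(-200, 998)))
        p = np.concatenate([r.p_values.ravel() for r in reps])
        assert p.size >= 10000
        rate = (p < 0.05).mean()
        assert abs(rate - 0.05) < 0.01
        # under the full null the BH-corrected discovery proportion is ~0
        bh = np.mean([r.fdr_mask.mean() for r in reps])
        assert bh <= 0.05

    def test_planted_window_concentrates_the_mask(self):
        """Effect planted in 300-400 ms: mask density inside >= 5x outside."""
        rng = np.random.default_rng(31)
        t = -200.0 + np.arange(600) * 2.0
        bump = ((t >= 300) & (t < 400)).astype(float) * 1.5
        base = [rng.standard_normal((1, 600)) for _ in range(12)]
        a = waveform_set([x + bump for x in base])
        b = waveform_set(base)
        res = mass_univariate_ttest(a, b, paired=True)
        inside = (res.times_ms >= 300) & (res.times_ms < 400)
        d_in = res.fdr_mask[0, inside].mean()
        d_out = max(res.fdr_mask[0, ~inside].mean(), 1e-12)
        assert d_in >= 5 * d_out
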