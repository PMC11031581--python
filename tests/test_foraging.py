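import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import filicann as fc
from filicann.foraging import integrate_consumption
from filicann.params import ParameterError

pref_val = st.floats(0.0, 1.0)


def record(fp, c3=0.0, c4=0.0, c5=0.0, het=0.0):
    return fc.ConsumptionRecord(c3, c4, c5, het)


class TestFunctionalResponse:
    def test_zero_preference_consumes_nothing(self, real_set):
        fp, lh = real_set
        rec = fc.functional_response((10, 5, 2), fp.y, fc.PreyPreference(0, 0),
                                     fp, lh.activity_minutes_per_unit)
        assert rec == record(fp)

    def test_zero_time_consumes_nothing(self, real_set):
        fp, _ = real_set
        rec = fc.functional_response((10, 5, 2), fp.y, fc.PreyPreference(1, 1), fp, 0.0)
        assert rec == record(fp)

    def test_no_prey_at_all(self, real_set):
        fp, _ = real_set
        rec = fc.functional_response((0, 0, 0), 0.0, fc.PreyPreference(1, 1), fp, 1000.0)
        assert rec == record(fp)

    def test_single_prey_closed_form(self, real_set):
        """With only heterospecific prey the disc relation T/(tau_s+tau_b) holds."""
        fp, lh = real_set
        T = lh.activity_minutes_per_unit
        rec = fc.functional_response((0, 0, 0), fp.y, fc.PreyPreference(0.7, 1.0), fp, T)
        assert rec.total_conspecific == 0.0
        assert rec.consumed_het == pytest.approx(T / (fp.tau_s + fp.tau_b))

    def test_negative_input_rejected(self, real_set):
        fp, _ = real_set
        with pytest.raises(ParameterError):
            fc.functional_response((-1, 0, 0), fp.y, fc.PreyPreference(1, 1), fp, 100.0)

    def test_consumption_capped_at_availability(self, real_set):
        fp, lh = real_set
        rec = fc.functional_response((0.5, 0.2, 0.1), 0.0, fc.PreyPreference(1, 1),
                                     fp, lh.activity_minutes_per_unit)
        assert rec.consumed_c3 <= 0.5 and rec.consumed_c4 <= 0.2 and rec.consumed_c5 <= 0.1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pa=pref_val, pb=pref_val, c3=st.floats(0, 200), c4=st.floats(0, 200),
           c5=st.floats(0, 200), T=st.floats(0, 4800))
    def test_monotone_in_time_and_preference(self, real_set, pa, pb, c3, c4, c5, T):
        fp, _ = real_set
        base = fc.functional_response((c3, c4, c5), fp.y, fc.PreyPreference(pa, pb), fp, T)
        more_t = fc.functional_response((c3, c4, c5), fp.y, fc.PreyPreference(pa, pb), fp, T + 500)
        for f in ("consumed_c3", "consumed_c4", "consumed_c5", "consumed_het"):
            assert getattr(more_t, f) >= getattr(base, f) - 1e-12
        more_pa = fc.functional_response((c3, c4, c5), fp.y,
                                         fc.PreyPreference(min(pa + 0.2, 1.0), pb), fp, T)
        assert more_pa.total_conspecific >= base.total_conspecific - 1e-12

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pa=pref_val, pb=pref_val, c3=st.floats(0, 200), c4=st.floats(0, 200),
           c5=st.floats(0, 200))
    def test_encounter_budget(self, real_set, pa, pb, c3, c4, c5):
        """Items consumed cannot exceed the number of search cycles T/tau_s."""
        fp, _ = real_set
        T = 4800.0
        rec = fc.functional_response((c3, c4, c5), fp.y, fc.PreyPreference(pa, pb), fp, T)
        assert rec.total_conspecific + rec.consumed_het <= T / fp.tau_s + 1e-9


class TestDepletion:
    def test_matches_fixed_density_form_when_nothing_depletes(self, real_set):
        """With no conspecific attack the within-step integral is exactly the
        fixed-density form: nothing changes during the window."""
        fp, lh = real_set
        T = lh.activity_minutes_per_unit
        c3, c4, c5 = 30.0, 20.0, 10.0
        rec = fc.functional_response((c3, c4, c5), fp.y, fc.PreyPreference(0.0, 0.8), fp, T)
        r3, r4, r5, het = integrate_consumption(c3, c4, c5, fp.y, 0.0, 0.8, fp, T)
        assert float(r3) == c3 and float(r4) == c4 and float(r5) == c5
        assert float(het) == pytest.approx(rec.consumed_het, rel=1e-9)

    def test_depletion_consumes_less_conspecifics_than_fixed_density(self, real_set):
        fp, lh = real_set
        T = lh.activity_minutes_per_unit
        c = (40.0, 30.0, 20.0)
        fixed = fc.functional_response(c, fp.y, fc.PreyPreference(0.6, 1.0), fp, T)
        r3, r4, r5, _ = integrate_consumption(*c, fp.y, 0.6, 1.0, fp, T)
        eaten = (c[0] - float(r3)) + (c[1] - float(r4)) + (c[2] - float(r5))
        assert eaten <= fixed.total_conspecific + 1e-9
        assert all(v >= -1e-12 for v in (r3, r4, r5))

    def test_substep_refinement_converged(self, real_set):
        fp, lh = real_set
        T = lh.activity_minutes_per_unit
        coarse = integrate_consumption(40.0, 30.0, 20.0, fp.y, 0.6, 1.0, fp, T, substeps=150)
        fine = integrate_consumption(40.0, 30.0, 20.0, fp.y, 0.6, 1.0, fp, T, substeps=600)
        assert np.allclose([float(v) for v in coarse], [float(v) for v in fine], rtol=1e-5)


class TestNumericalResponse:
    def test_one_item_of_each_kind(self, real_set):
        fp, _ = real_set
        assert fc.numerical_response(record(fp, c3=1.0), fp) == pytest.approx(0.91)
        assert fc.numerical_response(record(fp, het=1.0), fp) == pytest.approx(0.44)
        assert fc.numerical_response(record(fp), fp) == 0.0

    def test_linear_combination(self, illustrative_set):
        fp, _ = illustrative_set
        rec = fc.ConsumptionRecord(1.5, 0.5, 2.0, 3.0)
        expected = 2.0 * 1.5 + 6.0 * 0.5 + 11.0 * 2.0 + 0.04 * 3.0
        assert fc.numerical_response(rec, fp) == pytest.approx(expected)


class TestStochasticRenewalOracle:
    def test_single_prey_mean_matches_closed_form(self, real_set):
        fp, _ = real_set
        T = 800.0
        res = fc.simulate_functional_response((0, 0, 0), fp.y, fc.PreyPreference(0, 1),
                                              fp, T, n_bouts=4000, seed=7)
        expected = T / (fp.tau_s + fp.tau_b)
        assert abs(res.mean.consumed_het - expected) < max(3 * res.se.consumed_het, 0.6)

    @pytest.mark.parametrize("seed", range(20))
    def test_mixed_prey_mean_matches_deterministic(self, seed):
        """The fixed-density record equals the mean of sequential stochastic
        foraging bouts across seeded random parameter sets (within 3 SE plus
        a half-cycle truncation allowance)."""
        fp, lh = fc.random_parameters(seed)
        rng = np.random.default_rng(seed + 1000)
        c = tuple(rng.uniform(5, 50, size=3))
        pref = fc.PreyPreference(*rng.uniform(0.2, 1.0, size=2))
        T = 600.0
        det = fc.functional_response(c, fp.y, pref, fp, T)
        sim = fc.simulate_functional_response(c, fp.y, pref, fp, T, n_bouts=1500,
                                              seed=seed)
        for f in ("consumed_c3", "consumed_c4", "consumed_c5", "consumed_het"):
            d, m, s = getattr(det, f), getattr(sim.mean, f), getattr(sim.se, f)
            assert abs(m - d) < 3 * s + 1.0, f"{f}: det={d}, sim={m}±{s}"
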