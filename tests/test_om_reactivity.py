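"""Reactive continuum model and its multi-G discretization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedrtm.om_reactivity import (MultiG, RCMParams, analytic_toc_profile,
                                  bulk_fraction_remaining, discretize_rcm,
                                  k_at_age)

TABLE_PARAMS = [(20.0, 0.150), (20.0, 0.090), (100.0, 0.100),
                (10.0, 0.090), (20.0, 0.200)]

params_st = st.tuples(st.floats(1.0, 1000.0), st.floats(0.01, 1.0))


class TestKAtAge:
    def test_interface_reactivity(self):
        assert k_at_age(RCMParams(20, 0.150), 0.0) == pytest.approx(7.5e-3)
        assert k_at_age(RCMParams(100, 0.100), 0.0) == pytest.approx(1.0e-3)
        assert k_at_age(RCMParams(1, 1), 0.0) == 1.0

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            k_at_age(RCMParams(20, 0.15), -1.0)

    @given(p=params_st, age=st.floats(0, 1e4), dage=st.floats(1.0, 1e4))
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing_in_age(self, p, age, dage):
        rcm = RCMParams(*p)
        assert k_at_age(rcm, age + dage) < k_at_age(rcm, age)

    @given(p=params_st, factor=st.floats(1.1, 50.0), age=st.floats(0, 1e4))
    @settings(max_examples=60, deadline=None)
    def test_higher_a_lowers_k_everywhere(self, p, factor, age):
        a, v = p
        assert k_at_age(RCMParams(a * factor, v), age) < k_at_age(RCMParams(a, v), age)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RCMParams(0.0, 0.1)
        with pytest.raises(ValueError):
            RCMParams(10.0, -0.1)


class TestDiscretization:
    @pytest.mark.parametrize("n", [2, 10, 50, 200])
    @pytest.mark.parametrize("a,v", TABLE_PARAMS)
    def test_mass_and_mean_exact(self, a, v, n):
        mg = discretize_rcm(RCMParams(a, v), n)
        assert mg.f.sum() == pytest.approx(1.0, abs=1e-12)
        # quantile-bin conditional means telescope to the distribution mean
        assert mg.mean_k() == pytest.approx(v / a, rel=1e-9)

    def test_rate_constants_strictly_increasing(self):
        mg = discretize_rcm(RCMParams(20, 0.15), 200)
        assert np.all(np.diff(mg.k) > 0)

    def test_bulk_decay_example(self):
        mg = discretize_rcm(RCMParams(20, 0.150), 200)
        assert mg.bulk_decay(100.0) == pytest.approx(0.7644, abs=1e-3)

    @pytest.mark.parametrize("a,v", TABLE_PARAMS)
    def test_bulk_decay_matches_closed_form(self, a, v):
        rcm = RCMParams(a, v)
        mg = discretize_rcm(rcm, 200)
        t = np.linspace(0.0, 30.0 * a, 400)
        rel = np.abs(mg.bulk_decay(t) - bulk_fraction_remaining(rcm, t))
        rel /= bulk_fraction_remaining(rcm, t)
        assert rel.max() < 5e-3

    @pytest.mark.parametrize("a,v", [(20.0, 0.150), (10.0, 0.090)])
    def test_discretization_error_decreases_with_n(self, a, v):
        rcm = RCMParams(a, v)
        t = np.linspace(0.0, 2000.0, 200)
        exact = bulk_fraction_remaining(rcm, t)
        errors = []
        for n in (25, 50, 100, 200):
            mg = discretize_rcm(rcm, n)
            errors.append(np.max(np.abs(mg.bulk_decay(t) - exact) / exact))
        assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))

    def test_too_few_fractions_rejected(self):
        with pytest.raises(ValueError):
            discretize_rcm(RCMParams(20, 0.15), 1)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MultiG(k=np.array([0.1, 0.1]), f=np.array([0.5, 0.5]),
                   params=RCMParams(20, 0.15))
        with pytest.raises(ValueError):
            MultiG(k=np.array([0.1, 0.2]), f=np.array([0.5, 0.6]),
                   params=RCMParams(20, 0.15))


class TestClosedForms:
    def test_no_decay_at_t0(self):
        assert bulk_fraction_remaining(RCMParams(3, 0.7), 0.0) == 1.0

    def test_survival_values(self):
        assert bulk_fraction_remaining(RCMParams(20, 0.15), 100.0) == \
            pytest.approx(0.7644, abs=2e-4)
        assert bulk_fraction_remaining(RCMParams(100, 0.10), 2000.0) == \
            pytest.approx(0.7375, abs=2e-4)

    def test_analytic_profile(self):
        rcm = RCMParams(20, 0.15)
        assert analytic_toc_profile(rcm, 0.05, 1.0, 0.0) == 1.0
        assert analytic_toc_profile(rcm, 0.05, 1.0, 5.0) == pytest.approx(0.7644, abs=2e-4)
        assert analytic_toc_profile(RCMParams(100, 0.10), 0.05, 1.0, 100.0) == \
            pytest.approx(0.7375, abs=2e-4)

    def test_requires_positive_burial(self):
        with pytest.raises(ValueError):
            analytic_toc_profile(RCMParams(20, 0.15), 0.0, 1.0, 5.0)
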