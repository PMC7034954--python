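"""Unit and property tests for the subsystem kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendroclock import ModelParameters, ModelState
from dendroclock import _kernel
from dendroclock.kinetics import (ac_rates, calcium_store_rhs, effective_calcium,
                                  f_cicr, full_rhs, gi_input, gs_input,
                                  pka_pathway_rhs, rgs_rhs, rgs_switch)
from dendroclock.state import SPECIES

conc = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)
pos = st.floats(min_value=1e-3, max_value=50.0, allow_nan=False)


class TestCICRGate:
    @pytest.mark.parametrize("y,h,n,expected", [
        (0.7, 0.7, 1.0, 0.5),      # half-saturation by symmetry
        (0.7, 0.7, 7.0, 0.5),
        (0.0, 0.5, 4.0, 0.0),
        (1.5, 0.5, 2.0, 0.9),      # 9h²/(9h²+h²)
    ])
    def test_examples(self, y, h, n, expected):
        assert f_cicr(y, h, n) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            f_cicr(-0.1, 0.5, 2.0)
        with pytest.raises(ValueError):
            f_cicr(0.1, 0.0, 2.0)

    @given(y1=conc, y2=conc, h=pos, n=st.floats(min_value=1, max_value=8))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, y1, y2, h, n):
        f1, f2 = f_cicr(y1, h, n), f_cicr(y2, h, n)
        assert 0.0 <= f1 < 1.0
        if y1 <= y2:
            assert f1 <= f2 + 1e-15


class TestCalciumStore:
    def test_empty_store_gives_pure_influx(self, params):
        s = ModelState(x=0.0, y=0.0)
        dx, dy = calcium_store_rhs(s, params)
        assert dx == 0.0
        assert dy == pytest.approx(params.gamma)

    @given(x=conc, y=conc)
    @settings(max_examples=50, deadline=None)
    def test_total_calcium_identity(self, x, y):
        """d(x+y)/dt equals influx - removal exactly: exchange terms cancel."""
        p = ModelParameters()
        s = ModelState(x=x, y=y)
        dx, dy = calcium_store_rhs(s, p)
        assert dx + dy == pytest.approx(p.gamma - p.beta * y, rel=1e-12, abs=1e-12)

    def test_fixed_point(self):
        """At y = gamma/beta with balanced exchange both derivatives vanish."""
        p = ModelParameters()
        y0 = p.gamma / p.beta
        fy = f_cicr(y0, p.h, p.n)
        x0 = p.k1 * y0 / (p.k2 + p.alpha_store * fy)
        dx, dy = calcium_store_rhs(ModelState(x=x0, y=y0), p)
        assert dx == pytest.approx(0.0, abs=1e-12)
        assert dy == pytest.approx(0.0, abs=1e-12)


class TestEffectiveCalcium:
    def test_basal_before_any_cs(self, params):
        s = ModelState(y=3.0, PKA=0.5, t_since_CS=None)
        assert effective_calcium(s, params) == params.B_Ca

    def test_basal_after_window_closes(self, params):
        s = ModelState(y=3.0, PKA=0.5, t_since_CS=params.ca_window + 0.1)
        assert effective_calcium(s, params) == params.B_Ca

    @pytest.mark.parametrize("pka,factor", [(0.0, 1.0), (0.1, 2.0), (1.0, 11.0)])
    def test_pka_amplification_inside_window(self, params, pka, factor):
        s = ModelState(y=0.8, PKA=pka, t_since_CS=1.0)
        assert effective_calcium(s, params) == pytest.approx(factor * 0.8)


class TestGiTransient:
    def test_shape(self, params):
        assert gi_input(None, params) == 0.0
        assert gi_input(0.0, params) == pytest.approx(params.gi_a)
        hold = params.gi_a * math.exp(params.gi_b * params.gi_rise_window)
        assert gi_input(1.5, params) == pytest.approx(hold)   # held after the rise
        assert gi_input(2.5, params) == 0.0                   # deactivated after 2 s

    def test_constant_transient_when_rate_zero(self, params):
        p = params.replace(gi_b=0.0)
        assert gi_input(0.6, p) == pytest.approx(p.gi_a)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            gi_input(-0.01, params)


class TestGsInput:
    def test_full_amplitude_without_rgs(self, params):
        assert gs_input(0.05, 0.0, params) == pytest.approx(params.gs_amplitude)

    def test_half_suppression_at_kg(self, params):
        assert gs_input(0.05, params.K_g, params) == pytest.approx(params.gs_amplitude / 2)

    def test_window_closes(self, params):
        assert gs_input(0.3, 0.0, params) == 0.0
        assert gs_input(None, 0.0, params) == 0.0

    @given(r1=st.floats(0, 1), r2=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_rgs(self, r1, r2):
        p = ModelParameters()
        if r1 + 1e-6 < r2:  # separations below float resolution are ties
            assert gs_input(0.1, r1, p) > gs_input(0.1, r2, p)


class TestACRates:
    def test_no_gs_means_baseline_only(self, params):
        """Calcium alone never raises the activation rate: coincidence detection."""
        for ca in (0.0, 0.5, 5.0, 50.0):
            r1, _ = ac_rates(ca, 0.0, 0.0, params)
            assert r1 == params.r1_bl

    def test_half_half_synergy(self, params):
        g = 2.0
        r1, _ = ac_rates(params.K_ca_AC, g, params.K_Gi, params)
        assert r1 == pytest.approx(params.r1_bl + params.r_cag * g * 0.25)

    def test_deactivation(self, params):
        _, r2 = ac_rates(0.0, 1.0, 0.0, params)
        assert r2 == params.r2_bl
        _, r2b = ac_rates(2.0, 1.0, 0.0, params)
        assert r2b == pytest.approx(params.r2_bl + 2.0 * params.r_ca)

    @given(c1=conc, c2=conc, gs=pos, gi=conc)
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_calcium_and_gi(self, c1, c2, gs, gi):
        p = ModelParameters()
        lo, hi = sorted((c1, c2))
        assert ac_rates(lo, gs, gi, p)[0] <= ac_rates(hi, gs, gi, p)[0] + 1e-12
        assert ac_rates(c1, gs, gi + 1.0, p)[0] <= ac_rates(c1, gs, gi, p)[0] + 1e-12


class TestPKAPathway:
    def test_saturated_ac_can_only_deactivate(self, params):
        s = ModelState(AC=params.AC_total, t_since_CS=None)
        dAC, _, _, _ = pka_pathway_rhs(s, params)
        assert dAC <= 0.0

    def test_empty_camp_and_ac(self, params):
        s = ModelState(AC=0.0, cAMP=0.0, PKA=0.0, PDE=0.0)
        _, dcAMP, dPKA, _ = pka_pathway_rhs(s, params)
        assert dcAMP == 0.0
        assert dPKA == 0.0

    def test_conservation_violation_raises(self, params):
        s = ModelState(PKA=params.PKA_total + 0.1)
        with pytest.raises(ValueError):
            pka_pathway_rhs(s, params)


class TestRGS:
    @pytest.mark.parametrize("z,expected", [(0.2, 1), (0.05, 0), (0.1, 0)])
    def test_switch_strict_threshold(self, params, z, expected):
        assert rgs_switch(z, params) == expected

    def test_full_rgs_decays_when_switch_on(self, params):
        s = ModelState(RGS=1.0, z=0.5)
        dRGS, _ = rgs_rhs(s, 1.0, params)
        assert dRGS == pytest.approx(-params.r6)

    def test_z_pure_decay_without_calcium(self, params):
        s = ModelState(RGS=0.0, z=0.4)
        _, dz = rgs_rhs(s, 0.0, params)
        assert dz == pytest.approx(-params.r4 * 0.4)

    def test_both_rise_from_zero_with_calcium(self, params):
        s = ModelState(RGS=0.0, z=0.0)
        dRGS, dz = rgs_rhs(s, 1.0, params)
        assert dRGS >= 0.0
        assert dz > 0.0


@given(vec=st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=8, max_size=8),
       tc=st.one_of(st.none(), st.floats(0, 3)),
       tu=st.one_of(st.none(), st.floats(0, 3)))
@settings(max_examples=60, deadline=None)
def test_kernel_matches_reference_rhs(vec, tc, tu):
    """The packed-array kernel and the documented per-subsystem functions
    compute identical derivatives for arbitrary admissible states."""
    p = ModelParameters()
    vec = list(vec)
    vec[SPECIES.index("AC")] = min(vec[SPECIES.index("AC")], p.AC_total)
    vec[SPECIES.index("PKA")] = min(vec[SPECIES.index("PKA")], p.PKA_total)
    vec[SPECIES.index("PDE")] = min(vec[SPECIES.index("PDE")], p.PDE_total)
    vec[SPECIES.index("RGS")] = min(vec[SPECIES.index("RGS")], 1.0)
    vec[SPECIES.index("z")] = min(vec[SPECIES.index("z")], 1.0)
    state = ModelState(t_since_CS=tc, t_since_US=tu)
    state = state.with_vector(np.array(vec))
    state.t_since_CS, state.t_since_US = tc, tu
    ref = full_rhs(state, p)

    out = np.empty(8)
    cs_time = _kernel.NO_EVENT if tc is None else -tc
    us_time = _kernel.NO_EVENT if tu is None else -tu
    _kernel.rhs(0.0, np.array(vec), p.to_array(), cs_time, us_time, out)
    np.testing.assert_allclose(out, ref.to_vector(), rtol=1e-12, atol=1e-12)
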