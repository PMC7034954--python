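"""Backward-Euler stepping, event handling and accuracy checks."""

import numpy as np
import pytest

from dendroclock import (IntegrationError, IntegratorConfig, ModelParameters,
                         ModelState, integrate, step)
from dendroclock.state import SPECIES, resting_state


def test_linear_decay_matches_implicit_closed_form():
    """With all drives off, z decays linearly and one backward-Euler step
    must equal the closed-form implicit update z/(1 + r4*dt) exactly."""
    p = ModelParameters().replace(gamma=0.0, B_Ca=0.0, init_cAMP=0.0,
                                  r1_bl=0.0, k13=0.0, r5=0.0)
    s = ModelState(z=0.05, RGS=0.25)  # z below threshold: the switch stays off
    cfg = IntegratorConfig(dt=1e-3)
    out = step(s, p, cfg)
    assert out.z == pytest.approx(0.05 / (1 + p.r4 * cfg.dt), rel=1e-9)
    assert out.RGS == pytest.approx(0.25 / (1 + p.r6 * cfg.dt), rel=1e-9)


def test_quiescent_state_is_a_fixed_point():
    p = ModelParameters().replace(gamma=0.0, B_Ca=0.0, init_cAMP=0.0,
                                  r1_bl=0.0, k13=0.0, r5=0.0)
    s = ModelState()  # all zero, no stimuli
    out = step(s, p, IntegratorConfig(dt=1e-3))
    np.testing.assert_allclose(out.to_vector(), np.zeros(8), atol=1e-15)


def test_trace_shape_and_sampling(params):
    cfg = IntegratorConfig(dt=25e-6, record_stride=40)
    _, trace = integrate(resting_state(params), [], params, cfg, 1.0)
    assert len(trace) == 1001            # 1 s at 1 ms recording plus t = 0
    assert trace.dt_record == pytest.approx(1e-3)


def test_empty_schedule_keeps_basal_calcium(params, coarse_cfg):
    _, trace = integrate(resting_state(params), [], params, coarse_cfg, 1.0)
    np.testing.assert_allclose(trace["Ca"], params.B_Ca, rtol=1e-9)
    assert np.all(trace["Gi"] == 0.0)
    assert np.all(trace["Gs"] == 0.0)


def test_cs_event_sets_pool_calcium(params, coarse_cfg):
    _, trace = integrate(resting_state(params), [(0.1, "CS")], params, coarse_cfg, 0.5)
    i = trace.event_index("CS")
    assert trace.time[i] == pytest.approx(0.1)
    assert trace["x"][i] == pytest.approx(params.x_init_on_CS)
    assert trace["x"][i - 1] < 1.0


def test_unknown_event_label_rejected(params, coarse_cfg):
    with pytest.raises(ValueError):
        integrate(resting_state(params), [(0.1, "CR")], params, coarse_cfg, 0.5)


def test_determinism_bit_identical(params, coarse_cfg):
    runs = []
    for _ in range(2):
        _, tr = integrate(resting_state(params), [(0.1, "CS"), (0.25, "US")],
                          params, coarse_cfg, 1.0)
        runs.append(tr)
    assert np.array_equal(runs[0].data, runs[1].data)
    assert np.array_equal(runs[0].algebraic, runs[1].algebraic)


def test_step_size_robustness(params):
    """Halving the step changes every recorded species by < 1 % pointwise
    (relative to each species' dynamic range) on a 150 ms-ISI trial."""
    traces = {}
    for dt, stride in ((2e-4, 10), (1e-4, 20)):
        cfg = IntegratorConfig(dt=dt, record_stride=stride)  # 2 ms sampling both
        _, traces[dt] = integrate(resting_state(params),
                                  [(0.1, "CS"), (0.25, "US")], params, cfg, 2.0)
    a, b = traces[2e-4].data, traces[1e-4].data
    scale = np.maximum(np.abs(b).max(axis=0), 1e-6)
    assert np.max(np.abs(a - b) / scale) < 0.01


def test_backward_euler_agrees_with_fine_rk4_at_rest(params):
    """Unstimulated 100 ms: production backward Euler vs a 5x finer explicit
    RK4 oracle, within 1e-4 relative per species."""
    s0 = resting_state(params)
    be_cfg = IntegratorConfig(dt=25e-6, record_stride=400)
    rk_cfg = IntegratorConfig(dt=5e-6, method="rk4_oracle", record_stride=2000)
    end_be, _ = integrate(s0, [], params, be_cfg, 0.1)
    end_rk, _ = integrate(s0, [], params, rk_cfg, 0.1)
    a, b = end_be.to_vector(), end_rk.to_vector()
    assert np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-6)) < 1e-4


def test_newton_failure_raises_with_time(params):
    cfg = IntegratorConfig(dt=50.0, newton_max_iter=1, newton_tol=1e-14,
                           validate=False)
    state = resting_state(params)
    state.t_since_CS = 0.0  # window active, strong kinetics
    state.cAMP = 40.0
    with pytest.raises(IntegrationError):
        integrate(state, [], params, cfg, 200.0)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        IntegratorConfig(dt=0.0)
    with pytest.raises(ValueError):
        IntegratorConfig(record_stride=0)
    with pytest.raises(ValueError):
        IntegratorConfig(method="crank_nicolson")
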