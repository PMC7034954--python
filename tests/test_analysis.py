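"""Learning read-outs: activation latency, amplification, learning curves."""

import numpy as np
import pytest

from dendroclock import (ModelParameters, SimulationTrace, StimulusProtocol,
                         TrainingResult, TrialRecord, calcium_amplification,
                         isi_sweep, pairings_to_learn, rgs_activation_time)
from dendroclock.state import ALGEBRAIC, SPECIES


def synthetic_trace(z_step_at=0.5, rgs_ramp=False, with_cs=True, n=1001):
    """Constructed fixture: z steps above threshold at an exact time."""
    t = np.linspace(0.0, 1.0, n)
    data = np.zeros((n, len(SPECIES)))
    data[:, SPECIES.index("z")] = np.where(t >= z_step_at, 0.5, 0.0)
    if rgs_ramp:
        data[:, SPECIES.index("RGS")] = np.clip((t - 0.2) / 0.6, 0.0, 1.0)
    alg = np.zeros((n, len(ALGEBRAIC)))
    events = [(0.0, "CS")] if with_cs else []
    return SimulationTrace(time=t, data=data, algebraic=alg, events=events)


class TestActivationTime:
    def test_step_fixture_recovers_exact_time(self, params):
        tr = synthetic_trace(z_step_at=0.5)
        t = rgs_activation_time(tr, params)
        assert t == pytest.approx(0.5, abs=2e-3)

    def test_absent_when_never_above_threshold(self, params):
        tr = synthetic_trace(z_step_at=2.0)  # never steps inside the trace
        assert rgs_activation_time(tr, params) is None

    def test_requires_cs_event(self, params):
        tr = synthetic_trace(with_cs=False)
        with pytest.raises(ValueError):
            rgs_activation_time(tr, params)

    def test_rgs_fraction_criterion(self, params):
        tr = synthetic_trace(rgs_ramp=True)
        t = rgs_activation_time(tr, params, criterion="rgs_fraction", fraction=0.5)
        assert t == pytest.approx(0.5, abs=2e-3)  # ramp reaches half max at 0.5
        with pytest.raises(ValueError):
            rgs_activation_time(tr, params, criterion="rgs_fraction", fraction=1.5)
        with pytest.raises(ValueError):
            rgs_activation_time(tr, params, criterion="peak")


def record(i, integral, **kw):
    defaults = dict(index=i, isi=0.15, rgs_activation_time=None, anticipated=False,
                    peak_Ca=1.0, Ca_integral=integral, end_AC=0.0, end_cAMP=0.0,
                    end_PKA=0.0, end_PDE=0.0, end_RGS=0.0)
    defaults.update(kw)
    return TrialRecord(**defaults)


class TestAmplification:
    def proto(self):
        return StimulusProtocol.pairing_series(2, 0.15)

    def test_doubled_integral_is_100_percent(self):
        res = TrainingResult(records=[record(1, 2.0), record(2, 4.0)], protocol=self.proto())
        assert calcium_amplification(res) == pytest.approx(100.0)

    def test_identical_trials_give_zero(self):
        res = TrainingResult(records=[record(1, 2.0), record(2, 2.0)], protocol=self.proto())
        assert calcium_amplification(res) == pytest.approx(0.0)

    def test_zero_baseline_raises(self):
        res = TrainingResult(records=[record(1, 0.0), record(2, 1.0)], protocol=self.proto())
        with pytest.raises(ZeroDivisionError):
            calcium_amplification(res)

    def test_needs_two_trials(self):
        res = TrainingResult(records=[record(1, 1.0)], protocol=self.proto())
        with pytest.raises(ValueError):
            calcium_amplification(res)


def test_record_invariant_anticipation_needs_early_activation():
    with pytest.raises(ValueError):
        record(1, 1.0, anticipated=True)                       # no activation time
    with pytest.raises(ValueError):
        record(1, 1.0, anticipated=True, rgs_activation_time=0.2)  # after the US
    ok = record(1, 1.0, anticipated=True, rgs_activation_time=0.1)
    assert ok.anticipated


class TestLearningCurves:
    def test_input_validation(self, params, coarse_cfg):
        with pytest.raises(ValueError):
            pairings_to_learn(-0.1, params, coarse_cfg)
        with pytest.raises(ValueError):
            pairings_to_learn(0.15, params, coarse_cfg, max_pairings=0)
        with pytest.raises(ValueError):
            isi_sweep([], params, coarse_cfg)

    def test_sweep_single_element_matches_pairings_to_learn(self, params, coarse_cfg):
        n = pairings_to_learn(0.15, params, coarse_cfg, max_pairings=14)
        table = isi_sweep([0.15], params, coarse_cfg, max_pairings=14)
        assert len(table) == 1
        assert table["pairings_to_learn"].iloc[0] == n
        assert table["final_rgs_activation_time_s"].iloc[0] < 0.15

    def test_unlearnable_isi_returns_absent(self, params, coarse_cfg):
        """An ISI shorter than the calcium-signal onset lag can never be
        anticipated: the gating variable cannot charge that fast."""
        assert pairings_to_learn(0.05, params, coarse_cfg, max_pairings=8) is None
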