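import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haemopost.windkessel import (
    PressureTargets,
    WindkesselError,
    WindkesselParams,
    derive_pressure_targets,
    normalize_branch_flows,
    retune_scaled,
    simulate_network,
    tune_wk3,
)

PERIOD = 60.0 / 94.0


def _inflow(n=64, mean=100.0, pulsatility=0.9):
    t = np.arange(n) * PERIOD / n
    q = mean * (1.0 + pulsatility * np.sin(2 * np.pi * t / PERIOD))
    return t, q


# ------------------------------------------------------------- targets


def test_pressure_targets_from_brachial():
    t = derive_pressure_targets(138.0, 81.0)
    assert t.ps == pytest.approx(0.83 * 138 + 0.15 * 81)
    assert t.ps_rounded == 127
    assert t.pd == 81.0
    assert t.map == pytest.approx(81 + (t.ps - 81) / 3)


def test_pressure_targets_validation():
    with pytest.raises(WindkesselError):
        derive_pressure_targets(80.0, 90.0)
    with pytest.raises(WindkesselError):
        PressureTargets(ps=100.0, pd=120.0, brachial_ps=1, brachial_pd=1)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.floats(90.0, 200.0),
    st.floats(40.0, 85.0),
)
def test_targets_property_ordering(ps_b, pd_b):
    t = derive_pressure_targets(ps_b, pd_b)
    assert t.pd < t.map < t.ps
    assert t.ps <= ps_b  # central systolic never exceeds brachial systolic


def test_normalize_branch_flows():
    out = normalize_branch_flows({"a": 2.0, "b": 6.0}, plane_difference=4.0)
    assert sum(out.values()) == pytest.approx(4.0)
    assert out["b"] / out["a"] == pytest.approx(3.0)


# ------------------------------------------------------------- simulation


def test_steady_state_matches_resistive_divider():
    """Constant inflow: junction pressure must equal Q * R_parallel and the
    cycle mass balance must close, both within 0.1%."""
    t, _ = _inflow()
    q = np.full_like(t, 80.0)
    params = [
        WindkesselParams("a", 0.1, 1.0, 0.5, 40.0),
        WindkesselParams("b", 0.2, 1.5, 0.3, 40.0),
    ]
    state = simulate_network(t, q, params, PERIOD)
    r_par = 1.0 / sum(1.0 / (p.r1 + p.r2) for p in params)
    assert state.mean_pressure == pytest.approx(80.0 * r_par, rel=1e-3)
    assert state.ps - state.pd < 1e-3 * state.mean_pressure
    assert abs(state.mass_balance_error()) < 1e-3


def test_pulsatile_mass_balance_closes():
    t, q = _inflow()
    params = [WindkesselParams("a", 0.08, 0.9, 1.2, 100.0)]
    state = simulate_network(t, q, params, PERIOD)
    assert state.converged
    assert abs(state.mass_balance_error()) < 1e-3


def test_mean_pressure_tracks_mean_flow():
    t, q = _inflow(mean=90.0)
    params = [WindkesselParams("a", 0.05, 0.95, 1.0, 90.0)]
    state = simulate_network(t, q, params, PERIOD)
    assert state.mean_pressure == pytest.approx(90.0 * 1.0, rel=0.01)


def test_simulation_requires_outlets():
    t, q = _inflow()
    with pytest.raises(WindkesselError):
        simulate_network(t, q, [], PERIOD)


# ------------------------------------------------------------- tuning


def test_tuner_hits_pressure_targets():
    t, q = _inflow(mean=100.0)
    targets = derive_pressure_targets(138.0, 81.0)
    q_targets = {"upper": 30.0, "lower": 70.0}
    rho = {"upper": 0.1, "lower": 0.1}
    result = tune_wk3(t, q, PERIOD, targets, q_targets, rho)
    assert result.achieved_ps == pytest.approx(targets.ps, rel=0.01)
    assert result.achieved_pd == pytest.approx(targets.pd, rel=0.01)
    # mean flows split per target within 1%
    means = result.state.mean_outlet_flows()
    assert means[0] / means[1] == pytest.approx(30.0 / 70.0, rel=0.01)
    assert abs(result.state.mass_balance_error()) < 1e-3


def test_tuner_recovers_known_network():
    """Simulate a known WK3 network, then re-tune against its own Ps/Pd:
    the tuner must reproduce those pressures within 1%."""
    t, q = _inflow(mean=100.0)
    truth = [
        WindkesselParams("upper", 0.096, 0.864, 0.9, 30.0),
        WindkesselParams("lower", 0.0411, 0.37, 2.1, 70.0),
    ]
    ref = simulate_network(t, q, truth, PERIOD)
    targets = PressureTargets(ref.ps, ref.pd, brachial_ps=ref.ps, brachial_pd=ref.pd)
    result = tune_wk3(
        t, q, PERIOD, targets, {"upper": 30.0, "lower": 70.0}, {"upper": 0.1, "lower": 0.1}
    )
    assert result.achieved_ps == pytest.approx(ref.ps, rel=0.01)
    assert result.achieved_pd == pytest.approx(ref.pd, rel=0.01)


def test_tuner_rejects_inconsistent_flow_targets():
    t, q = _inflow(mean=100.0)
    targets = derive_pressure_targets(138.0, 81.0)
    with pytest.raises(WindkesselError, match="match the inflow"):
        tune_wk3(t, q, PERIOD, targets, {"a": 10.0}, {"a": 0.1})


def test_retune_scaled_keeps_pressures():
    """+25% flow with unchanged pressure targets: resistances drop by ~20%,
    pressures stay on target."""
    t, q = _inflow(mean=100.0)
    targets = derive_pressure_targets(138.0, 81.0)
    q_targets = {"upper": 30.0, "lower": 70.0}
    rho = {"upper": 0.1, "lower": 0.1}
    base = tune_wk3(t, q, PERIOD, targets, q_targets, rho)
    scaled = retune_scaled(t, q * 1.25, PERIOD, targets, q_targets, rho, factor=1.25)
    assert scaled.achieved_ps == pytest.approx(targets.ps, rel=0.01)
    assert scaled.achieved_pd == pytest.approx(targets.pd, rel=0.01)
    for pb, ps_ in zip(base.params, scaled.params):
        assert ps_.r_tot == pytest.approx(pb.r_tot / 1.25, rel=0.05)
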