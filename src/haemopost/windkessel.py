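"""Pressure targets, branch-flow normalization and three-element Windkessel
(WK3) outlet calibration on a 0D lumped model of the aorta.

The network is an imposed inflow feeding a zero-resistance junction with all
WK3 outlets in parallel; each outlet is a proximal resistance R1 in series
with an (R2 || C) block referenced to zero distal pressure.  This module
works in clinical units throughout (mmHg, ml/s, ml/mmHg), the units WK3
parameters are conventionally stated in.

Central pressure targets follow the brachial-to-aortic estimates
P_d = P_d' and P_s = 0.83 P_s' + 0.15 P_d'.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import interp1d
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import brentq


class WindkesselError(RuntimeError):
    pass


@dataclass(frozen=True)
class PressureTargets:
    """Central systolic/diastolic targets derived from a brachial cuff pair."""

    ps: float  # mmHg
    pd: float  # mmHg
    brachial_ps: float
    brachial_pd: float

    def __post_init__(self):
        if not (self.ps > self.pd > 0):
            raise WindkesselError(
                f"inconsistent pressure targets: Ps={self.ps} must exceed Pd={self.pd} > 0"
            )

    @property
    def pulse(self) -> float:
        return self.ps - self.pd

    @property
    def map(self) -> float:
        """Mean arterial pressure estimate Pd + pulse/3."""
        return self.pd + self.pulse / 3.0

    @property
    def ps_rounded(self) -> int:
        return int(round(self.ps))

    @property
    def pd_rounded(self) -> int:
        return int(round(self.pd))


def derive_pressure_targets(brachial_ps: float, brachial_pd: float) -> PressureTargets:
    """Central targets from a brachial measurement: Pd = Pd',
    Ps = 0.83 Ps' + 0.15 Pd'."""
    if not (brachial_ps > brachial_pd > 0):
        raise WindkesselError("brachial pair must satisfy Ps' > Pd' > 0")
    ps = 0.83 * brachial_ps + 0.15 * brachial_pd
    return PressureTargets(ps=ps, pd=brachial_pd, brachial_ps=brachial_ps, brachial_pd=brachial_pd)


def normalize_branch_flows(measured: dict[str, float], plane_difference: float) -> dict[str, float]:
    """Rescale a group of measured branch mean flows so they sum to the mean
    flow difference between the aortic planes bracketing the group."""
    total = sum(measured.values())
    if total <= 0:
        raise WindkesselError("group flow sum must be positive")
    if plane_difference <= 0:
        raise WindkesselError("plane flow difference must be positive")
    f = plane_difference / total
    return {k: v * f for k, v in measured.items()}


@dataclass
class WindkesselParams:
    """One outlet's WK3 parameters and its mean-flow target.

    rho_split = R1 / (R1 + R2) is the proximal share of the total resistance.
    """

    name: str
    r1: float  # mmHg.s/ml
    r2: float  # mmHg.s/ml
    c: float  # ml/mmHg
    q_target: float  # ml/s

    def __post_init__(self):
        if min(self.r1, self.r2, self.c) <= 0:
            raise WindkesselError(f"{self.name}: R1, R2, C must be positive")

    @property
    def r_tot(self) -> float:
        return self.r1 + self.r2

    @property
    def rho_split(self) -> float:
        return self.r1 / (self.r1 + self.r2)


@dataclass
class NetworkState:
    """Final-cycle solution of the 0D network at cyclic periodicity."""

    times: np.ndarray  # (n_t,) within the final cycle, s
    p_inlet: np.ndarray  # junction pressure, mmHg
    p_cap: np.ndarray  # (n_t, n_outlets) capacitor pressures, mmHg
    q_out: np.ndarray  # (n_t, n_outlets) outlet flows (through R1), ml/s
    q_in: np.ndarray  # (n_t,) imposed inflow, ml/s
    r2: np.ndarray  # (n_outlets,)
    c: np.ndarray  # (n_outlets,)
    n_cycles: int
    converged: bool

    @property
    def ps(self) -> float:
        return float(self.p_inlet.max())

    @property
    def pd(self) -> float:
        return float(self.p_inlet.min())

    @property
    def mean_pressure(self) -> float:
        return float(self.p_inlet.mean())

    def mean_outlet_flows(self) -> np.ndarray:
        return self.q_out.mean(axis=0)

    def mass_balance_error(self) -> float:
        """Relative cycle mass defect: (inflow volume - distal outflow volume
        - capacitor storage change) / inflow volume, using the integrator's
        own backward-Euler quadrature."""
        dt = self.times[1] - self.times[0]
        vin = self.q_in[1:].sum() * dt
        v_distal = float(((self.p_cap[1:] / self.r2).sum()) * dt)
        storage = float((self.c * (self.p_cap[-1] - self.p_cap[0])).sum())
        return (vin - v_distal - storage) / vin if vin else 0.0


def _periodic_interp(times: np.ndarray, values: np.ndarray, period: float):
    t = np.concatenate([times, [times[0] + period]])
    v = np.concatenate([values, [values[0]]])
    f = interp1d(t, v, kind="linear")

    def q(tq):
        return f(np.mod(tq - times[0], period) + times[0])

    return q


def simulate_network(
    inflow_times: np.ndarray,
    inflow_values: np.ndarray,
    params: list[WindkesselParams],
    period: float,
    dt: float = 1e-3,
    n_cycles_max: int = 60,
    periodicity_tol: float = 0.01,
) -> NetworkState:
    """Integrate the 0D network to cyclic periodicity.

    Implicit (backward) Euler at ``dt``; cyclic periodicity is declared when
    systolic and diastolic junction pressure change by less than
    ``periodicity_tol`` (1% by default) between subsequent cycles.
    """
    if not params:
        raise WindkesselError("at least one outlet is required")
    q_of = _periodic_interp(np.asarray(inflow_times, float), np.asarray(inflow_values, float), period)
    n = len(params)
    r1 = np.array([p.r1 for p in params])
    r2 = np.array([p.r2 for p in params])
    c = np.array([p.c for p in params])
    n_steps = max(2, int(round(period / dt)))
    dt = period / n_steps
    # unknowns x = [p_cap(1..n), p_junction]; implicit Euler system A x = b
    A = np.zeros((n + 1, n + 1))
    A[np.arange(n), np.arange(n)] = c / dt + 1.0 / r2 + 1.0 / r1
    A[np.arange(n), n] = -1.0 / r1
    A[n, :n] = -1.0 / r1
    A[n, n] = (1.0 / r1).sum()
    lu = lu_factor(A)

    # start from the steady state of the mean inflow
    q_mean = float(np.mean(inflow_values))
    r_tot = r1 + r2
    p_j = q_mean / (1.0 / r_tot).sum() if q_mean > 0 else 0.0
    p_cap = p_j * r2 / r_tot

    t_cycle = np.arange(n_steps + 1) * dt
    ps_prev = pd_prev = None
    for cycle in range(1, n_cycles_max + 1):
        pj_hist = np.empty(n_steps + 1)
        pc_hist = np.empty((n_steps + 1, n))
        qo_hist = np.empty((n_steps + 1, n))
        qi_hist = np.empty(n_steps + 1)
        # initial sample (end of previous step state)
        pj0 = (q_of(0.0) + (p_cap / r1).sum()) / (1.0 / r1).sum()
        pj_hist[0], pc_hist[0] = pj0, p_cap
        qo_hist[0] = (pj0 - p_cap) / r1
        qi_hist[0] = q_of(0.0)
        for k in range(1, n_steps + 1):
            t = k * dt
            q_in = float(q_of(t))
            b = np.concatenate([c / dt * p_cap, [q_in]])
            x = lu_solve(lu, b)
            p_cap, p_j = x[:n], x[n]
            pj_hist[k], pc_hist[k] = p_j, p_cap
            qo_hist[k] = (p_j - p_cap) / r1
            qi_hist[k] = q_in
        ps, pd = pj_hist.max(), pj_hist.min()
        if ps_prev is not None:
            if abs(ps - ps_prev) <= periodicity_tol * abs(ps_prev) and abs(
                pd - pd_prev
            ) <= periodicity_tol * abs(pd_prev):
                return NetworkState(
                    t_cycle, pj_hist, pc_hist, qo_hist, qi_hist, r2, c, cycle, True
                )
        ps_prev, pd_prev = ps, pd
    raise WindkesselError(
        f"no cyclic periodicity within {n_cycles_max} cycles "
        f"(last Ps={ps:.2f}, Pd={pd:.2f} mmHg)"
    )


@dataclass
class TuningResult:
    params: list[WindkesselParams]
    achieved_ps: float
    achieved_pd: float
    state: NetworkState
    n_outer_iterations: int


def tune_wk3(
    inflow_times: np.ndarray,
    inflow_values: np.ndarray,
    period: float,
    targets: PressureTargets,
    q_targets: dict[str, float],
    rho_split: dict[str, float],
    tol: float = 0.01,
    dt: float = 1e-3,
    max_outer: int = 12,
) -> TuningResult:
    """Tune WK3 parameters so simulated Ps and Pd hit the targets within 1%.

    Total resistances follow R_tot,i = MAP / Qbar_i (zero distal pressure),
    split by rho; compliances share a common time constant whose global
    scale is tuned by bracketed root finding on the simulated pulse
    pressure.  A small outer fixed-point loop on the working (MAP, pulse)
    set-points absorbs the difference between the clinical MAP estimate and
    the waveform's actual mean-to-extremes relation.
    """
    q_mean_in = float(np.mean(inflow_values))
    q_sum = sum(q_targets.values())
    if abs(q_sum - q_mean_in) > 0.02 * abs(q_mean_in):
        raise WindkesselError(
            f"outlet mean-flow targets ({q_sum:.2f} ml/s) must match the inflow "
            f"mean ({q_mean_in:.2f} ml/s) within 2%"
        )
    names = list(q_targets)

    map_work = targets.map
    pp_work = targets.pulse

    def build(map_val: float, c_scale: float) -> list[WindkesselParams]:
        out = []
        for name in names:
            r_tot = map_val / q_targets[name]
            rho = rho_split[name]
            # common time constant tau = R2*C, scaled globally
            c = c_scale / (r_tot * (1.0 - rho))
            out.append(
                WindkesselParams(name, rho * r_tot, (1.0 - rho) * r_tot, c, q_targets[name])
            )
        return out

    def simulate(map_val: float, c_scale: float) -> NetworkState:
        return simulate_network(inflow_times, inflow_values, build(map_val, c_scale), period, dt=dt)

    state = None
    for outer in range(1, max_outer + 1):
        # bracket the global compliance scale on pulse pressure (PP decreases
        # monotonically with compliance)
        lo, hi = 1e-3, 1e2

        def pp_err(s):
            st = simulate(map_work, s)
            return (st.ps - st.pd) - pp_work

        flo, fhi = pp_err(lo), pp_err(hi)
        if flo * fhi > 0:
            raise WindkesselError(
                "capacitance root-finding bracket not found: pulse-pressure "
                f"errors at bracket ends are {flo:.2f} and {fhi:.2f} mmHg"
            )
        c_scale = brentq(pp_err, lo, hi, xtol=1e-6, rtol=1e-6)
        state = simulate(map_work, c_scale)
        err_s = (state.ps - targets.ps) / targets.ps
        err_d = (state.pd - targets.pd) / targets.pd
        if abs(err_s) <= tol and abs(err_d) <= tol:
            return TuningResult(build(map_work, c_scale), state.ps, state.pd, state, outer)
        # shift the working set-points by the residuals
        map_work = map_work - ((state.ps - targets.ps) + (state.pd - targets.pd)) / 2.0
        pp_work = pp_work - ((state.ps - state.pd) - targets.pulse)
    raise WindkesselError(
        f"tuning did not reach Ps/Pd within {100 * tol:.0f}% in {max_outer} outer "
        f"iterations (achieved {state.ps:.2f}/{state.pd:.2f} mmHg)"
    )


def retune_scaled(
    inflow_times,
    inflow_values,
    period,
    targets: PressureTargets,
    q_targets: dict[str, float],
    rho_split: dict[str, float],
    factor: float = 1.25,
    **kw,
) -> TuningResult:
    """Re-tune for a flow-scaled case: outlet mean-flow targets scaled by
    ``factor`` with unchanged pressure targets (the inflow waveform passed
    here must already be the scaled one)."""
    q_scaled = {k: v * factor for k, v in q_targets.items()}
    return tune_wk3(inflow_times, inflow_values, period, targets, q_scaled, rho_split, **kw)
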