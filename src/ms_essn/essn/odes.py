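"""Deterministic (mean-field) approximation of a net.

The vector field is ``dx/dt = sum_r L_r a_r(x, t)`` with ``a_r`` the
propensity of reaction ``r`` evaluated on a real-valued state — the usual
fluid limit of the underlying Markov jump process.  Scheduled events
become state jumps with an integrator restart.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from . import kernels
from .compile import CompiledNet, compile_net
from .model import ESSNModel, EventSchedule, Marking, ModelError
from .simulate import Trajectory

__all__ = ["derive_vector_field", "ode_solve", "IntegratorError"]


class IntegratorError(RuntimeError):
    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


def derive_vector_field(model: ESSNModel | CompiledNet, params=None):
    """Right-hand side ``f(x, t) -> dx/dt`` over the dynamic variables.

    The dimension equals the number of ``(place, color)`` state variables
    of the net (isolated annotation places carry no dynamics).
    """
    net = model if isinstance(model, CompiledNet) else compile_net(model, params)
    arrays = net.arrays()
    Lt = np.asarray(arrays[-1], dtype=np.float64).T.copy()

    def field(x, t=0.0):
        a = kernels.propensities_real(np.asarray(x, dtype=np.float64), arrays)
        return Lt @ a

    field.n_equations = net.n_variables
    field.columns = list(net.var_names)
    field.compiled_net = net
    return field


def ode_solve(field, x0, record_grid, events: EventSchedule | None = None,
              rtol: float = 1e-6, atol: float = 1e-9,
              method: str = "LSODA", columns=None) -> Trajectory:
    """Integrate a vector field over a grid with event restarts.

    States are clipped at zero after each segment (the fluid limit can
    undershoot by integration error; clips larger than ``atol`` are
    counted in the trajectory metadata).
    """
    grid = np.asarray(record_grid, dtype=np.float64)
    if np.any(np.diff(grid) <= 0):
        raise ModelError("record grid must be strictly increasing")
    if isinstance(x0, Marking):
        net = getattr(field, "compiled_net", None)
        if net is None:
            raise ModelError("marking initial state needs a derived field")
        x = x0.as_vector(net.variables).astype(np.float64)
    else:
        x = np.asarray(x0, dtype=np.float64).copy()
    columns = columns or getattr(field, "columns",
                                 [f"x{i}" for i in range(len(x))])
    if events is not None and len(events):
        net = getattr(field, "compiled_net", None)
        if net is not None:
            ev_times, ev_deltas = events.arrays(net.variables)
        else:
            raise ModelError("events require a field derived from a model")
    else:
        ev_times = np.empty(0)
        ev_deltas = np.empty((0, len(x)))

    t0, t_end = float(grid[0]), float(grid[-1])
    # events exactly at the start apply before integration begins
    for k, te in enumerate(ev_times):
        if te == t0:
            x = x + ev_deltas[k]
    boundaries = sorted({t for t in ev_times if t0 < t <= t_end})
    if not boundaries or boundaries[-1] != t_end:
        boundaries.append(t_end)
    segments = [t0] + boundaries
    out = np.zeros((len(grid), len(x)))
    clips = 0
    # record grid points that coincide with t0
    mask0 = grid == t0
    out[mask0] = x
    rhs = lambda t, y: field(y, t)
    for s0, s1 in zip(segments, segments[1:]):
        inner = grid[(grid > s0) & (grid <= s1)]
        if s1 > s0:
            t_eval = inner if inner.size else None
            sol = solve_ivp(rhs, (s0, s1), x, method=method, rtol=rtol,
                            atol=atol, t_eval=t_eval, dense_output=False)
            if not sol.success:
                raise IntegratorError(
                    f"integration failed at t={sol.t[-1] if sol.t.size else s0}: "
                    f"{sol.message}", time=float(sol.t[-1]) if sol.t.size else s0)
            if inner.size:
                ys = sol.y.T
                clips += int(np.sum(ys < -atol))
                out[(grid > s0) & (grid <= s1)] = np.clip(ys, 0.0, None)
            x = np.clip(sol.y[:, -1], 0.0, None)
        # apply every event scheduled exactly at s1, in schedule order
        for k, te in enumerate(ev_times):
            if te == s1:
                x = x + ev_deltas[k]
                if np.any(x < 0):
                    raise IntegratorError(f"event at t={s1} drove state negative",
                                          time=s1)
        # grid points exactly at s1 see the post-event state
        out[grid == s1] = x
    return Trajectory(grid, out, list(columns), "ode",
                      meta={"clipped_values": clips, "rtol": rtol, "atol": atol})
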