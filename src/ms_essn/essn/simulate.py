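"""Stochastic simulation backends: exact SSA and tau-leaping.

Both backends operate on the compiled-array encoding and are seeded
explicitly; identical ``(model, initial marking, seed, grid)`` inputs
give bit-identical trajectories.  Models whose general transitions carry
python-callable rates are handled by a slower pure-python stepper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels
from .compile import CompiledNet, compile_net
from .model import ESSNModel, EventSchedule, Marking, ModelError
from .unfold import propensity, unfold

__all__ = ["Trajectory", "ssa_simulate", "tau_leap_simulate",
           "ensemble_summary", "SimulationError"]


class SimulationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Time-stamped state path from one simulation run.

    ``states`` has one row per grid time and one column per ``(place,
    color)`` variable; integer-valued for the ssa / tau_leap backends,
    nonnegative reals for the ode backend.
    """

    times: np.ndarray
    states: np.ndarray
    columns: list[str]
    backend: str
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) < 0):
            raise ModelError("trajectory times must be increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.columns)
        df.insert(0, "time", self.times)
        return df

    def get(self, column: str) -> np.ndarray:
        return self.states[:, self.columns.index(column)]

    def sum_over(self, place: str) -> np.ndarray:
        """Sum all color variables of one folded place."""
        cols = [i for i, c in enumerate(self.columns)
                if c == place or c.startswith(place + ":")]
        return self.states[:, cols].sum(axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _prepare(model: ESSNModel | CompiledNet, m0: Marking, t_end: float,
             events: EventSchedule | None, record_grid, params):
    if t_end <= 0:
        raise ModelError(f"t_end must be positive, got {t_end}")
    net = model if isinstance(model, CompiledNet) else None
    callables = False
    if net is None:
        reactions = unfold(model)
        callables = any(callable(r.rate) for r in reactions)
        if not callables:
            net = CompiledNet(model, reactions, params)
        mdl = model
    else:
        mdl = net.model
        reactions = net.reactions
    variables = mdl.variables()
    if record_grid is None:
        record_grid = np.linspace(0.0, t_end, 101)
    grid = np.asarray(record_grid, dtype=np.float64)
    if grid.size and (grid.min() < 0 or grid.max() > t_end):
        raise ModelError("record grid must lie within [0, t_end]")
    events = events or EventSchedule()
    ev_times, ev_deltas = events.arrays(variables)
    x0 = m0.as_vector(variables)
    names = [p if c is None else f"{p}:{c}" for p, c in variables]
    return net, reactions, mdl, grid, ev_times, ev_deltas, x0, names, callables


def ssa_simulate(model, m0: Marking, t_end: float,
                 events: EventSchedule | None = None, seed: int = 0,
                 record_grid=None, params=None,
                 max_steps: int = 200_000_000) -> Trajectory:
    """Exact Gillespie direct-method simulation.

    Waiting times are exponential with the total propensity, the firing
    reaction is chosen proportionally to the individual propensities, and
    scheduled events are applied exactly at their times.
    """
    (net, reactions, mdl, grid, ev_times, ev_deltas, x0, names,
     callables) = _prepare(model, m0, t_end, events, record_grid, params)
    if callables:
        states, status = _python_ssa(reactions, mdl, x0, names, t_end, grid,
                                     ev_times, ev_deltas, seed, params,
                                     max_steps)
    else:
        states, status, _steps = kernels.ssa_kernel(
            x0, 0.0, float(t_end), grid, ev_times, ev_deltas,
            *net.arrays(), int(seed) % (2 ** 32), int(max_steps))
    if status == kernels.NEGATIVE_EVENT:
        raise SimulationError("event schedule drove a count negative")
    if status == kernels.MAX_STEPS:
        raise SimulationError(f"SSA exceeded {max_steps} steps")
    return Trajectory(grid, np.asarray(states, dtype=np.int64), names,
                      "ssa", seed)


def tau_leap_simulate(model, m0: Marking, t_end: float,
                      events: EventSchedule | None = None, seed: int = 0,
                      record_grid=None, params=None,
                      tau: float = 0.01) -> Trajectory:
    """Poisson tau-leaping; converges to SSA statistics as tau -> 0."""
    if tau <= 0:
        raise ModelError(f"tau must be positive, got {tau}")
    (net, reactions, mdl, grid, ev_times, ev_deltas, x0, names,
     callables) = _prepare(model, m0, t_end, events, record_grid, params)
    if callables:
        raise ModelError("tau-leaping requires kernel-encodable rate forms")
    states, status = kernels.tau_kernel(
        x0, 0.0, float(t_end), grid, ev_times, ev_deltas,
        *net.arrays(), int(seed) % (2 ** 32), float(tau))
    if status == kernels.NEGATIVE_EVENT:
        raise SimulationError("event schedule drove a count negative")
    return Trajectory(grid, np.asarray(np.rint(states), dtype=np.int64),
                      names, "tau_leap", seed)


def _python_ssa(reactions, model, x0, names, t_end, grid, ev_times,
                ev_deltas, seed, params, max_steps):
    """Reference stepper for models with callable general rates."""
    rng = np.random.RandomState(int(seed) % (2 ** 32))
    index = {k: i for i, k in enumerate(names)}
    x = x0.astype(np.int64).copy()
    out = np.zeros((len(grid), len(x)), dtype=np.int64)
    t, gpos, epos, steps = 0.0, 0, 0, 0

    def marking():
        m = Marking(dict(zip(names, x.tolist())), time=t)
        return m

    while True:
        m = marking()
        a = np.array([propensity(r, m, t, params) for r in reactions])
        a0 = a.sum()
        t_next = t - np.log(1.0 - rng.random_sample()) / a0 if a0 > 0 else np.inf
        if epos < len(ev_times) and ev_times[epos] <= t_end:
            bound, is_event = ev_times[epos], True
        else:
            bound, is_event = t_end, False
        if t_next >= bound:
            while gpos < len(grid) and grid[gpos] < bound:
                out[gpos] = x
                gpos += 1
            t = bound
            if is_event:
                x = x + ev_deltas[epos]
                if np.any(x < 0):
                    return out, kernels.NEGATIVE_EVENT
                epos += 1
            else:
                while gpos < len(grid):
                    out[gpos] = x
                    gpos += 1
                return out, kernels.OK
        else:
            while gpos < len(grid) and grid[gpos] < t_next:
                out[gpos] = x
                gpos += 1
            r = np.searchsorted(np.cumsum(a), rng.random_sample() * a0)
            r = min(r, len(reactions) - 1)
            for key, delta in reactions[r].change.items():
                x[index[key]] += delta
            t = t_next
            steps += 1
            if steps >= max_steps:
                return out, kernels.MAX_STEPS


def ensemble_summary(trajectories: list[Trajectory],
                     columns: list[str] | None = None) -> pd.DataFrame:
    """Per-time, per-variable ensemble statistics (mean, median, IQR)."""
    if not trajectories:
        raise ValueError("empty ensemble")
    t0 = trajectories[0]
    cols = columns or t0.columns
    idx = [t0.columns.index(c) for c in cols]
    stack = np.stack([tr.states[:, idx] for tr in trajectories])  # (n, T, k)
    rows = []
    for j, c in enumerate(cols):
        block = stack[:, :, j]
        rows.append(pd.DataFrame({
            "time": t0.times,
            "variable": c,
            "mean": block.mean(axis=0),
            "median": np.median(block, axis=0),
            "q25": np.quantile(block, 0.25, axis=0),
            "q75": np.quantile(block, 0.75, axis=0),
        }))
    return pd.concat(rows, ignore_index=True)


def ssa_ensemble(model, m0: Marking, t_end: float, seeds,
                 events: EventSchedule | None = None, record_grid=None,
                 params=None, max_steps: int = 200_000_000) -> list[Trajectory]:
    """Many SSA runs sharing one compiled net (one seed per trajectory)."""
    if not isinstance(model, CompiledNet):
        model = compile_net(model, params)
    return [ssa_simulate(model, m0, t_end, events, s, record_grid, params,
                         max_steps) for s in seeds]
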