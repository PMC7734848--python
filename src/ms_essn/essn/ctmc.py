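"""Exact transient analysis of the underlying CTMC (small nets only).

Enumerates the reachability set from the initial marking, assembles the
infinitesimal generator from the reaction propensities, and solves the
master equation

    d pi(m_i, t) / dt = sum_k pi(m_k, t) q_{k,i}

with a Krylov matrix-exponential action.  Intended as a test oracle: the
state space of realistic models is far too large for this route, which is
exactly why the simulation backends exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import expm_multiply

from .model import ESSNModel, Marking
from .unfold import propensity, unfold

__all__ = ["TransientDistribution", "exact_transient_distribution",
           "StateSpaceOverflow"]


class StateSpaceOverflow(RuntimeError):
    """Reachable state space exceeded the configured cap."""


@dataclass
class TransientDistribution:
    """Probability vector over an enumerated reachable state space."""

    states: list[tuple]           # each state: tuple of counts over variables
    variables: list[str]
    probabilities: np.ndarray
    time: float

    def probability_of(self, state: dict) -> float:
        key = tuple(state.get(v, 0) for v in self.variables)
        try:
            return float(self.probabilities[self.states.index(key)])
        except ValueError:
            return 0.0


def exact_transient_distribution(model: ESSNModel, m0: Marking, t: float,
                                 state_cap: int = 20_000,
                                 params=None) -> TransientDistribution:
    reactions = unfold(model)
    variables = model.variable_names()
    x0 = tuple(int(v) for v in m0.as_vector(model.variables()))

    vindex = {v: i for i, v in enumerate(variables)}
    index: dict[tuple, int] = {x0: 0}
    states: list[tuple] = [x0]
    edges: list[tuple[int, int, float]] = []  # (from, to, rate)
    frontier = [x0]
    while frontier:
        nxt = []
        for state in frontier:
            i = index[state]
            m = Marking(dict(zip(variables, state)))
            for rx in reactions:
                a = propensity(rx, m, 0.0, params)
                if a <= 0.0:
                    continue
                new = list(state)
                for key, delta in rx.change.items():
                    new[vindex[key]] += delta
                new_t = tuple(new)
                if new_t not in index:
                    if len(states) >= state_cap:
                        raise StateSpaceOverflow(
                            f"reachability set exceeds cap of {state_cap} states"
                        )
                    index[new_t] = len(states)
                    states.append(new_t)
                    nxt.append(new_t)
                edges.append((i, index[new_t], a))
        frontier = nxt

    n = len(states)
    rows = np.array([e[0] for e in edges] + list(range(n)), dtype=np.int64)
    cols = np.array([e[1] for e in edges] + list(range(n)), dtype=np.int64)
    diag = np.zeros(n)
    for i, _j, a in edges:
        diag[i] -= a
    data = np.array([e[2] for e in edges] + list(diag))
    Q = csr_matrix((data, (rows, cols)), shape=(n, n))

    pi0 = np.zeros(n)
    pi0[0] = 1.0
    if t == 0:
        pi = pi0
    else:
        pi = expm_multiply(Q.T.tocsr() * float(t), pi0)
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
    total = float(pi.sum())
    if abs(total - 1.0) > 1e-9:
        raise RuntimeError(f"transient distribution sums to {total}")
    return TransientDistribution(states, variables, pi, float(t))
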