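"""Array encoding of an unfolded net for the fast simulation kernels.

The ground reactions of a model are packed into flat numpy arrays so the
SSA / tau-leap kernels and the ODE right-hand side can run inside numba.
Only the declarative rate forms (mass action, linear, bilinear, hill) are
encodable; models with python-callable rates fall back to the reference
simulator.
"""

from __future__ import annotations

import numpy as np

from .model import ESSNModel, ModelError
from .unfold import Reaction, unfold

__all__ = ["CompiledNet", "compile_net"]

KIND_MA = 0
KIND_HILL = 1
KIND_BILINEAR = 2
KIND_LINEAR = 3


class CompiledNet:
    """Flat-array view of a model's reactions.

    Attributes (n reactions, m variables):

    * ``kind``    int64[n]  — rate-law id
    * ``rate_c``  float64[n] — resolved rate constant
    * ``khalf``   float64[n] — half-saturation constant (hill only)
    * ``gi, gj``  int64[n]  — agent / substrate variable index (-1 unused)
    * ``in_start``int64[n+1], ``in_idx``/``in_mult`` — CSR input lists
    * ``L``       int64[n, m] — state-change vectors
    """

    def __init__(self, model: ESSNModel, reactions: list[Reaction],
                 params=None) -> None:
        self.model = model
        self.reactions = reactions
        self.variables = model.variables()
        self.var_names = model.variable_names()
        self.index = {k: i for i, k in enumerate(self.var_names)}
        n, m = len(reactions), len(self.variables)
        self.kind = np.zeros(n, dtype=np.int64)
        self.rate_c = np.zeros(n, dtype=np.float64)
        self.khalf = np.zeros(n, dtype=np.float64)
        self.gi = np.full(n, -1, dtype=np.int64)
        self.gj = np.full(n, -1, dtype=np.int64)
        self.L = np.zeros((n, m), dtype=np.int64)
        in_idx: list[int] = []
        in_mult: list[int] = []
        self.in_start = np.zeros(n + 1, dtype=np.int64)
        self._rate_names: list[tuple[int, str]] = []
        self._khalf_names: list[tuple[int, str]] = []
        table = dict(model.constants)
        if params is not None:
            table.update(params)
        for r, rx in enumerate(reactions):
            for key, mult in rx.inputs.items():
                in_idx.append(self.index[key])
                in_mult.append(mult)
            self.in_start[r + 1] = len(in_idx)
            for key, delta in rx.change.items():
                self.L[r, self.index[key]] = delta
            rate = rx.rate
            if callable(rate):
                raise ModelError(
                    f"{rx.name}: callable rates are not kernel-encodable"
                )
            if rx.kind == "mass_action":
                self.kind[r] = KIND_MA
                self.rate_c[r] = self._const(rate, table, r, self._rate_names)
            else:
                form = rate["form"]
                self.rate_c[r] = self._const(rate["rate"], table, r, self._rate_names)
                if form == "linear":
                    self.kind[r] = KIND_LINEAR
                    self.gi[r] = self.index[rate["agent"]]
                elif form == "bilinear":
                    self.kind[r] = KIND_BILINEAR
                    self.gi[r] = self.index[rate["agent"]]
                    self.gj[r] = self.index[rate["substrate"]]
                elif form == "hill":
                    self.kind[r] = KIND_HILL
                    self.gi[r] = self.index[rate["agent"]]
                    self.gj[r] = self.index[rate["substrate"]]
                    self.khalf[r] = self._const(rate["k_half"], table, r,
                                                self._khalf_names)
                else:
                    raise ModelError(f"unknown rate form {form!r}")
            if self.rate_c[r] < 0:
                raise ModelError(f"{rx.name}: negative rate constant")
        self.in_idx = np.array(in_idx, dtype=np.int64)
        self.in_mult = np.array(in_mult, dtype=np.int64)

    @staticmethod
    def _const(spec, table, r, names) -> float:
        if isinstance(spec, str):
            if spec not in table:
                raise ModelError(f"rate constant {spec!r} missing from parameters")
            names.append((r, spec))
            return float(table[spec])
        return float(spec)

    def update_params(self, params) -> None:
        """Refresh the numeric constants in place (same structure)."""
        table = dict(self.model.constants)
        table.update(params)
        for r, name in self._rate_names:
            self.rate_c[r] = float(table[name])
        for r, name in self._khalf_names:
            self.khalf[r] = float(table[name])

    def arrays(self) -> tuple:
        return (self.kind, self.rate_c, self.khalf, self.gi, self.gj,
                self.in_start, self.in_idx, self.in_mult, self.L)

    @property
    def n_variables(self) -> int:
        return len(self.variables)


def compile_net(model: ESSNModel, params=None,
                reactions: list[Reaction] | None = None) -> CompiledNet:
    if reactions is None:
        reactions = unfold(model)
    return CompiledNet(model, reactions, params)
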