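"""Color unfolding: ground transition instances and their rates.

A colored transition with binding variables is instantiated into one
:class:`Reaction` per admissible binding (guard true); neutral transitions
yield exactly one reaction.  Reactions are what the simulators, the ODE
derivation and the CTMC oracle operate on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .model import ESSNModel, Marking, ModelError, Transition

__all__ = ["Reaction", "unfold", "propensity", "fire", "EnablingError"]


class EnablingError(RuntimeError):
    """Firing attempted for a reaction that is not enabled."""


@dataclass
class Reaction:
    """A ground transition instance ``<t, c>`` after color unfolding.

    ``inputs`` / ``outputs`` map variable keys (``"Place"`` or
    ``"Place:color"``) to multiplicities; ``change`` is the integer vector
    ``L = O - I`` as a sparse dict.  ``rate`` is the resolved rate spec:
    a float (mass action), a declarative form dict with place references
    resolved to variable keys (general), or a python callable.
    """

    transition: str
    kind: str
    binding: dict
    inputs: dict
    outputs: dict
    change: dict
    rate: object

    @property
    def name(self) -> str:
        if not self.binding:
            return self.transition
        b = ",".join(f"{k}={v}" for k, v in self.binding.items())
        return f"{self.transition}[{b}]"


def _resolve_expr(model: ESSNModel, trans: Transition, place: str, expr, binding: dict):
    """Variable key for the token moved along one arc under a binding."""
    pl = model.places[place]
    if expr is None:
        if pl.color_domain:
            raise ModelError(
                f"transition {trans.name!r}: neutral arc on colored place {place!r}"
            )
        return place
    if not pl.color_domain:
        raise ModelError(
            f"transition {trans.name!r}: colored arc on neutral place {place!r}"
        )
    if len(pl.color_domain) != 1:
        raise ModelError("multi-class color domains need tuple expressions")
    cls = model.color_classes[pl.color_domain[0]]
    if isinstance(expr, tuple) and expr[0] == "const":
        color = expr[1]
    elif isinstance(expr, str):
        op = None
        var = expr
        if expr.endswith("++"):
            var, op = expr[:-2], "succ"
        elif expr.endswith("--"):
            var, op = expr[:-2], "pred"
        if var not in trans.variables:
            raise ModelError(
                f"transition {trans.name!r}: undeclared binding variable {var!r}"
            )
        if trans.variables[var] != cls.name:
            raise ModelError(
                f"transition {trans.name!r}: variable {var!r} is not of class "
                f"{cls.name!r}"
            )
        color = binding[var]
        if op == "succ":
            color = cls.successor(color)
        elif op == "pred":
            color = cls.predecessor(color)
    else:
        raise ModelError(f"transition {trans.name!r}: bad arc expression {expr!r}")
    if color not in cls.elements:
        raise ModelError(f"unknown color {color!r} in class {cls.name!r}")
    return f"{place}:{color}"


def _guard_holds(guard: dict | None, binding: dict) -> bool:
    if not guard:
        return True
    for var, cond in guard.items():
        val = binding.get(var)
        if "in" in cond and val not in cond["in"]:
            return False
        if "not_in" in cond and val in cond["not_in"]:
            return False
    return True


def _resolve_rate(model, trans, binding):
    rate = trans.rate
    if callable(rate) or isinstance(rate, (int, float)):
        return rate
    if isinstance(rate, str):
        return rate  # parameter name, resolved at compile time
    if isinstance(rate, dict):
        out = dict(rate)
        for key in ("agent", "substrate"):
            if key in out:
                pl = out[key]
                pobj = model.places[pl] if pl in model.places else None
                if pobj is not None and pobj.color_domain:
                    # colored operand: resolve via the arc variable binding
                    out[key] = _resolve_expr(model, trans, pl, out.get(f"{key}_expr", "l"), binding)
                # neutral places keep their own name as variable key
        out.pop("agent_expr", None)
        out.pop("substrate_expr", None)
        return out
    raise ModelError(f"transition {trans.name!r}: bad rate spec {rate!r}")


def unfold(model: ESSNModel) -> list[Reaction]:
    """One reaction per transition binding with a true guard.

    Bindings enumerate the Cartesian product of each declared variable's
    color-class elements; a transition with no variables is neutral and
    yields exactly one reaction.
    """
    reactions: list[Reaction] = []
    for trans in model.transitions.values():
        if trans.variables:
            names = list(trans.variables)
            spaces = [model.color_classes[trans.variables[v]].elements for v in names]
            bindings = [dict(zip(names, combo)) for combo in itertools.product(*spaces)]
        else:
            bindings = [{}]
        for binding in bindings:
            if not _guard_holds(trans.guard, binding):
                continue
            inputs: dict[str, int] = {}
            outputs: dict[str, int] = {}
            for arc in trans.inputs:
                key = _resolve_expr(model, trans, arc.place, arc.expr, binding)
                inputs[key] = inputs.get(key, 0) + arc.mult
            for arc in trans.outputs:
                key = _resolve_expr(model, trans, arc.place, arc.expr, binding)
                outputs[key] = outputs.get(key, 0) + arc.mult
            change = {k: -v for k, v in inputs.items()}
            for k, v in outputs.items():
                change[k] = change.get(k, 0) + v
            change = {k: v for k, v in change.items() if v != 0}
            rate = _resolve_rate(model, trans, binding)
            if isinstance(rate, dict):
                # general-rate locality: the form may only read input places
                for operand in ("agent", "substrate"):
                    if operand in rate and rate[operand] not in inputs:
                        raise ModelError(
                            f"transition {trans.name!r}: rate reads "
                            f"{rate[operand]!r} which is not an input place"
                        )
            reactions.append(
                Reaction(
                    transition=trans.name,
                    kind=trans.kind,
                    binding=binding,
                    inputs=inputs,
                    outputs=outputs,
                    change=change,
                    rate=rate,
                )
            )
    return reactions


def _rate_value(rate, params) -> float:
    if isinstance(rate, str):
        if params is None or rate not in params:
            raise ModelError(f"rate constant {rate!r} missing from parameter table")
        return float(params[rate])
    return float(rate)


def propensity(reaction: Reaction, marking: Marking, time: float = 0.0,
               params=None) -> float:
    """Rate of a ground transition instance in a marking.

    Mass action: ``omega * prod count**multiplicity`` over the input
    variables, zero whenever any input count is below its multiplicity.
    General: the configured form (or callable) evaluated on the input
    sub-marking and time; general rates see *only* the input places.
    """
    for key, mult in reaction.inputs.items():
        if marking[key] < mult:
            return 0.0
    rate = reaction.rate
    if reaction.kind == "mass_action":
        a = _rate_value(rate, params)
        for key, mult in reaction.inputs.items():
            a *= float(marking[key]) ** mult
        return a
    if callable(rate):
        sub = {k: marking[k] for k in reaction.inputs}
        a = float(rate(sub, time, params))
    else:
        c = _rate_value(rate["rate"], params)
        form = rate["form"]
        if form == "linear":
            a = c * marking[rate["agent"]]
        elif form == "bilinear":
            a = c * marking[rate["agent"]] * marking[rate["substrate"]]
        elif form == "hill":
            k = _rate_value(rate["k_half"], params)
            s = marking[rate["substrate"]]
            a = c * marking[rate["agent"]] * s / (k + s)
        else:
            raise ModelError(f"unknown general rate form {form!r}")
    if a < 0:
        raise ModelError(
            f"general rate of {reaction.name} returned {a} (< 0): contract violation"
        )
    return a


def fire(marking: Marking, reaction: Reaction) -> Marking:
    """Apply ``m' = m + O - I``; the input marking is left untouched."""
    for key, mult in reaction.inputs.items():
        if marking[key] < mult:
            raise EnablingError(
                f"{reaction.name} not enabled: needs {mult} tokens in {key!r}, "
                f"found {marking[key]}"
            )
    out = marking.copy()
    for key, delta in reaction.change.items():
        out[key] = out[key] + delta
    return out
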