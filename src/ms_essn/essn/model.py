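"""Structural representation of Extended Stochastic Symmetric Nets.

An ESSN is a stochastic Petri net whose places may carry colored tokens
(tokens tagged with an element of a finite, optionally circularly ordered
color class) and whose transitions are split into two kinds:

* ``mass_action`` ("standard") transitions fire with the mass-action law,
  rate constant times the product of input token counts raised to the arc
  multiplicities;
* ``general`` transitions carry an arbitrary rate function that may depend
  only on the marking of the transition's own input places and on time.

The classes here hold structure only; color unfolding, propensity
evaluation and simulation live in sibling modules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import yaml

__all__ = [
    "ColorClass",
    "Place",
    "ArcExpr",
    "Transition",
    "ESSNModel",
    "Marking",
    "EventSchedule",
    "ModelError",
    "save_model",
    "load_model",
]


class ModelError(ValueError):
    """Raised for ill-formed net structure (unknown places, bad arcs...)."""


@dataclass(frozen=True)
class ColorClass:
    """A finite color class, optionally with a circular successor order.

    ``elements`` are the subclass labels in order.  When ``ordered`` is
    true the successor operator ``++`` maps each element to the next one,
    wrapping from the last back to the first (circular order).
    """

    name: str
    elements: tuple[str, ...]
    ordered: bool = True

    def __post_init__(self) -> None:
        if not self.elements:
            raise ModelError(f"color class {self.name!r} has no elements")
        if len(set(self.elements)) != len(self.elements):
            raise ModelError(f"color class {self.name!r} has duplicate elements")

    def index(self, element: str) -> int:
        return self.elements.index(element)

    def successor(self, element: str) -> str:
        """Circular successor (the ``++`` operator)."""
        i = self.index(element)
        return self.elements[(i + 1) % len(self.elements)]

    def predecessor(self, element: str) -> str:
        i = self.index(element)
        return self.elements[(i - 1) % len(self.elements)]


@dataclass(frozen=True)
class Place:
    """A state variable of the net.

    ``color_domain`` lists the names of the color classes whose Cartesian
    product types the tokens; an empty tuple means a neutral (uncolored)
    place.  ``compartment`` is a free structural tag ("periphery", "CNS",
    "interface", ...). ``reconstructed`` marks places that are part of the
    documented housekeeping reconstruction rather than the named catalogue.
    """

    name: str
    color_domain: tuple[str, ...] = ()
    compartment: str = ""
    reconstructed: bool = False


# Arc expressions: how the color of moved tokens relates to the binding.
#   None            -> neutral token (place must be uncolored)
#   "l"             -> the binding variable l
#   "l++" / "l--"   -> circular successor / predecessor of l
#   ("const", "L3") -> a fixed color element
ArcExpr = object


@dataclass(frozen=True)
class Arc:
    place: str
    mult: int = 1
    expr: ArcExpr = None

    def __post_init__(self) -> None:
        if self.mult < 1:
            raise ModelError(f"arc on {self.place!r} has multiplicity {self.mult}")


def _as_arc(spec) -> Arc:
    if isinstance(spec, Arc):
        return spec
    if isinstance(spec, str):
        return Arc(spec)
    return Arc(*spec)


@dataclass
class Transition:
    """An event of the net.

    ``kind`` is ``"mass_action"`` or ``"general"``.  For mass-action
    transitions ``rate`` names a nonnegative rate constant in the
    parameter table (or is a literal float).  For general transitions
    ``rate`` is a declarative form::

        {"form": "linear",   "rate": <name>, "agent": <place>}
        {"form": "bilinear", "rate": <name>, "agent": <place>, "substrate": <place>}
        {"form": "hill",     "rate": <name>, "agent": <place>, "substrate": <place>,
         "k_half": <name or float>}

    meaning ``c*agent``, ``c*agent*substrate`` and
    ``c*agent*substrate/(k+substrate)`` respectively, evaluated on the
    transition's input sub-marking.  A python callable
    ``f(submarking, t, params)`` is also accepted for general transitions
    (supported by the reference simulator, not the compiled kernels).

    ``variables`` declares the binding variables of a colored transition
    (name -> color class); ``guard`` restricts the admissible bindings,
    written declaratively as ``{var: {"not_in": [...]}}`` or
    ``{var: {"in": [...]}}``.
    """

    name: str
    kind: str
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    rate: object = 0.0
    variables: dict = field(default_factory=dict)
    guard: dict | None = None
    reconstructed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("mass_action", "general"):
            raise ModelError(f"transition {self.name!r}: unknown kind {self.kind!r}")
        self.inputs = [_as_arc(a) for a in self.inputs]
        self.outputs = [_as_arc(a) for a in self.outputs]


class ESSNModel:
    """A full net: color classes, places, transitions, fixed constants.

    ``constants`` holds default values for rate-constant names so a model
    file is runnable on its own; a :class:`~ms_essn.rrms.ParameterSet`
    passed at compile time overrides them.
    """

    def __init__(
        self,
        name: str = "model",
        color_classes: Iterable[ColorClass] = (),
        places: Iterable[Place] = (),
        transitions: Iterable[Transition] = (),
        constants: Mapping[str, float] | None = None,
    ) -> None:
        self.name = name
        self.color_classes: dict[str, ColorClass] = {c.name: c for c in color_classes}
        self.places: dict[str, Place] = {}
        for p in places:
            self.add_place(p)
        self.transitions: dict[str, Transition] = {}
        for t in transitions:
            self.add_transition(t)
        self.constants: dict[str, float] = dict(constants or {})

    # -- construction -------------------------------------------------
    def add_color_class(self, c: ColorClass) -> None:
        self.color_classes[c.name] = c

    def add_place(self, p: Place) -> None:
        if p.name in self.places:
            raise ModelError(f"duplicate place {p.name!r}")
        for cc in p.color_domain:
            if cc not in self.color_classes:
                raise ModelError(f"place {p.name!r}: undeclared color class {cc!r}")
        self.places[p.name] = p

    def add_transition(self, t: Transition) -> None:
        if t.name in self.transitions:
            raise ModelError(f"duplicate transition {t.name!r}")
        for arc in itertools.chain(t.inputs, t.outputs):
            if arc.place not in self.places:
                raise ModelError(f"transition {t.name!r}: unknown place {arc.place!r}")
        for var, cls in t.variables.items():
            if cls not in self.color_classes:
                raise ModelError(
                    f"transition {t.name!r}: variable {var!r} has undeclared "
                    f"color class {cls!r}"
                )
        self.transitions[t.name] = t

    # -- derived structure --------------------------------------------
    def variables(self) -> list[tuple[str, str | None]]:
        """Dynamic state variables: ``(place, color)`` pairs in declaration
        order, colored places expanded in class-element order.  Places with
        no arcs at all (pure annotation nodes) carry no dynamics and are
        excluded."""
        connected = set()
        for t in self.transitions.values():
            for arc in itertools.chain(t.inputs, t.outputs):
                connected.add(arc.place)
        out: list[tuple[str, str | None]] = []
        for p in self.places.values():
            if p.name not in connected:
                continue
            if not p.color_domain:
                out.append((p.name, None))
            else:
                for combo in itertools.product(
                    *(self.color_classes[cc].elements for cc in p.color_domain)
                ):
                    out.append((p.name, "|".join(combo)))
        return out

    def variable_names(self) -> list[str]:
        return [p if c is None else f"{p}:{c}" for p, c in self.variables()]

    def to_graph(self):
        """Bipartite place/transition graph (networkx DiGraph) for export."""
        import networkx as nx

        g = nx.DiGraph(name=self.name)
        for p in self.places.values():
            g.add_node(p.name, kind="place", compartment=p.compartment)
        for t in self.transitions.values():
            g.add_node(t.name, kind="transition", rate_kind=t.kind)
            for arc in t.inputs:
                g.add_edge(arc.place, t.name, mult=arc.mult)
            for arc in t.outputs:
                g.add_edge(t.name, arc.place, mult=arc.mult)
        return g


class Marking(dict):
    """Token counts over ``(place, color)`` keys, plus a time stamp (days).

    Keys are ``"Place"`` for neutral places and ``"Place:color"`` for
    colored ones.  Counts are nonnegative integers.
    """

    def __init__(self, counts: Mapping[str, int] | None = None, time: float = 0.0):
        super().__init__()
        self.time = float(time)
        for k, v in (counts or {}).items():
            self[k] = v

    def __setitem__(self, key: str, value) -> None:
        iv = int(value)
        if iv != value or iv < 0:
            raise ModelError(f"marking[{key!r}] = {value!r}: counts are nonneg ints")
        super().__setitem__(key, iv)

    def __missing__(self, key: str) -> int:
        return 0

    def copy(self) -> "Marking":
        return Marking(self, time=self.time)

    def as_vector(self, variables: list[tuple[str, str | None]]):
        import numpy as np

        keys = [p if c is None else f"{p}:{c}" for p, c in variables]
        return np.array([self[k] for k in keys], dtype=np.int64)


@dataclass
class EventSchedule:
    """Deterministic timed interventions: ``(time, variable key, delta)``.

    Used for antigen and drug injections; deltas are applied exactly at
    their times by every simulation backend, in schedule order when times
    tie.
    """

    events: list[tuple[float, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e[0] for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ModelError("event times must be sorted ascending")

    def __len__(self) -> int:
        return len(self.events)

    def __add__(self, other: "EventSchedule") -> "EventSchedule":
        merged = sorted(self.events + other.events, key=lambda e: e[0])
        return EventSchedule(merged)

    def arrays(self, variables: list[tuple[str, str | None]]):
        import numpy as np

        keys = {(p if c is None else f"{p}:{c}"): i for i, (p, c) in enumerate(variables)}
        times = np.array([e[0] for e in self.events], dtype=np.float64)
        deltas = np.zeros((len(self.events), len(keys)), dtype=np.int64)
        for row, (_, key, delta) in enumerate(self.events):
            if key not in keys:
                raise ModelError(f"event on unknown variable {key!r}")
            deltas[row, keys[key]] += int(delta)
        return times, deltas


# -- structured-text round trip ---------------------------------------

def _arc_to_obj(arc: Arc):
    expr = arc.expr
    if isinstance(expr, tuple):
        expr = list(expr)
    return {"place": arc.place, "mult": arc.mult, "expr": expr}


def _arc_from_obj(obj) -> Arc:
    expr = obj.get("expr")
    if isinstance(expr, list):
        expr = tuple(expr)
    return Arc(obj["place"], obj.get("mult", 1), expr)


def model_to_dict(model: ESSNModel) -> dict:
    d: dict = {"name": model.name, "color_classes": [], "places": [], "transitions": []}
    for c in model.color_classes.values():
        d["color_classes"].append(
            {"name": c.name, "elements": list(c.elements), "ordered": c.ordered}
        )
    for p in model.places.values():
        obj = {"name": p.name, "compartment": p.compartment}
        if p.color_domain:
            obj["color_domain"] = list(p.color_domain)
        if p.reconstructed:
            obj["reconstructed"] = True
        d["places"].append(obj)
    for t in model.transitions.values():
        if callable(t.rate):
            raise ModelError(
                f"transition {t.name!r}: callable rates cannot be serialized"
            )
        obj = {
            "name": t.name,
            "kind": t.kind,
            "inputs": [_arc_to_obj(a) for a in t.inputs],
            "outputs": [_arc_to_obj(a) for a in t.outputs],
            "rate": t.rate,
        }
        if t.variables:
            obj["variables"] = dict(t.variables)
        if t.guard:
            obj["guard"] = t.guard
        if t.reconstructed:
            obj["reconstructed"] = True
        d["transitions"].append(obj)
    if model.constants:
        d["constants"] = dict(model.constants)
    return d


def model_from_dict(d: dict) -> ESSNModel:
    model = ESSNModel(name=d.get("name", "model"))
    for c in d.get("color_classes", []):
        model.add_color_class(
            ColorClass(c["name"], tuple(c["elements"]), c.get("ordered", True))
        )
    for p in d.get("places", []):
        model.add_place(
            Place(
                p["name"],
                tuple(p.get("color_domain", ())),
                p.get("compartment", ""),
                p.get("reconstructed", False),
            )
        )
    for t in d.get("transitions", []):
        model.add_transition(
            Transition(
                t["name"],
                t["kind"],
                [_arc_from_obj(a) for a in t.get("inputs", [])],
                [_arc_from_obj(a) for a in t.get("outputs", [])],
                t.get("rate", 0.0),
                dict(t.get("variables", {})),
                t.get("guard"),
                t.get("reconstructed", False),
            )
        )
    model.constants = dict(d.get("constants", {}))
    return model


def save_model(model: ESSNModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> ESSNModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
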