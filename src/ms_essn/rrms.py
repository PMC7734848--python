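"""Two-compartment immune network of relapsing-remitting MS.

The net couples a peripheral lymph-node/blood compartment (antigen,
effector and regulatory T cells, NK cells, the cytokines IFNg/IL-17/IL-10,
and the drug daclizumab) to the CNS (re-activated T cells, CNS cytokines,
and oligodendrocytes) through the blood-brain barrier.  BBB tokens count
permeability quanta: IL-17 adds them (barrier damage), IL-10 removes them
(repair), and T cells cross at a rate proportional to both the circulating
cells and the current permeability.

Oligodendrocytes carry a five-level myelination color
``Lmin < L1 < L2 < L3 < Lmax``: every cell starts fully myelinated at
``Lmax``; each effector-T attack moves one cell one level down; cells at
``L1..L3`` can remyelinate one level up; ``Lmin`` is irreversible (no
transition consumes an ``Lmin`` token).

The folded net has 26 places and 55 transitions, 40 mass-action and 15
general (the interaction/saturation processes).  Ten housekeeping
transitions and four annotation places are not individually named in the
published diagram's description; every such addition is flagged
``reconstructed`` in the model structure and in the shipped model file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .essn import (ColorClass, ESSNModel, EventSchedule, Marking, Place,
                   Transition)

__all__ = [
    "MYE_LEVELS", "ParameterSet", "ConfigurationError", "CALIBRATABLE",
    "ACTIVATION", "default_parameters", "build_rrms",
    "default_initial_marking", "antigen_schedule", "dac_schedule",
    "StructuralSummary", "structural_summary", "GENERAL_TRANSITIONS",
    "THERAPY_ANTIGEN_DAYS", "CALIBRATION_ANTIGEN_DAY", "ANTIGEN_COPIES",
]

# myelination levels, ordered from irreversible damage to full myelination
MYE_LEVELS = ("Lmin", "L1", "L2", "L3", "Lmax")

#: the eight antigen-injection days of the two-year relapse scenario
THERAPY_ANTIGEN_DAYS = (2.0, 67.0, 127.0, 295.0, 300.0, 303.0, 307.0, 600.0)
CALIBRATION_ANTIGEN_DAY = 2.0
ANTIGEN_COPIES = 100

#: the 20 rate constants estimated by calibration
CALIBRATABLE = (
    "p_Teff_Activation", "p_Treg_Activation",
    "p_T_dup", "p_T_death",
    "p_Treg_kills_Teff", "p_NK_kills_Teff",
    "p_IFNg_prod", "p_IL17_prod", "p_IL10_prod",
    "p_IFNg_prod_in", "p_IL17_prod_in",
    "p_IFNg_cons", "p_IL17_cons", "p_IL10_cons",
    "p_BBB_damage", "p_BBB_repair", "p_pass",
    "p_Teff_kills_ODC", "p_remyelination", "p_memory_reactivation",
)

#: the two constants in which healthy and MS configurations differ
ACTIVATION = ("p_Teff_Activation", "p_Treg_Activation")

#: auxiliary constants held fixed during calibration (units: per day, or
#: cells/mm^3 for half-saturation constants)
FIXED_DEFAULTS = {
    "k_half_antigen": 20.0,     # antigen half-saturation of T-cell priming
    "k_half_ifng": 5.0,         # CNS IFNg half-saturation of re-activation
    "k_half_kill": 50.0,        # target half-saturation of cell-cell killing
    "p_thymus_influx": 1.26,    # Treg arrival (balances resting death)
    "p_NK_influx": 3.0,         # NK arrival into the blood
    "p_antigen_decay": 0.25,    # spontaneous antigen clearance (transient episode)
    "p_resting_death": 0.02,    # turnover of resting/memory pools
    "p_basal_reactivation": 0.005,  # APC-contact re-activation of CNS Teff
    "p_bbb_decay": 0.5,         # spontaneous resealing of BBB breaches
    "p_Teff_influx": 40.0,      # naive Teff arrival (pool recovers in ~2 months)
    "p_dac_degradation": 0.02,  # first-order drug elimination (t1/2 ~ 5 weeks)
    "p_NK_turnover": 0.1,       # balanced NK duplication/degradation
    "p_NK_prod_IFNg": 0.2,      # innate IFNg baseline (group-independent)
    "p_NK_prod_IL10": 0.2,      # innate IL-10 baseline (group-independent)
    "p_Teff_kills_A": 0.005,    # per-cell antigen clearance
    "dac_kill_teff": 0.01,      # DAC potency on effector T cells
    "dac_kill_treg": 0.01,      # DAC potency on regulatory T cells
}

#: default magnitudes of the calibratable constants (per day).  These are
#: the reference-calibration magnitudes (rounded); they seed the optimizer's
#: first start and center its weak ridge, and give an untreated
#: MS-like course out of the box.
CALIBRATABLE_DEFAULTS = {
    "p_Teff_Activation": 0.1, "p_Treg_Activation": 0.5,
    "p_T_dup": 0.4, "p_T_death": 0.5,
    "p_Treg_kills_Teff": 0.01, "p_NK_kills_Teff": 0.01,
    "p_IFNg_prod": 1.0, "p_IL17_prod": 0.23, "p_IL10_prod": 6.5,
    "p_IFNg_prod_in": 3.6, "p_IL17_prod_in": 0.31,
    "p_IFNg_cons": 0.24, "p_IL17_cons": 0.093, "p_IL10_cons": 6.9,
    "p_BBB_damage": 4.4, "p_BBB_repair": 0.021, "p_pass": 0.088,
    "p_Teff_kills_ODC": 1e-3, "p_remyelination": 0.1,
    "p_memory_reactivation": 0.05,
}

GENERAL_TRANSITIONS = (
    "TeffActivation_out", "TeffActivation_in",
    "TregActivation_out", "TregActivation_in",
    "TregKillsTeff_out", "TregkillsTeff_in", "NKKillsTeff_out",
    "DACkillTeff", "DACkillTreg",
    "Teff_pass_BBB", "Treg_pass_BBB", "IL17_BBB", "IL10_BBB",
    "TeffKillsODC", "Remyelinization",
)


class ConfigurationError(ValueError):
    pass


class ParameterSet(dict):
    """Named nonnegative rate constants for the RRMS net.

    Missing names fall back to the documented defaults; negative values
    are rejected.  ``with_updates`` returns a modified copy.
    """

    def __init__(self, values=None, **kw):
        super().__init__()
        for table in (FIXED_DEFAULTS, CALIBRATABLE_DEFAULTS,
                      dict(values or {}), kw):
            for k, v in table.items():
                self[k] = v

    def __setitem__(self, key, value):
        v = float(value)
        if v < 0:
            raise ConfigurationError(f"parameter {key!r} = {v}: rates are >= 0")
        super().__setitem__(key, v)

    def with_updates(self, updates=None, **kw) -> "ParameterSet":
        out = ParameterSet(self)
        for k, v in {**(updates or {}), **kw}.items():
            out[k] = v
        return out

    def calibratable_vector(self):
        return [self[k] for k in CALIBRATABLE]


def default_parameters(**overrides) -> ParameterSet:
    return ParameterSet(overrides)


def _places() -> list[Place]:
    P = Place
    return [
        # peripheral lymph node / blood vessel
        P("Antigen", compartment="periphery"),
        P("Resting_Teff_out", compartment="periphery"),
        P("Teff_out", compartment="periphery"),
        P("TeffMemory_out", compartment="periphery"),
        P("Resting_Treg_out", compartment="periphery"),
        P("Treg_out", compartment="periphery"),
        P("NK_out", compartment="periphery"),
        P("IFNg_out", compartment="periphery"),
        P("IL17_out", compartment="periphery"),
        P("IL10_out", compartment="periphery"),
        P("DAC", compartment="periphery"),
        P("NLT_out", compartment="periphery", reconstructed=True),
        # annotation nodes of the published diagram (source/sink icons);
        # they carry no tokens and no dynamics
        P("Thymus", compartment="periphery", reconstructed=True),
        P("NK_source", compartment="periphery", reconstructed=True),
        P("DAC_source", compartment="periphery", reconstructed=True),
        P("Antigen_sink", compartment="periphery", reconstructed=True),
        # interface
        P("BBB", compartment="interface"),
        # central nervous system
        P("Resting_Teff_in", compartment="CNS"),
        P("Teff_in", compartment="CNS"),
        P("Resting_Treg_in", compartment="CNS"),
        P("Treg_in", compartment="CNS"),
        P("IFNg_in", compartment="CNS"),
        P("IL17_in", compartment="CNS"),
        P("IL10_in", compartment="CNS"),
        P("ODC", color_domain=("Mye",), compartment="CNS"),
        P("NLT_in", compartment="CNS", reconstructed=True),
    ]


def _transitions() -> list[Transition]:
    T = Transition
    ts: list[Transition] = []

    def ma(name, inputs, outputs, rate, reconstructed=False):
        ts.append(T(name, "mass_action", inputs, outputs, rate,
                    reconstructed=reconstructed))

    def gen(name, inputs, outputs, rate, **kw):
        ts.append(T(name, "general", inputs, outputs, rate, **kw))

    # --- periphery: antigen and effector T cells ---------------------
    ma("AntigenInjection", [], [("Antigen", 1)], 0.0)  # fired by schedule
    gen("TeffActivation_out",
        [("Resting_Teff_out", 1), ("Antigen", 1)],
        [("Teff_out", 1), ("Antigen", 1)],
        {"form": "hill", "rate": "p_Teff_Activation",
         "agent": "Resting_Teff_out", "substrate": "Antigen",
         "k_half": "k_half_antigen"})
    ma("TeffDup_Sym_out", [("Teff_out", 1)], [("Teff_out", 2)], "p_T_dup")
    ma("TeffDup_Asym_out", [("Teff_out", 1)],
       [("Teff_out", 1), ("TeffMemory_out", 1)], "p_T_dup")
    ma("TeffKillsA", [("Teff_out", 1), ("Antigen", 1)], [("Teff_out", 1)],
       "p_Teff_kills_A")
    ma("Teff_prod_IL17", [("Teff_out", 1)],
       [("Teff_out", 1), ("IL17_out", 1)], "p_IL17_prod")
    ma("Teff_prod_IFNg", [("Teff_out", 1)],
       [("Teff_out", 1), ("IFNg_out", 1)], "p_IFNg_prod")
    ma("Teff_to_NLT", [("Teff_out", 1)], [("NLT_out", 1)], "p_T_death")
    ma("IFNgConsumption_out", [("IFNg_out", 1)], [], "p_IFNg_cons")
    ma("IL17Consuption_out", [("IL17_out", 1)], [], "p_IL17_cons")
    # --- periphery: regulatory T cells -------------------------------
    ma("FromTimoReg", [], [("Resting_Treg_out", 1)], "p_thymus_influx")
    gen("TregActivation_out",
        [("Resting_Treg_out", 1), ("Antigen", 1)],
        [("Treg_out", 1), ("Antigen", 1)],
        {"form": "hill", "rate": "p_Treg_Activation",
         "agent": "Resting_Treg_out", "substrate": "Antigen",
         "k_half": "k_half_antigen"})
    gen("TregKillsTeff_out",
        [("Treg_out", 1), ("Teff_out", 1)],
        [("Treg_out", 1), ("NLT_out", 1)],
        {"form": "hill", "rate": "p_Treg_kills_Teff", "agent": "Treg_out",
         "substrate": "Teff_out", "k_half": "k_half_kill"})
    ma("TregDup_out", [("Treg_out", 1)], [("Treg_out", 2)], "p_T_dup")
    ma("TregDeath", [("Treg_out", 1)], [("NLT_out", 1)], "p_T_death")
    ma("Treg_prod_IL10_out", [("Treg_out", 1)],
       [("Treg_out", 1), ("IL10_out", 1)], "p_IL10_prod")
    ma("IL10Consuption_out", [("IL10_out", 1)], [], "p_IL10_cons")
    # --- periphery: natural killer cells -----------------------------
    ma("NKarrive", [], [("NK_out", 1)], "p_NK_influx")
    gen("NKKillsTeff_out",
        [("NK_out", 1), ("Teff_out", 1)],
        [("NK_out", 1), ("NLT_out", 1)],
        {"form": "hill", "rate": "p_NK_kills_Teff", "agent": "NK_out",
         "substrate": "Teff_out", "k_half": "k_half_kill"})
    ma("NK_prod_IFNg", [("NK_out", 1)], [("NK_out", 1), ("IFNg_out", 1)],
       "p_NK_prod_IFNg")
    ma("NK_prod_IL10", [("NK_out", 1)], [("NK_out", 1), ("IL10_out", 1)],
       "p_NK_prod_IL10")
    ma("NKDegradation", [("NK_out", 1)], [("NLT_out", 1)], "p_NK_turnover")
    ma("NKdup", [("NK_out", 1)], [("NK_out", 2)], "p_NK_turnover")
    # --- periphery: daclizumab ---------------------------------------
    ma("DACinjection", [], [("DAC", 1)], 0.0)  # fired by schedule
    ma("DACDegradation", [("DAC", 1)], [], "p_dac_degradation")
    # ten drug tokens are consumed per depleted cell, so the injected
    # dose bounds how many effector cells one cycle can neutralize
    gen("DACkillTeff", [("DAC", 10), ("Teff_out", 1)], [("NLT_out", 1)],
        {"form": "bilinear", "rate": "dac_kill_teff", "agent": "DAC",
         "substrate": "Teff_out"})
    gen("DACkillTreg", [("DAC", 10), ("Treg_out", 1)], [("NLT_out", 1)],
        {"form": "bilinear", "rate": "dac_kill_treg", "agent": "DAC",
         "substrate": "Treg_out"})
    # --- blood-brain barrier -----------------------------------------
    gen("IL17_BBB", [("IL17_out", 1)], [("IL17_out", 1), ("BBB", 1)],
        {"form": "linear", "rate": "p_BBB_damage", "agent": "IL17_out"})
    gen("IL10_BBB", [("IL10_out", 1), ("BBB", 1)], [("IL10_out", 1)],
        {"form": "bilinear", "rate": "p_BBB_repair", "agent": "IL10_out",
         "substrate": "BBB"})
    gen("Teff_pass_BBB", [("Teff_out", 1), ("BBB", 1)],
        [("Resting_Teff_in", 1), ("BBB", 1)],
        {"form": "bilinear", "rate": "p_pass", "agent": "Teff_out",
         "substrate": "BBB"})
    gen("Treg_pass_BBB", [("Treg_out", 1), ("BBB", 1)],
        [("Resting_Treg_in", 1), ("BBB", 1)],
        {"form": "bilinear", "rate": "p_pass", "agent": "Treg_out",
         "substrate": "BBB"})
    # --- CNS: effector T cells and oligodendrocytes ------------------
    gen("TeffActivation_in",
        [("Resting_Teff_in", 1), ("IFNg_in", 1)],
        [("Teff_in", 1), ("IFNg_in", 1)],
        {"form": "hill", "rate": "p_Teff_Activation",
         "agent": "Resting_Teff_in", "substrate": "IFNg_in",
         "k_half": "k_half_ifng"})
    ts.append(T("TeffKillsODC", "general",
                [("Teff_in", 1), ("ODC", 1, "l")],
                [("Teff_in", 1), ("ODC", 1, "l--")],
                {"form": "bilinear", "rate": "p_Teff_kills_ODC",
                 "agent": "Teff_in", "substrate": "ODC",
                 "substrate_expr": "l"},
                variables={"l": "Mye"},
                guard={"l": {"not_in": ["Lmin"]}}))
    ts.append(T("Remyelinization", "general",
                [("ODC", 1, "l")], [("ODC", 1, "l++")],
                {"form": "linear", "rate": "p_remyelination",
                 "agent": "ODC", "agent_expr": "l"},
                variables={"l": "Mye"},
                guard={"l": {"in": ["L1", "L2", "L3"]}}))
    ma("TeffDup_Sym_in", [("Teff_in", 1)], [("Teff_in", 2)], "p_T_dup")
    ma("Teff_prod_IL17_in", [("Teff_in", 1)],
       [("Teff_in", 1), ("IL17_in", 1)], "p_IL17_prod_in")
    ma("Teff_prod_IFNg_in", [("Teff_in", 1)],
       [("Teff_in", 1), ("IFNg_in", 1)], "p_IFNg_prod_in")
    ma("IFNgConsumption_in", [("IFNg_in", 1)], [], "p_IFNg_cons")
    ma("IL17Consuption_in", [("IL17_in", 1)], [], "p_IL17_cons")
    # --- CNS: regulatory T cells -------------------------------------
    gen("TregActivation_in",
        [("Resting_Treg_in", 1), ("IFNg_in", 1)],
        [("Treg_in", 1), ("IFNg_in", 1)],
        {"form": "hill", "rate": "p_Treg_Activation",
         "agent": "Resting_Treg_in", "substrate": "IFNg_in",
         "k_half": "k_half_ifng"})
    gen("TregkillsTeff_in",
        [("Treg_in", 1), ("Teff_in", 1)],
        [("Treg_in", 1), ("NLT_in", 1)],
        {"form": "hill", "rate": "p_Treg_kills_Teff", "agent": "Treg_in",
         "substrate": "Teff_in", "k_half": "k_half_kill"})
    ma("TregDup_in", [("Treg_in", 1)], [("Treg_in", 2)], "p_T_dup")
    ma("Treg_prod_IL10_in", [("Treg_in", 1)],
       [("Treg_in", 1), ("IL10_in", 1)], "p_IL10_prod")
    ma("IL10Consuption_in", [("IL10_in", 1)], [], "p_IL10_cons")
    ma("Treg_to_NLT", [("Treg_in", 1)], [("NLT_in", 1)], "p_T_death")
    # --- reconstructed housekeeping ----------------------------------
    ma("Teff_death_in", [("Teff_in", 1)], [("NLT_in", 1)], "p_T_death",
       reconstructed=True)
    ma("TeffMemory_death", [("TeffMemory_out", 1)], [("NLT_out", 1)],
       "p_resting_death", reconstructed=True)
    ma("MemoryReactivation", [("TeffMemory_out", 1), ("Antigen", 1)],
       [("Teff_out", 1), ("Antigen", 1)], "p_memory_reactivation",
       reconstructed=True)
    ma("AntigenDecay", [("Antigen", 1)], [], "p_antigen_decay",
       reconstructed=True)
    ma("BBB_decay", [("BBB", 1)], [], "p_bbb_decay", reconstructed=True)
    ma("Resting_Teff_death_out", [("Resting_Teff_out", 1)], [("NLT_out", 1)],
       "p_resting_death", reconstructed=True)
    ma("Resting_Treg_death_out", [("Resting_Treg_out", 1)], [("NLT_out", 1)],
       "p_resting_death", reconstructed=True)
    ma("TeffBasalActivation_in", [("Resting_Teff_in", 1)], [("Teff_in", 1)],
       "p_basal_reactivation", reconstructed=True)
    ma("Resting_Treg_death_in", [("Resting_Treg_in", 1)], [("NLT_in", 1)],
       "p_resting_death", reconstructed=True)
    ma("FromTimoTeff", [], [("Resting_Teff_out", 1)], "p_Teff_influx",
       reconstructed=True)
    return ts


def build_rrms(params: ParameterSet | None = None) -> ESSNModel:
    """Assemble the RRMS net; raises if a required constant is missing."""
    params = params if params is not None else default_parameters()
    required = set(CALIBRATABLE) | set(FIXED_DEFAULTS)
    missing = sorted(required - set(params))
    if missing:
        raise ConfigurationError(f"missing parameters: {', '.join(missing)}")
    model = ESSNModel(
        name="rrms",
        color_classes=[ColorClass("Mye", MYE_LEVELS, ordered=True)],
        places=_places(),
        transitions=_transitions(),
        constants=dict(params),
    )
    return model


def default_initial_marking() -> Marking:
    """Reference initial state (cells/mm^3): the healthy-donor blood means
    for the cytokine pools, literature values for the T/NK pools, and 500
    fully myelinated oligodendrocytes."""
    return Marking({
        "Resting_Teff_out": 1689,
        "Resting_Treg_out": 63,
        "NK_out": 30,
        "IL17_out": 8,
        "IL10_out": 13,
        "IFNg_out": 42,
        "IL17_in": 1,
        "IL10_in": 1,
        "IFNg_in": 1,
        "ODC:Lmax": 500,
    })


def antigen_schedule(days=THERAPY_ANTIGEN_DAYS,
                     copies: int = ANTIGEN_COPIES) -> EventSchedule:
    """One +copies event on the Antigen place per listed day."""
    days = list(days)
    if any(b < a for a, b in zip(days, days[1:])):
        raise ConfigurationError("antigen days must be sorted ascending")
    if copies <= 0:
        raise ConfigurationError("antigen copies must be positive")
    return EventSchedule([(float(d), "Antigen", int(copies)) for d in days])


def dac_schedule(start_day: float, dose: int, interval_days: float = 28.0,
                 end_day: float = 730.0) -> EventSchedule:
    """Repeated +dose events on the DAC place from start to end.

    The early regime starts at day 30 (first month), the late regime at
    day 180 (sixth month); administration repeats every four weeks.
    """
    if dose < 0:
        raise ConfigurationError("DAC dose must be >= 0")
    if interval_days <= 0:
        raise ConfigurationError("DAC interval must be positive")
    if start_day > end_day:
        warnings.warn("DAC regime starts after the horizon: empty schedule")
        return EventSchedule([])
    events = []
    t = float(start_day)
    while t <= end_day:
        events.append((t, "DAC", int(dose)))
        t += interval_days
    return EventSchedule(events)


@dataclass
class StructuralSummary:
    places: int
    transitions: int
    mass_action: int
    general: int
    per_compartment: dict

    def as_dict(self) -> dict:
        return {
            "places": self.places,
            "transitions": self.transitions,
            "mass_action": self.mass_action,
            "general": self.general,
            "per_compartment": self.per_compartment,
        }


def structural_summary(model: ESSNModel) -> StructuralSummary:
    """Folded structural counts (colored places count once)."""
    ma = sum(1 for t in model.transitions.values() if t.kind == "mass_action")
    per: dict[str, int] = {}
    for p in model.places.values():
        per[p.compartment] = per.get(p.compartment, 0) + 1
    return StructuralSummary(
        places=len(model.places),
        transitions=len(model.transitions),
        mass_action=ma,
        general=len(model.transitions) - ma,
        per_compartment=per,
    )
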