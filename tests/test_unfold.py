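"""Color unfolding, propensity evaluation and firing semantics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ms_essn.essn import (ColorClass, ESSNModel, EnablingError, Marking,
                          ModelError, Place, Transition, fire, propensity,
                          unfold)


def _mye_model(guard=None, out_expr="l--"):
    return ESSNModel(
        color_classes=[ColorClass("Mye", ("Lmin", "L1", "L2", "L3", "Lmax"))],
        places=[Place("ODC", color_domain=("Mye",)), Place("T")],
        transitions=[Transition(
            "hit", "general",
            [("T", 1), ("ODC", 1, "l")], [("T", 1), ("ODC", 1, out_expr)],
            {"form": "bilinear", "rate": 1.0, "agent": "T",
             "substrate": "ODC", "substrate_expr": "l"},
            variables={"l": "Mye"}, guard=guard)],
    )


class TestUnfold:
    def test_neutral_transition_yields_one_reaction(self):
        model = ESSNModel(
            places=[Place("A"), Place("B")],
            transitions=[Transition("t", "mass_action", [("A", 1)],
                                    [("B", 1)], 1.0)])
        rx = unfold(model)
        assert len(rx) == 1
        assert rx[0].change == {"A": -1, "B": 1}

    def test_guard_filters_bindings(self):
        rx = unfold(_mye_model(guard={"l": {"not_in": ["Lmin"]}}))
        assert len(rx) == 4
        assert all(r.binding["l"] != "Lmin" for r in rx)

    def test_damage_moves_one_level_down(self):
        rx = unfold(_mye_model(guard={"l": {"not_in": ["Lmin"]}}))
        hits = {r.binding["l"]: r for r in rx}
        assert hits["L3"].change == {"ODC:L3": -1, "ODC:L2": 1}
        assert hits["L1"].change == {"ODC:L1": -1, "ODC:Lmin": 1}
        # level moves conserve the total token count
        for r in rx:
            assert sum(r.change.values()) == 0

    def test_every_transition_is_covered(self, rrms_model):
        rx = unfold(rrms_model)
        assert {r.transition for r in rx} == set(rrms_model.transitions)

    def test_rate_reading_non_input_place_rejected(self):
        model = ESSNModel(
            places=[Place("A"), Place("B")],
            transitions=[Transition(
                "t", "general", [("A", 1)], [],
                {"form": "bilinear", "rate": 1.0, "agent": "A",
                 "substrate": "B"})])
        with pytest.raises(ModelError):
            unfold(model)


class TestPropensity:
    def test_mass_action_product_form(self):
        model = ESSNModel(
            places=[Place("A"), Place("B"), Place("C")],
            transitions=[Transition("t", "mass_action",
                                    [("A", 1), ("B", 1)], [("C", 1)], 2.0)])
        (rx,) = unfold(model)
        assert propensity(rx, Marking({"A": 3, "B": 4})) == 24.0
        assert propensity(rx, Marking({"A": 0, "B": 4})) == 0.0

    def test_source_reaction_has_constant_rate(self):
        model = ESSNModel(
            places=[Place("X")],
            transitions=[Transition("src", "mass_action", [], [("X", 1)], 5.0)])
        (rx,) = unfold(model)
        assert propensity(rx, Marking()) == 5.0

    def test_bilinear_drug_kill(self):
        model = ESSNModel(
            places=[Place("DAC"), Place("Teff")],
            transitions=[Transition(
                "kill", "general", [("DAC", 1), ("Teff", 1)], [],
                {"form": "bilinear", "rate": 0.01, "agent": "DAC",
                 "substrate": "Teff"})])
        (rx,) = unfold(model)
        assert propensity(rx, Marking({"DAC": 1000, "Teff": 10})) == 100.0

    def test_general_rate_sees_only_input_places(self):
        model = ESSNModel(
            places=[Place("A"), Place("S"), Place("Elsewhere")],
            transitions=[Transition(
                "t", "general", [("A", 1), ("S", 1)], [("A", 1), ("S", 1)],
                {"form": "hill", "rate": 2.0, "agent": "A", "substrate": "S",
                 "k_half": 10.0})])
        (rx,) = unfold(model)
        base = Marking({"A": 5, "S": 10, "Elsewhere": 0})
        perturbed = Marking({"A": 5, "S": 10, "Elsewhere": 999})
        assert propensity(rx, base) == propensity(rx, perturbed)
        assert propensity(rx, base) == pytest.approx(2.0 * 5 * 10 / 20)

    def test_negative_general_rate_is_contract_violation(self):
        model = ESSNModel(
            places=[Place("A")],
            transitions=[Transition("t", "general", [("A", 1)], [],
                                    lambda sub, t, p: -1.0)])
        (rx,) = unfold(model)
        with pytest.raises(ModelError):
            propensity(rx, Marking({"A": 1}))


class TestFire:
    def test_fire_moves_tokens(self):
        model = ESSNModel(
            places=[Place("A"), Place("B")],
            transitions=[Transition("t", "mass_action", [("A", 1)],
                                    [("B", 1)], 1.0)])
        (rx,) = unfold(model)
        m = Marking({"A": 2})
        m2 = fire(m, rx)
        assert m2["A"] == 1 and m2["B"] == 1
        assert m["A"] == 2 and m["B"] == 0  # input unchanged

    def test_firing_disabled_reaction_raises(self):
        model = ESSNModel(
            places=[Place("A"), Place("B")],
            transitions=[Transition("t", "mass_action", [("A", 1)],
                                    [("B", 1)], 1.0)])
        (rx,) = unfold(model)
        with pytest.raises(EnablingError):
            fire(Marking({"A": 0}), rx)

    def test_odc_damage_conserves_total(self):
        rx = unfold(_mye_model(guard={"l": {"not_in": ["Lmin"]}}))
        hit_l3 = next(r for r in rx if r.binding["l"] == "L3")
        m = Marking({"ODC:Lmax": 499, "ODC:L3": 1, "T": 1})
        m2 = fire(m, hit_l3)
        assert m2["ODC:L3"] == 0 and m2["ODC:L2"] == 1
        total = sum(m2[f"ODC:{l}"] for l in ("Lmin", "L1", "L2", "L3", "Lmax"))
        assert total == 500

    @settings(derandomize=True, max_examples=50)
    @given(a=st.integers(1, 30), b=st.integers(0, 30))
    def test_fire_then_unfire_restores_marking(self, a, b):
        model = ESSNModel(
            places=[Place("A"), Place("B")],
            transitions=[
                Transition("fwd", "mass_action", [("A", 2)], [("B", 3)], 1.0),
                Transition("rev", "mass_action", [("B", 3)], [("A", 2)], 1.0),
            ])
        fwd, rev = unfold(model)
        m = Marking({"A": a + 2, "B": b})
        assert fire(fire(m, fwd), rev) == m
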