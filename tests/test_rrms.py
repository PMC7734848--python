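"""The RRMS net: structure, guards, marking, schedules, model invariants."""

import numpy as np
import pytest

from ms_essn import rrms
from ms_essn.essn import Marking, ssa_simulate, unfold
from ms_essn.essn.simulate import ssa_ensemble


class TestStructure:
    def test_folded_counts(self, rrms_model):
        s = rrms.structural_summary(rrms_model)
        assert (s.places, s.transitions) == (26, 55)
        assert (s.mass_action, s.general) == (40, 15)
        assert s.mass_action + s.general == s.transitions

    def test_general_transition_set(self, rrms_model):
        general = {t.name for t in rrms_model.transitions.values()
                   if t.kind == "general"}
        assert general == set(rrms.GENERAL_TRANSITIONS)
        assert {"TeffActivation_in", "TeffKillsODC"} <= general

    def test_calibratable_set_has_20_constants(self):
        assert len(rrms.CALIBRATABLE) == 20
        assert set(rrms.ACTIVATION) <= set(rrms.CALIBRATABLE)

    def test_missing_parameter_is_named(self):
        params = rrms.default_parameters()
        del params["p_pass"]
        with pytest.raises(rrms.ConfigurationError, match="p_pass"):
            rrms.build_rrms(params)

    def test_odc_guards_protect_the_irreversible_level(self, rrms_model):
        rx = unfold(rrms_model)
        kills = [r for r in rx if r.transition == "TeffKillsODC"]
        remyel = [r for r in rx if r.transition == "Remyelinization"]
        assert {r.binding["l"] for r in kills} == {"L1", "L2", "L3", "Lmax"}
        assert {r.binding["l"] for r in remyel} == {"L1", "L2", "L3"}
        # nothing consumes an Lmin token
        for r in rx:
            assert r.inputs.get("ODC:Lmin", 0) == 0

    def test_only_passage_transitions_span_compartments(self, rrms_model):
        compartment = {p.name: p.compartment for p in rrms_model.places.values()}
        spanning = set()
        for t in rrms_model.transitions.values():
            comps = {compartment[a.place] for a in t.inputs + t.outputs}
            if {"periphery", "CNS"} <= comps:
                spanning.add(t.name)
        assert spanning == {"Teff_pass_BBB", "Treg_pass_BBB"}

    def test_reconstructed_additions_are_flagged(self, rrms_model):
        rec_places = {p.name for p in rrms_model.places.values()
                      if p.reconstructed}
        rec_trans = {t.name for t in rrms_model.transitions.values()
                     if t.reconstructed}
        assert len(rec_trans) == 10
        assert "Thymus" in rec_places and "NLT_out" in rec_places

    def test_packaged_model_file_matches_builder(self, rrms_model):
        from ms_essn.essn.model import model_to_dict
        from ms_essn.io import load_packaged_model

        assert model_to_dict(load_packaged_model()) == model_to_dict(rrms_model)


class TestInitialMarking:
    def test_reference_counts(self, marking0):
        assert marking0["Resting_Teff_out"] == 1689
        assert marking0["Resting_Treg_out"] == 63
        assert marking0["NK_out"] == 30
        assert marking0["IL17_out"] == 8
        assert marking0["IL10_out"] == 13
        assert marking0["IFNg_out"] == 42
        assert marking0["IL17_in"] == marking0["IL10_in"] == marking0["IFNg_in"] == 1
        assert marking0["ODC:Lmax"] == 500

    def test_everything_else_starts_empty(self, marking0, rrms_model):
        nonzero = {k for k, v in marking0.items() if v}
        assert marking0["DAC"] == 0
        assert marking0["Teff_out"] == 0
        assert len(nonzero) == 10

    def test_marking_table_fixture_agrees(self, marking0):
        from ms_essn.io import load_marking_table

        table = load_marking_table()
        assert len(table) == 10
        for _, row in table.iterrows():
            assert marking0[row["place"]] == row["cells_per_mm3"]


class TestSchedules:
    def test_therapy_antigen_days(self):
        sched = rrms.antigen_schedule()
        assert [e[0] for e in sched.events] == [2, 67, 127, 295, 300, 303,
                                                307, 600]
        assert all(e[1] == "Antigen" and e[2] == 100 for e in sched.events)

    def test_calibration_schedule_is_single_injection(self):
        sched = rrms.antigen_schedule(days=[rrms.CALIBRATION_ANTIGEN_DAY])
        assert sched.events == [(2.0, "Antigen", 100)]

    def test_empty_day_list(self):
        assert len(rrms.antigen_schedule(days=[])) == 0

    def test_unsorted_days_rejected(self):
        with pytest.raises(rrms.ConfigurationError):
            rrms.antigen_schedule(days=[5.0, 1.0])

    def test_regime_start_days(self):
        early = rrms.dac_schedule(30.0, 5000, 28.0, 730.0)
        late = rrms.dac_schedule(180.0, 5000, 28.0, 730.0)
        assert early.events[0][0] == 30.0
        assert late.events[0][0] == 180.0
        assert all(b[0] - a[0] == 28.0
                   for a, b in zip(early.events, early.events[1:]))

    def test_start_after_end_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            sched = rrms.dac_schedule(800.0, 5000, 28.0, 730.0)
        assert len(sched) == 0

    def test_zero_dose_events_change_nothing(self, rrms_model, marking0):
        sched = rrms.dac_schedule(30.0, 0, 28.0, 100.0)
        tr = ssa_simulate(rrms_model, marking0, 100.0, events=sched, seed=1,
                          record_grid=[100.0])
        assert tr.get("DAC")[-1] == 0


class TestModelInvariants:
    def test_odc_conservation_all_backends(self, rrms_net, marking0):
        from ms_essn.essn import tau_leap_simulate

        ev = rrms.antigen_schedule(days=[2.0])
        for tr in ssa_ensemble(rrms_net, marking0, 30.0, seeds=range(5),
                               events=ev, record_grid=np.linspace(0, 30, 61)):
            assert (tr.sum_over("ODC") == 500).all()
        tl = tau_leap_simulate(rrms_net, marking0, 30.0, events=ev, seed=0,
                               record_grid=np.linspace(0, 30, 61), tau=0.05)
        assert (tl.sum_over("ODC") == 500).all()

    def test_no_antigen_no_disease(self, rrms_net, marking0):
        """Without antigen exposure there is no effector activation, no CNS
        infiltration and no demyelination."""
        for tr in ssa_ensemble(rrms_net, marking0, 30.0, seeds=range(5),
                               record_grid=np.linspace(0, 30, 31)):
            assert (tr.get("Teff_in") == 0).all()
            assert (tr.get("Teff_out") == 0).all()
            assert (tr.sum_over("ODC") == tr.get("ODC:Lmax")).all()

    def test_lmin_is_absorbing_in_trajectories(self, reference_fit, marking0):
        from ms_essn.essn import compile_net

        params = reference_fit.params_for("MS")
        net = compile_net(rrms.build_rrms(params), params)
        ev = rrms.antigen_schedule(days=[2.0])
        for tr in ssa_ensemble(net, marking0, 30.0, seeds=range(5), events=ev,
                               record_grid=np.linspace(0, 30, 121)):
            assert (np.diff(tr.get("ODC:Lmin")) >= 0).all()
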