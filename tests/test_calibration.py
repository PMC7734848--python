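"""Calibration targets, objective, readout and fit machinery.

The full joint Table-driven fit and the parameter-recovery study are in
the acceptance suite; here the components are exercised directly.
"""

import numpy as np
import pytest

from ms_essn import calibration as cal
from ms_essn import rrms
from ms_essn.io import load_table1


@pytest.fixture(scope="module")
def table1():
    return load_table1()


class TestGroupTargets:
    def test_consistent_printed_cells_are_reproduced(self, table1):
        """Printed group-summary cells that ARE arithmetic column means."""
        hd = cal.group_targets(table1, "HD").values
        ms = cal.group_targets(table1, "MS").values
        assert hd["ifng_csf"] == 0.59
        assert ms["il10_csf"] == 0.09
        assert round(hd["il10_blood"]) == 13

    def test_some_printed_cells_are_not_column_means(self, table1):
        """The printed MS CSF IFNg (12.77) is closer to the column median;
        recomputation must not silently pretend otherwise."""
        ms_mean = cal.group_targets(table1, "MS", "mean").values["ifng_csf"]
        ms_median = cal.group_targets(table1, "MS", "median").values["ifng_csf"]
        assert ms_mean == 13.52
        assert ms_median == pytest.approx(12.77, abs=0.02)

    def test_single_subject_group_is_identity(self, table1):
        solo = table1.iloc[[0]]
        t = cal.group_targets(solo, "MS")
        for a in cal.ANALYTES:
            assert t.values[a] == float(solo.iloc[0][a])

    def test_empty_group_raises(self, table1):
        with pytest.raises(ValueError):
            cal.group_targets(table1[table1["group"] == "MS"], "HD")


class TestLoss:
    def test_zero_iff_model_equals_targets(self, reference_fit):
        sim_hd = cal.simulate_readout(reference_fit.params_for("HD"))
        sim_ms = cal.simulate_readout(reference_fit.params_for("MS"))
        t_hd = cal.CalibrationTargets(sim_hd, "HD")
        t_ms = cal.CalibrationTargets(sim_ms, "MS")
        assert cal.loss(reference_fit, t_hd, t_ms) == pytest.approx(0.0, abs=1e-12)

    def test_doubling_one_large_analyte_adds_about_one(self, reference_fit):
        sim_hd = cal.simulate_readout(reference_fit.params_for("HD"))
        sim_ms = cal.simulate_readout(reference_fit.params_for("MS"))
        t_hd = cal.CalibrationTargets(dict(sim_hd), "HD")
        t_ms = cal.CalibrationTargets(dict(sim_ms), "MS")
        base = cal.loss(reference_fit, t_hd, t_ms)
        # target = t, model = 2t for one analyte with t >> epsilon
        t = sim_ms["ifng_blood"]
        t_ms.values["ifng_blood"] = t / 2.0
        bumped = cal.loss(reference_fit, t_hd, t_ms)
        expected = ((t - t / 2) / (t / 2 + 1.0)) ** 2
        assert bumped - base == pytest.approx(expected, rel=1e-6)
        assert bumped - base == pytest.approx(1.0, abs=0.1)

    def test_loss_is_nonnegative(self, reference_fit):
        t_hd = cal.printed_targets("HD")
        t_ms = cal.printed_targets("MS")
        assert cal.loss(reference_fit, t_hd, t_ms) >= 0.0


class TestReadout:
    def test_all_rates_zero_freezes_cytokines(self):
        zero = rrms.default_parameters()
        for k in rrms.CALIBRATABLE:
            zero[k] = 0.0
        for k in ("p_thymus_influx", "p_NK_influx", "p_antigen_decay",
                  "p_resting_death", "p_basal_reactivation", "p_Teff_influx",
                  "p_NK_turnover", "p_NK_prod_IFNg", "p_NK_prod_IL10",
                  "p_Teff_kills_A", "p_bbb_decay"):
            zero[k] = 0.0
        out = cal.simulate_readout(zero)
        m0 = rrms.default_initial_marking()
        assert out["ifng_blood"] == pytest.approx(m0["IFNg_out"], abs=1e-6)
        assert out["il17_blood"] == pytest.approx(m0["IL17_out"], abs=1e-6)
        assert out["il10_csf"] == pytest.approx(m0["IL10_in"], abs=1e-6)

    def test_zero_production_leaves_pure_decay(self):
        p = rrms.default_parameters(p_IFNg_prod=0.0, p_NK_prod_IFNg=0.0)
        out = cal.simulate_readout(p)
        m0 = rrms.default_initial_marking()
        expected = m0["IFNg_out"] * np.exp(-p["p_IFNg_cons"] * cal.READOUT_DAY)
        assert out["ifng_blood"] == pytest.approx(expected, rel=1e-3)

    def test_readout_agrees_with_reference_integrator(self, reference_fit):
        """The calibration readout equals the LSODA route on the same model."""
        from ms_essn.essn import EventSchedule, derive_vector_field, ode_solve

        params = reference_fit.params_for("MS")
        model = rrms.build_rrms(params)
        field = derive_vector_field(model, params)
        tr = ode_solve(field, rrms.default_initial_marking(),
                       np.array([0.0, cal.READOUT_DAY]),
                       events=EventSchedule([(2.0, "Antigen", 100)]),
                       rtol=1e-8, atol=1e-10)
        fast = cal.simulate_readout(params)
        for a, place in cal.ANALYTE_PLACES.items():
            assert fast[a] == pytest.approx(tr.get(place)[-1],
                                            rel=1e-3, abs=1e-3)


class TestFitMachinery:
    def test_activation_profile_fit_is_deterministic(self, reference_fit):
        truth = reference_fit.params_for("MS")
        targets = cal.CalibrationTargets(cal.simulate_readout(truth), "MS")
        hd_targets = cal.CalibrationTargets(
            cal.simulate_readout(reference_fit.params_for("HD")), "HD")
        kw = dict(targets_hd=hd_targets, targets_ms=targets, n_starts=2,
                  seed=5, shared_fixed=reference_fit.params_for("HD"))
        a = cal.fit(**kw)
        b = cal.fit(**kw)
        assert a.shared == b.shared
        assert a.activation == b.activation
        assert a.loss == b.loss

    def test_result_groups_differ_only_in_activation(self, reference_fit):
        p_hd = reference_fit.params_for("HD")
        p_ms = reference_fit.params_for("MS")
        diff = {k for k in p_hd if p_hd[k] != p_ms[k]}
        assert diff == set(rrms.ACTIVATION)

    def test_fit_requires_table_or_targets(self):
        with pytest.raises(ValueError):
            cal.fit()
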