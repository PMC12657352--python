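"""Flow-division estimation: empirical rules, pressure conversion,
resistance conversion, the iterative loop, Windkessel tuning."""

import math

import numpy as np
import pytest

import aortaflow as af
from aortaflow import (EstimationConfig, MorphParams, NegativeResistanceError,
                      PressureTargets, ValidationError, brachial_to_aortic,
                      build_healthy_template, compare_divisions,
                      empirical_division, estimate_division,
                      mean_systolic_flow, outlet_resistances, tune_windkessel)
from aortaflow.anatomy import LesionKind, LesionSpec, apply_lesion, repair
from aortaflow.estimation import FlowDivision, Windkessel3
from aortaflow.steady import SteadyResult
from aortaflow.waveform import InletWaveform
from conftest import make_y


def template_with_supra_radii(r_bt, r_lcc, r_lsa, include_ima=True):
    p = MorphParams(include_ima=include_ima)
    p.branches = dict(p.branches)
    p.branches["BT"] = (r_bt, p.branches["BT"][1])
    p.branches["LCC"] = (r_lcc, p.branches["LCC"][1])
    p.branches["LSA"] = (r_lsa, p.branches["LSA"][1])
    return build_healthy_template(p)


class TestEmpiricalDivision:
    def test_iliac_fractions_all_twelve_branches(self):
        """Equal supra-aortic areas, IMA present: per-side iliac total
        is 11.25 %, split 70/30 external/internal."""
        net = template_with_supra_radii(0.5, 0.5, 0.5)
        div = empirical_division(net)
        for side in "LR":
            assert div[f"{side}EIA"] == pytest.approx(0.07875, abs=1e-12)
            assert div[f"{side}IIA"] == pytest.approx(0.03375, abs=1e-12)
        # printed to one decimal percent: 7.9 % external, 3.4 % internal
        assert round(100 * div["LEIA"], 1) == 7.9
        assert round(100 * div["LIIA"], 1) == 3.4
        for b in ("BT", "LCC", "LSA"):
            assert div[b] == pytest.approx(0.10, abs=1e-12)
        assert sum(div.fraction.values()) == pytest.approx(1.0, abs=1e-9)

    def test_ima_absent_enlarges_iliac_pool(self):
        net = template_with_supra_radii(0.5, 0.5, 0.5, include_ima=False)
        div = empirical_division(net)
        assert "IMA" not in div.fraction
        for side in "LR":
            assert div[f"{side}EIA"] == pytest.approx(0.0805, abs=1e-12)
            assert div[f"{side}IIA"] == pytest.approx(0.0345, abs=1e-12)

    def test_supra_aortic_split_proportional_to_area(self):
        # areas 2:1:1  (radius ratio √2:1:1)
        net = template_with_supra_radii(0.4 * math.sqrt(2), 0.4, 0.4)
        div = empirical_division(net)
        assert div["BT"] == pytest.approx(0.15, abs=1e-12)
        assert div["LCC"] == pytest.approx(0.075, abs=1e-12)
        assert div["LSA"] == pytest.approx(0.075, abs=1e-12)

    def test_fixed_visceral_fractions(self, healthy):
        div = empirical_division(healthy)
        assert div["CT"] == pytest.approx(0.155)
        for b in ("SMA", "LRA", "RRA"):
            assert div[b] == pytest.approx(0.105)
        assert div["IMA"] == pytest.approx(0.005)

    def test_missing_mandatory_branch_rejected(self, healthy):
        partial = healthy.copy()
        del partial.outlets["LCC"]
        with pytest.raises(ValidationError, match="LCC"):
            empirical_division(partial)


class TestPressureConversion:
    @pytest.mark.parametrize("sys_bra,dia_bra,mean_ao", [
        (146, 87, 105.892),
        (120, 87, 97.26),
        (140, 83, 101.26),
    ])
    def test_cuff_to_aortic_values(self, sys_bra, dia_bra, mean_ao):
        t = brachial_to_aortic(sys_bra, dia_bra)
        assert t.P_sys_ao == pytest.approx(
            0.83 * sys_bra + 0.15 * dia_bra, abs=1e-9)
        assert t.P_dia_ao == dia_bra
        assert t.P_mean_ao == pytest.approx(mean_ao, abs=1e-9)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValidationError):
            brachial_to_aortic(100, 100)
        with pytest.raises(ValidationError):
            brachial_to_aortic(120, -5)


class TestMeanSystolicFlow:
    def test_half_sine_closed_form(self):
        """Half-sine systole over [0, T/3]: mean systolic flow 2 Q_p/π,
        cross-checked against dense numerical quadrature."""
        qp, ts = 400.0, 1.0 / 3.0
        t = np.linspace(0, 1, 6001)
        q = np.where(t <= ts, qp * np.sin(np.pi * t / np.minimum(ts, 1)), 0.0)
        q[t > ts] = 0.0
        wf = InletWaveform(t, q)
        dense = np.linspace(0, ts, 200001)
        oracle = np.trapezoid(qp * np.sin(np.pi * dense / ts), dense) / ts
        got = mean_systolic_flow(wf)
        assert oracle == pytest.approx(2 * qp / np.pi, rel=1e-8)
        assert got == pytest.approx(oracle, rel=1e-3)

    def test_constant_waveform_returns_constant(self):
        wf = InletWaveform(np.linspace(0, 1, 11), np.full(11, 42.0))
        assert mean_systolic_flow(wf) == pytest.approx(42.0)

    def test_all_zero_waveform_rejected(self):
        wf = InletWaveform(np.linspace(0, 1, 11), np.zeros(11))
        with pytest.raises(ValidationError):
            mean_systolic_flow(wf)

    def test_explicit_override(self):
        wf = InletWaveform(np.linspace(0, 1, 101),
                           np.sin(np.pi * np.linspace(0, 1, 101)))
        assert mean_systolic_flow(wf, t_end=1.0) == pytest.approx(
            2 / np.pi, rel=1e-3)


class TestOutletResistances:
    @staticmethod
    def result(p_in, p_out, q):
        return SteadyResult(node_pressure={}, segment_flow={}, P_in=p_in,
                            P_out={"CT": p_out}, Q={"CT": q})

    def test_arithmetic(self):
        assert outlet_resistances(self.result(102, 100, 10), 100.0) == \
            pytest.approx({"CT": 9.8})
        assert outlet_resistances(self.result(100, 100, 20), 100.0) == \
            pytest.approx({"CT": 5.0})

    def test_mean_pressure_below_drop_rejected(self):
        with pytest.raises(NegativeResistanceError):
            outlet_resistances(self.result(102, 100, 10), 1.0)


class TestEstimateDivision:
    def test_identity_recovery(self, healthy, targets_p1, waveform_p1):
        """Lesion-free pair: the loop must converge on the first check
        and reproduce the empirical division exactly (algebraic
        self-consistency of the resistance conversion)."""
        division, trace, resistances = estimate_division(
            healthy, healthy, targets_p1, waveform_p1)
        emp = empirical_division(healthy)
        assert trace.converged and trace.n_iter == 1
        for b in emp.fraction:
            assert division[b] == pytest.approx(emp[b], abs=1e-8)
        assert trace.records[-1]["P_pred"] == pytest.approx(
            targets_p1.P_mean_ao, abs=1e-6)
        assert all(r > 0 for r in resistances.values())

    def test_stenosis_steal_direction(self, healthy, targets_p1,
                                      waveform_p1):
        dis = apply_lesion(healthy, LesionSpec(
            LesionKind.OSTIAL_STENOSIS, target="CT", area_ratio=0.2))
        division, trace, _ = estimate_division(
            repair(dis), dis, targets_p1, waveform_p1)
        assert trace.converged
        assert division["CT"] < 0.155

    def test_steal_monotone_in_severity(self, healthy, targets_p1,
                                        waveform_p1):
        fractions = []
        for ar in (1.0, 0.5, 0.25, 0.1):
            dis = apply_lesion(healthy, LesionSpec(
                LesionKind.OSTIAL_STENOSIS, target="CT", area_ratio=ar))
            division, _, _ = estimate_division(
                repair(dis), dis, targets_p1, waveform_p1)
            assert sum(division.fraction.values()) == pytest.approx(
                1.0, abs=1e-9)
            fractions.append(division["CT"])
        assert all(b < a for a, b in zip(fractions, fractions[1:]))

    def test_self_consistency_of_final_resistances(self, healthy, targets_p1,
                                                   waveform_p1):
        """Re-solving with the returned resistances reproduces an inlet
        pressure within the loop's own 1 % stopping rule."""
        from aortaflow.steady import BCMode, OutletBC, solve_steady
        dis = apply_lesion(healthy, LesionSpec(
            LesionKind.OSTIAL_STENOSIS, target="CT", area_ratio=0.25))
        _, _, resistances = estimate_division(
            repair(dis), dis, targets_p1, waveform_p1)
        bcs = {b: OutletBC(BCMode.RESISTANCE, r)
               for b, r in resistances.items()}
        res = solve_steady(dis, mean_systolic_flow(waveform_p1), bcs)
        assert abs(res.P_in - targets_p1.P_mean_ao) / targets_p1.P_mean_ao \
            < 0.01

    def test_predicted_pressure_monotone_in_p_mean(self, healthy,
                                                   waveform_p1):
        """P_pred increases with the P_mean used in the resistance
        conversion — the property that makes the additive update safe."""
        from aortaflow.steady import BCMode, OutletBC, solve_steady
        dis = apply_lesion(healthy, LesionSpec(
            LesionKind.OSTIAL_STENOSIS, target="CT", area_ratio=0.3))
        q_in = mean_systolic_flow(waveform_p1)
        emp = empirical_division(healthy)
        from aortaflow.steady import BCMode as M
        ref_res = solve_steady(
            healthy, q_in,
            {b: OutletBC(M.PRESCRIBED_FRACTION, emp[b])
             for b in healthy.outlets})
        preds = []
        for p_mean in (80.0, 95.0, 110.0, 125.0):
            rs = outlet_resistances(ref_res, p_mean)
            bcs = {b: OutletBC(M.RESISTANCE, r) for b, r in rs.items()}
            preds.append(solve_steady(dis, q_in, bcs).P_in)
        assert all(b > a for a, b in zip(preds, preds[1:]))

    def test_unreachable_target_pressure_rejected(self, healthy,
                                                  waveform_p1):
        targets = PressureTargets(P_sys_bra=1.0, P_dia_bra=0.5,
                                  P_sys_ao=1.0, P_dia_ao=0.5,
                                  P_mean_ao=1e-4)
        with pytest.raises(NegativeResistanceError):
            estimate_division(healthy, healthy, targets, waveform_p1)

    def test_mismatched_branch_sets_rejected(self, healthy, targets_p1,
                                             waveform_p1):
        partial = healthy.copy()
        del partial.outlets["IMA"]
        with pytest.raises(ValidationError):
            estimate_division(healthy, partial, targets_p1, waveform_p1)


class TestWindkesselTuning:
    def test_zero_characteristic_share(self, healthy, targets_p1,
                                       waveform_p1):
        emp = empirical_division(healthy)
        wk = tune_windkessel(healthy, emp, targets_p1, waveform_p1,
                             config=EstimationConfig(f_c=0.0))
        for w in wk.values():
            assert w.R_c == 0.0 and w.R_p > 0

    def test_compliance_proportional_to_tau(self, healthy, targets_p1,
                                            waveform_p1):
        emp = empirical_division(healthy)
        wk1 = tune_windkessel(healthy, emp, targets_p1, waveform_p1,
                              config=EstimationConfig(tau=1.79))
        wk2 = tune_windkessel(healthy, emp, targets_p1, waveform_p1,
                              config=EstimationConfig(tau=3.58))
        for b in wk1:
            assert wk2[b].C == pytest.approx(2 * wk1[b].C, rel=1e-12)
            assert wk2[b].R_p == pytest.approx(wk1[b].R_p, rel=1e-12)

    def test_symmetric_outlets_get_identical_parameters(self, targets_p1,
                                                        waveform_p1):
        net = make_y()
        division = FlowDivision({"LEIA": 0.5, "REIA": 0.5})
        wk = tune_windkessel(net, division, targets_p1, waveform_p1)
        for attr in ("R_c", "R_p", "C"):
            assert getattr(wk["LEIA"], attr) == pytest.approx(
                getattr(wk["REIA"], attr), rel=1e-12)


class TestCompareDivisions:
    def test_identical_divisions(self, healthy):
        div = empirical_division(healthy)
        r, mean_diff, loa = compare_divisions(div, div)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert mean_diff == 0.0
        assert loa == (0.0, 0.0)

    def test_constant_offset(self, healthy):
        div = empirical_division(healthy)
        shifted = {b: f + 0.01 for b, f in div.fraction.items()}
        r, mean_diff, loa = compare_divisions(div.fraction, shifted)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert mean_diff == pytest.approx(0.01, abs=1e-12)
        assert loa[1] - loa[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(5)
        names = list(af.BRANCH_NAMES)
        a = dict(zip(names, rng.uniform(0.01, 0.2, 12)))
        b = dict(zip(names, rng.uniform(0.01, 0.2, 12)))
        r, mean_diff, loa = compare_divisions(a, b)
        va = np.array([a[k] for k in sorted(a)])
        vb = np.array([b[k] for k in sorted(b)])
        n = va.size
        sxy = np.sum((va - va.mean()) * (vb - vb.mean()))
        r_oracle = sxy / math.sqrt(np.sum((va - va.mean())**2)
                                   * np.sum((vb - vb.mean())**2))
        assert r == pytest.approx(r_oracle, abs=1e-12)
        d = vb - va
        assert mean_diff == pytest.approx(d.mean(), abs=1e-15)
        sd = math.sqrt(np.sum((d - d.mean())**2) / n)
        assert loa[0] == pytest.approx(d.mean() - 1.96 * sd, abs=1e-12)

    def test_mismatched_branch_sets_rejected(self):
        with pytest.raises(ValidationError):
            compare_divisions({"BT": 0.5, "LCC": 0.3, "LSA": 0.2},
                              {"BT": 0.5, "LCC": 0.3, "CT": 0.2})
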