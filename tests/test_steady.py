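"""Steady solver: constitutive law, Newton solution, BC modes."""

import math

import numpy as np
import pytest
from scipy.optimize import fsolve

import aortaflow as af
from aortaflow.network import AorticNetwork, StenosisSpec, VesselSegment
from aortaflow.steady import (BCMode, OutletBC, segment_coefficients,
                              segment_dP, solve_steady, solve_zero_pressure)
from conftest import make_y


class TestSegmentLaw:
    def test_poiseuille_hand_value(self):
        # independent unit-conversion oracle, evaluated inline in SI
        seg = VesselSegment("s", "a", "b", length=10.0, radius=0.5)
        r_si = 8 * 0.0035 * 0.10 / (math.pi * 0.005**4)     # Pa·s·m⁻³
        expected = r_si * 1e-6 / 133.322                    # mmHg·s·mL⁻¹
        assert segment_dP(seg, 1.0) == pytest.approx(expected, rel=1e-12)
        assert segment_dP(seg, 1.0) == pytest.approx(0.010696, rel=1e-4)

    def test_zero_flow_zero_drop(self):
        seg = VesselSegment("s", "a", "b", 10.0, 0.5,
                            stenosis=StenosisSpec(0.3))
        assert segment_dP(seg, 0.0) == 0.0

    def test_open_stenosis_reduces_to_poiseuille(self):
        plain = VesselSegment("s", "a", "b", 10.0, 0.5)
        open_sten = VesselSegment("s", "a", "b", 10.0, 0.5,
                                  stenosis=StenosisSpec(1.0))
        assert segment_dP(open_sten, 5.0) == segment_dP(plain, 5.0)

    def test_quadratic_term_value(self):
        # K = Kt·ρ/(2 A_s²)·(A0/As − 1)², converted — oracle inline
        seg = VesselSegment("s", "a", "b", 10.0, 0.5,
                            stenosis=StenosisSpec(0.25, kt=1.52))
        a0 = math.pi * 0.005**2
        a_s = 0.25 * a0
        k_si = 1.52 * (1060.0 / (2 * a_s**2)) * (1 / 0.25 - 1) ** 2
        k = k_si * 1e-12 / 133.322
        r, kk = segment_coefficients(seg)
        assert kk == pytest.approx(k, rel=1e-12)
        q = 3.0
        assert segment_dP(seg, q) == pytest.approx(r * q + k * q * q)

    def test_drop_sign_follows_flow(self):
        seg = VesselSegment("s", "a", "b", 10.0, 0.5,
                            stenosis=StenosisSpec(0.3))
        assert segment_dP(seg, -2.0) == -segment_dP(seg, 2.0)


class TestSolveSteady:
    def test_symmetric_y_splits_evenly(self, symmetric_y):
        bcs = {b: OutletBC(BCMode.RESISTANCE, 2.0)
               for b in symmetric_y.outlets}
        res = solve_steady(symmetric_y, 10.0, bcs)
        assert res.Q["LEIA"] == pytest.approx(5.0, abs=1e-10)
        assert res.Q["REIA"] == pytest.approx(5.0, abs=1e-10)

    def test_series_law_single_vessel(self, single_vessel):
        R = 3.0
        res = solve_steady(single_vessel, 7.0,
                           {"BT": OutletBC(BCMode.RESISTANCE, R)})
        r_pois, _ = segment_coefficients(single_vessel.segments[0])
        assert res.P_in == pytest.approx((R + r_pois) * 7.0, rel=1e-12)
        assert res.P_out["BT"] == pytest.approx(R * 7.0, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        """Newton nodal solve vs an independent joint (P, Q) root-find
        of the full nonlinear residual system on a 6-outlet tree."""
        rng = np.random.default_rng(42)
        net = _random_tree(rng)
        bcs = {b: OutletBC(BCMode.RESISTANCE, float(rng.uniform(0.5, 3.0)))
               for b in net.outlets}
        q_in = 50.0
        res = solve_steady(net, q_in, bcs)

        segs = net.segments
        coeff = [segment_coefficients(s) for s in segs]
        nodes = sorted(net.nodes)
        nidx = {n: i for i, n in enumerate(nodes)}
        o_by_node = {net.outlets[b]: bcs[b].value for b in net.outlets}

        def residual(x):
            p, q = x[:len(nodes)], x[len(nodes):]
            out = []
            for (s, (R, K)), qi in zip(zip(segs, coeff), q):
                dp = p[nidx[s.from_node]] - p[nidx[s.to_node]]
                out.append(dp - (R * qi + K * qi * abs(qi)))
            for n in nodes:
                bal = sum(qi for s, qi in zip(segs, q) if s.to_node == n) \
                    - sum(qi for s, qi in zip(segs, q) if s.from_node == n)
                if n == net.inlet_node:
                    bal += q_in
                if n in o_by_node:
                    bal -= p[nidx[n]] / o_by_node[n]
                out.append(bal)
            out.pop(len(segs) + nidx[net.inlet_node])  # redundant balance
            out.append(sum(q[i] for i, s in enumerate(segs)
                           if s.from_node == net.inlet_node) - q_in)
            return out

        x0 = np.concatenate([np.full(len(nodes), 50.0),
                             np.full(len(segs), q_in / len(segs))])
        sol = fsolve(residual, x0, xtol=1e-13)
        p_oracle = {n: sol[nidx[n]] for n in nodes}
        q_oracle = {s.id: sol[len(nodes) + i] for i, s in enumerate(segs)}
        for sid, qv in res.segment_flow.items():
            assert qv == pytest.approx(q_oracle[sid], abs=1e-8)
        for n, pv in res.node_pressure.items():
            assert pv == pytest.approx(p_oracle[n], abs=1e-8)

    @pytest.mark.parametrize("mode", ["fraction", "resistance", "zero"])
    def test_conservation(self, healthy, mode):
        if mode == "fraction":
            div = af.empirical_division(healthy)
            bcs = {b: OutletBC(BCMode.PRESCRIBED_FRACTION, div[b])
                   for b in healthy.outlets}
        elif mode == "resistance":
            bcs = {b: OutletBC(BCMode.RESISTANCE, 1.0 + i * 0.1)
                   for i, b in enumerate(sorted(healthy.outlets))}
        else:
            bcs = {b: OutletBC(BCMode.ZERO_PRESSURE)
                   for b in healthy.outlets}
        res = solve_steady(healthy, 250.0, bcs)
        assert abs(sum(res.Q.values()) - 250.0) / 250.0 <= 1e-10

    def test_datum_invariance_of_dp(self, healthy):
        div = af.empirical_division(healthy)
        bcs = {b: OutletBC(BCMode.PRESCRIBED_FRACTION, div[b])
               for b in healthy.outlets}
        a = solve_steady(healthy, 250.0, bcs, reference_pressure=0.0)
        b = solve_steady(healthy, 250.0, bcs, reference_pressure=50.0)
        assert b.P_in == pytest.approx(50.0, abs=1e-9)
        for br in a.dP:
            assert a.dP[br] == pytest.approx(b.dP[br], abs=1e-9)

    def test_tighter_stenosis_never_gains_flow(self, healthy):
        from aortaflow import LesionKind, LesionSpec, apply_lesion
        bcs = {b: OutletBC(BCMode.RESISTANCE, 1.2) for b in healthy.outlets}
        flows = []
        for ar in (1.0, 0.6, 0.3, 0.15):
            dis = apply_lesion(healthy, LesionSpec(
                LesionKind.OSTIAL_STENOSIS, target="CT", area_ratio=ar))
            flows.append(solve_steady(dis, 250.0, bcs).Q["CT"])
        assert all(b <= a + 1e-12 for a, b in zip(flows, flows[1:]))

    def test_invalid_inputs_rejected(self, symmetric_y):
        bcs = {b: OutletBC(BCMode.RESISTANCE, 1.0)
               for b in symmetric_y.outlets}
        with pytest.raises(af.ValidationError):
            solve_steady(symmetric_y, -1.0, bcs)
        with pytest.raises(af.ValidationError):  # missing BC
            solve_steady(symmetric_y, 1.0, {"LEIA": bcs["LEIA"]})
        with pytest.raises(af.ValidationError):  # fractions must sum to 1
            solve_steady(symmetric_y, 1.0,
                         {"LEIA": OutletBC(BCMode.PRESCRIBED_FRACTION, 0.5),
                          "REIA": OutletBC(BCMode.PRESCRIBED_FRACTION, 0.4)})
        with pytest.raises(af.ValidationError):  # no mode mixing
            solve_steady(symmetric_y, 1.0,
                         {"LEIA": OutletBC(BCMode.PRESCRIBED_FRACTION, 1.0),
                          "REIA": OutletBC(BCMode.RESISTANCE, 1.0)})


class TestZeroPressure:
    def test_symmetric_split(self, symmetric_y):
        _, division = solve_zero_pressure(symmetric_y, 10.0)
        assert division["LEIA"] == pytest.approx(0.5, abs=1e-10)

    def test_narrower_branch_gets_less(self):
        net = make_y(r_left=0.25, r_right=0.5)
        _, division = solve_zero_pressure(net, 10.0)
        assert division["LEIA"] < division["REIA"]
        assert division["LEIA"] < 0.5

    def test_twelve_outlet_fractions_sum_to_one(self, healthy):
        _, division = solve_zero_pressure(healthy, 250.0)
        assert sum(division.values()) == pytest.approx(1.0, abs=1e-10)


def _random_tree(rng) -> AorticNetwork:
    """Small random 6-outlet tree with one stenosed branch (8 segments)."""
    segs = [VesselSegment("S0", "n0", "n1", float(rng.uniform(3, 10)),
                          float(rng.uniform(0.6, 1.0))),
            VesselSegment("S1", "n1", "n2", float(rng.uniform(3, 10)),
                          float(rng.uniform(0.5, 0.9)))]
    outlets = {}
    names = ["BT", "LCC", "LSA", "CT", "SMA", "LRA"]
    attach = ["n1", "n1", "n2", "n2", "n2", "n2"]
    for i, (b, at) in enumerate(zip(names, attach)):
        sten = StenosisSpec(0.35) if i == 3 else None
        segs.append(VesselSegment(f"B{i}", at, f"o{i}",
                                  float(rng.uniform(2, 6)),
                                  float(rng.uniform(0.25, 0.5)),
                                  stenosis=sten))
        outlets[b] = f"o{i}"
    nodes = {s.from_node for s in segs} | {s.to_node for s in segs}
    return AorticNetwork(nodes=nodes, segments=segs, inlet_node="n0",
                         outlets=outlets)
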