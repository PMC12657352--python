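"""Steady nonlinear 0D network solver.

Each vessel segment obeys a series pressure-loss law

    ΔP = R_pois · Q + K_loss · Q·|Q|

with the Poiseuille resistance R_pois = 8 μ L / (π r⁴) and, for
stenosed segments, a quadratic expansion-loss coefficient

    K_loss = Kt · (ρ / (2 A_s²)) · (A₀/A_s − 1)²,   A_s = area_ratio · A₀

(the classic empirical form for blunt stenoses).  Coefficients are
computed in SI and converted once to mmHg·s·mL⁻¹ so the nodal Newton
iteration operates on O(1) quantities.

The nodal unknowns are pressures; segment flows follow from inverting
the (monotone) segment law.  Outlet boundary conditions come in four
modes — prescribed flow fraction, linear resistance to a venous
reference, zero pressure, and three-element Windkessel (the transient
module couples the latter; the steady solver treats a WK3 outlet as the
equivalent series resistance R_c + R_p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Union

import numpy as np

from . import units
from .network import AorticNetwork, TopologyError, ValidationError, VesselSegment

__all__ = [
    "BloodProperties",
    "BCMode",
    "OutletBC",
    "SteadyResult",
    "SolverError",
    "segment_dP",
    "segment_coefficients",
    "solve_steady",
    "solve_zero_pressure",
]


@dataclass(frozen=True)
class BloodProperties:
    """Newtonian blood: density kg·m⁻³, dynamic viscosity Pa·s."""

    density: float = 1060.0
    viscosity: float = 0.0035

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValidationError("blood density and viscosity must be > 0")


class BCMode(str, Enum):
    PRESCRIBED_FRACTION = "PRESCRIBED_FRACTION"
    RESISTANCE = "RESISTANCE"
    ZERO_PRESSURE = "ZERO_PRESSURE"
    WK3 = "WK3"


@dataclass(frozen=True)
class OutletBC:
    mode: BCMode
    value: Union[float, "object", None] = None  # fraction | R | None | Windkessel3

    def __post_init__(self):
        if self.mode is BCMode.RESISTANCE and (
                self.value is None or self.value < 0):
            raise ValidationError("resistance BC requires value >= 0")
        if self.mode is BCMode.PRESCRIBED_FRACTION and (
                self.value is None or self.value < 0):
            raise ValidationError("fraction BC requires value >= 0")


class SolverError(RuntimeError):
    """Newton iteration failed to converge; carries the residual trace."""

    def __init__(self, msg: str, residuals=None):
        super().__init__(msg)
        self.residuals = list(residuals or [])


@dataclass
class SteadyResult:
    """Nodal pressures and segment flows from one steady solve.

    Pressures in mmHg, flows in mL·s⁻¹.  ``dP[b] = P_in − P_out[b]`` is
    the internal (geometric) pressure drop from the inlet to outlet
    ``b`` and is independent of the pressure datum.
    """

    node_pressure: dict[str, float]
    segment_flow: dict[str, float]
    P_in: float
    P_out: dict[str, float]
    Q: dict[str, float]
    dP: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.dP:
            self.dP = {b: self.P_in - p for b, p in self.P_out.items()}

    def division(self) -> dict[str, float]:
        total = sum(self.Q.values())
        return {b: q / total for b, q in self.Q.items()}


# ---------------------------------------------------------------------------
# segment constitutive law


def segment_coefficients(segment: VesselSegment,
                         blood: BloodProperties = BloodProperties(),
                         ) -> tuple[float, float]:
    """(R_pois, K_loss) in mmHg·s·mL⁻¹ and mmHg·s²·mL⁻²."""
    L = segment.length * units.M_PER_CM
    r = segment.radius * units.M_PER_CM
    r_si = 8.0 * blood.viscosity * L / (math.pi * r**4)
    k_si = 0.0
    if segment.stenosis is not None and segment.stenosis.area_ratio < 1.0:
        a0 = math.pi * r**2
        a_s = segment.stenosis.area_ratio * a0
        k_si = segment.stenosis.kt * (blood.density / (2.0 * a_s**2)) \
            * (a0 / a_s - 1.0)**2
    return (units.resistance_si_to_mmhg_ml(r_si),
            units.quad_coeff_si_to_mmhg_ml(k_si))


def segment_dP(segment: VesselSegment, Q: float,
               blood: BloodProperties = BloodProperties()) -> float:
    """Pressure drop (mmHg) across a segment carrying Q (mL·s⁻¹)."""
    R, K = segment_coefficients(segment, blood)
    return R * Q + K * Q * abs(Q)


def _flow_from_dp(dp: float, R: float, K: float) -> tuple[float, float]:
    """Invert ΔP = R·Q + K·Q|Q|; returns (Q, dQ/dΔP)."""
    if K == 0.0:
        return dp / R, 1.0 / R
    disc = math.sqrt(R * R + 4.0 * K * abs(dp))
    q = math.copysign((disc - R) / (2.0 * K), dp)
    return q, 1.0 / disc


# ---------------------------------------------------------------------------
# assembly and Newton iteration


def _bc_map(network: AorticNetwork, outlet_bcs) -> dict[str, OutletBC]:
    bcs: dict[str, OutletBC] = {}
    for b in network.outlets:
        if b not in outlet_bcs:
            raise ValidationError(f"missing outlet BC for branch {b}")
        bc = outlet_bcs[b]
        if bc.mode is BCMode.WK3:
            wk = bc.value
            bc = OutletBC(BCMode.RESISTANCE, wk.R_c + wk.R_p)
        bcs[b] = bc
    modes = {bc.mode for bc in bcs.values()}
    if BCMode.PRESCRIBED_FRACTION in modes:
        if modes != {BCMode.PRESCRIBED_FRACTION}:
            raise ValidationError(
                "prescribed-fraction BCs cannot be mixed with other modes")
        total = sum(bc.value for bc in bcs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"prescribed fractions must sum to 1, got {total!r}")
    return bcs


def solve_steady(network: AorticNetwork,
                 inlet_flow: float,
                 outlet_bcs: Mapping[str, OutletBC],
                 blood: BloodProperties = BloodProperties(),
                 venous_pressure: float = 0.0,
                 reference_pressure: float = 0.0,
                 tol: float = 1e-12,
                 max_iter: int = 100,
                 ) -> SteadyResult:
    """Solve the steady nonlinear nodal system.

    Parameters
    ----------
    inlet_flow : float
        Inlet flow rate, mL·s⁻¹ (> 0).
    outlet_bcs : mapping branch name -> OutletBC
        Homogeneous PRESCRIBED_FRACTION, or any mix of RESISTANCE /
        ZERO_PRESSURE / WK3 (treated as R_c + R_p).
    venous_pressure : float
        Distal reference pressure behind resistance outlets, mmHg.
    reference_pressure : float
        Pressure datum reported at the inlet in prescribed-fraction
        mode (flows and dP values are datum-independent).

    Newton iteration on the nodal pressures, damping 0.7 on the first 5
    iterations, initial guess from the linearised (Poiseuille-only)
    system; converged when max |node imbalance| / inlet_flow <= tol.
    """
    if inlet_flow <= 0:
        raise ValidationError(f"inlet_flow must be > 0, got {inlet_flow}")
    network.validate()
    bcs = _bc_map(network, outlet_bcs)
    fraction_mode = any(bc.mode is BCMode.PRESCRIBED_FRACTION
                        for bc in bcs.values())

    outlet_node = {network.outlets[b]: b for b in bcs}
    segs = [(s, *segment_coefficients(s, blood)) for s in network.segments]

    # fixed-pressure nodes
    pinned: dict[str, float] = {}
    if fraction_mode:
        pinned[network.inlet_node] = reference_pressure
    for b, bc in bcs.items():
        node = network.outlets[b]
        if bc.mode is BCMode.ZERO_PRESSURE:
            pinned[node] = venous_pressure
        elif bc.mode is BCMode.RESISTANCE and bc.value == 0.0:
            pinned[node] = venous_pressure

    unknowns = sorted(n for n in network.nodes if n not in pinned)
    idx = {n: i for i, n in enumerate(unknowns)}
    n_unk = len(unknowns)

    def pressures(x: np.ndarray) -> dict[str, float]:
        p = dict(pinned)
        p.update({n: x[idx[n]] for n in unknowns})
        return p

    def residual_jac(x: np.ndarray):
        p = pressures(x)
        F = np.zeros(n_unk)
        J = np.zeros((n_unk, n_unk))
        flows: dict[str, float] = {}

        def add(node, val):
            if node in idx:
                F[idx[node]] += val

        def add_j(node_r, node_c, val):
            if node_r in idx and node_c in idx:
                J[idx[node_r]][idx[node_c]] += val

        for s, R, K in segs:
            dp = p[s.from_node] - p[s.to_node]
            q, dq = _flow_from_dp(dp, R, K)
            flows[s.id] = q
            add(s.from_node, -q)
            add(s.to_node, q)
            add_j(s.from_node, s.from_node, -dq)
            add_j(s.from_node, s.to_node, dq)
            add_j(s.to_node, s.from_node, dq)
            add_j(s.to_node, s.to_node, -dq)
        add(network.inlet_node, inlet_flow)
        for b, bc in bcs.items():
            node = network.outlets[b]
            if bc.mode is BCMode.PRESCRIBED_FRACTION:
                add(node, -bc.value * inlet_flow)
            elif bc.mode is BCMode.RESISTANCE and bc.value > 0.0:
                add(node, -(p[node] - venous_pressure) / bc.value)
                add_j(node, node, -1.0 / bc.value)
        return F, J, flows, p

    # initial guess: linearised (Poiseuille-only) solve
    x = _linear_initial_guess(network, bcs, segs, pinned, unknowns, idx,
                              inlet_flow, venous_pressure)

    trace = []
    for it in range(max_iter):
        F, J, flows, p = residual_jac(x)
        res = float(np.max(np.abs(F))) / inlet_flow if n_unk else 0.0
        trace.append(res)
        if res <= tol:
            break
        # accept stagnation at the round-off floor once well converged
        if len(trace) > 1 and res <= 1e-10 and res >= 0.5 * trace[-2]:
            break
        try:
            dx = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError as e:
            raise SolverError(f"singular Jacobian at iteration {it}: {e}",
                              trace)
        x = x + (0.7 if it < 5 else 1.0) * dx
    else:
        raise SolverError(
            f"steady solve did not converge in {max_iter} iterations "
            f"(residual {trace[-1]:.3e})", trace)

    # assemble results
    Q: dict[str, float] = {}
    P_out: dict[str, float] = {}
    g_in: dict[str, float] = {}
    for s, R, K in segs:
        q = flows[s.id]
        g_in[s.to_node] = g_in.get(s.to_node, 0.0) + q
        g_in[s.from_node] = g_in.get(s.from_node, 0.0) - q
    for b in bcs:
        node = network.outlets[b]
        Q[b] = g_in.get(node, 0.0)
        P_out[b] = p[node]
    return SteadyResult(node_pressure=p, segment_flow=dict(flows),
                        P_in=p[network.inlet_node], P_out=P_out, Q=Q)


def _linear_initial_guess(network, bcs, segs, pinned, unknowns, idx,
                          inlet_flow, venous_pressure) -> np.ndarray:
    n_unk = len(unknowns)
    A = np.zeros((n_unk, n_unk))
    rhs = np.zeros(n_unk)

    def add_a(nr, nc, val):
        if nr in idx and nc in idx:
            A[idx[nr]][idx[nc]] += val

    def add_rhs(node, val):
        if node in idx:
            rhs[idx[node]] += val

    for s, R, K in segs:
        g = 1.0 / R
        add_a(s.from_node, s.from_node, -g)
        add_a(s.from_node, s.to_node, g)
        add_a(s.to_node, s.from_node, g)
        add_a(s.to_node, s.to_node, -g)
        # pinned-node pressures contribute constant terms to the residual
        for a_node, b_node in ((s.from_node, s.to_node),
                               (s.to_node, s.from_node)):
            if a_node in idx and b_node in pinned:
                rhs[idx[a_node]] += g * pinned[b_node]
    add_rhs(network.inlet_node, inlet_flow)
    for b, bc in bcs.items():
        node = network.outlets[b]
        if bc.mode is BCMode.PRESCRIBED_FRACTION:
            add_rhs(node, -bc.value * inlet_flow)
        elif bc.mode is BCMode.RESISTANCE and bc.value > 0.0:
            add_a(node, node, -1.0 / bc.value)
            add_rhs(node, venous_pressure / bc.value)
    if n_unk == 0:
        return np.zeros(0)
    try:
        return np.linalg.solve(A, -rhs)
    except np.linalg.LinAlgError:
        return np.zeros(n_unk)


def solve_zero_pressure(network: AorticNetwork, inlet_flow: float,
                        blood: BloodProperties = BloodProperties(),
                        **kwargs) -> tuple[SteadyResult, dict[str, float]]:
    """Steady solve with zero-pressure outlets; also returns the flow
    division Q_i / inlet_flow determined purely by geometric resistance."""
    bcs = {b: OutletBC(BCMode.ZERO_PRESSURE) for b in network.outlets}
    res = solve_steady(network, inlet_flow, bcs, blood=blood, **kwargs)
    division = {b: q / inlet_flow for b, q in res.Q.items()}
    return res, division
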