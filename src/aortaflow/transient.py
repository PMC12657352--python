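"""Time-resolved 0D simulation with three-element Windkessel outlets.

Backward-Euler (first-order implicit) time stepping: at each step the
nonlinear nodal system and the Windkessel capacitor states are solved
simultaneously.  The outlet law couples the outlet node pressure P to
the capacitor pressure P_c through the characteristic resistance,

    Q_i = (P_i − P_c,i) / R_c,i
    C_i · (P_c,i^{n+1} − P_c,i^n)/Δt = Q_i^{n+1} − P_c,i^{n+1} / R_p,i

with Δt = T / n_steps_per_cycle.  The default protocol runs 1,000
steps per cycle over 5 cardiac cycles and analyses the final cycle.
Capacitor pressures are initialised from the steady solve at the
cycle-mean inflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .estimation import Windkessel3
from .network import AorticNetwork, ValidationError
from .steady import (BCMode, BloodProperties, OutletBC, SolverError,
                     segment_coefficients, solve_steady, _flow_from_dp)
from .waveform import InletWaveform, scale_waveform

__all__ = [
    "TransientResult",
    "solve_transient",
    "periodicity",
    "scale_waveform",
    "InletWaveform",
]


@dataclass
class TransientResult:
    """Series output of one transient run (pressures mmHg, flows mL·s⁻¹).

    Arrays are indexed ``[time, entity]``; ``times`` includes the
    initial instant, so a run of ``n_cycles`` cycles of ``n_steps``
    steps has ``n_cycles·n_steps + 1`` samples.
    """

    times: np.ndarray
    node_ids: list[str]
    node_pressure: np.ndarray       # (n_t, n_nodes)
    segment_ids: list[str]
    segment_flow: np.ndarray        # (n_t, n_segments)
    outlet_names: list[str]
    capacitor_pressure: np.ndarray  # (n_t, n_outlets)
    outlet_flow: np.ndarray         # (n_t, n_outlets)
    inlet_flow: np.ndarray          # (n_t,)
    inlet_node: str
    cycles_run: int
    n_steps_per_cycle: int

    def node_series(self, node: str) -> np.ndarray:
        return self.node_pressure[:, self.node_ids.index(node)]

    def segment_series(self, seg_id: str) -> np.ndarray:
        return self.segment_flow[:, self.segment_ids.index(seg_id)]

    def inlet_pressure(self) -> np.ndarray:
        return self.node_series(self.inlet_node)

    def last_cycle(self) -> slice:
        n = self.n_steps_per_cycle
        return slice(self.times.size - n - 1, self.times.size)

    def cycle(self, k: int) -> slice:
        n = self.n_steps_per_cycle
        return slice(k * n, (k + 1) * n + 1)


def solve_transient(network: AorticNetwork,
                    waveform: InletWaveform,
                    wk3_map: Mapping[str, Windkessel3],
                    n_steps_per_cycle: int = 1000,
                    n_cycles: int = 5,
                    blood: BloodProperties = BloodProperties(),
                    newton_tol: float = 1e-10,
                    max_newton: int = 50,
                    ) -> TransientResult:
    """Run the transient simulation.

    Every outlet must carry a :class:`Windkessel3`.  Raises
    :class:`~aortaflow.steady.SolverError` (with the step index) if the
    per-step Newton iteration fails.
    """
    for b in network.outlets:
        if b not in wk3_map:
            raise ValidationError(f"missing Windkessel parameters for {b}")
    if n_steps_per_cycle < 2 or n_cycles < 1:
        raise ValidationError("need n_steps_per_cycle >= 2 and n_cycles >= 1")
    network.validate()

    T = waveform.period
    dt = T / n_steps_per_cycle
    n_t = n_cycles * n_steps_per_cycle + 1
    times = np.arange(n_t) * dt

    nodes = sorted(network.nodes)
    nidx = {n: i for i, n in enumerate(nodes)}
    n_nodes = len(nodes)
    outlets = sorted(network.outlets)
    onode = [network.outlets[b] for b in outlets]
    wk = [wk3_map[b] for b in outlets]
    n_out = len(outlets)
    segs = [(s, *segment_coefficients(s, blood)) for s in network.segments]
    seg_ids = [s.id for s, _, _ in segs]
    inlet_i = nidx[network.inlet_node]

    # initial state: steady solve at the cycle-mean inflow through the
    # equivalent series resistance R_c + R_p
    q_mean = waveform.cycle_mean()
    q_init = q_mean if q_mean > 0 else max(1e-6, float(np.max(
        np.abs(waveform.flow))) * 1e-3)
    bcs = {b: OutletBC(BCMode.RESISTANCE, w.R_c + w.R_p)
           for b, w in zip(outlets, wk)}
    steady0 = solve_steady(network, q_init, bcs, blood=blood)
    x = np.empty(n_nodes + n_out)
    for n, i in nidx.items():
        x[i] = steady0.node_pressure[n]
    for j, b in enumerate(outlets):
        x[n_nodes + j] = steady0.Q[b] * wk[j].R_p

    P = np.empty((n_t, n_nodes))
    Pc = np.empty((n_t, n_out))
    Qseg = np.empty((n_t, len(segs)))
    Qout = np.empty((n_t, n_out))
    Qin = waveform.interp(times)

    def record(k, x, flows):
        P[k] = x[:n_nodes]
        Pc[k] = x[n_nodes:]
        Qseg[k] = flows
        for j in range(n_out):
            Qout[k, j] = (x[nidx[onode[j]]] - x[n_nodes + j]) / wk[j].R_c

    flows0 = np.array([steady0.segment_flow[i] for i in seg_ids])
    record(0, x, flows0)

    n_unk = n_nodes + n_out
    for k in range(1, n_t):
        q_in = Qin[k]
        pc_old = Pc[k - 1]
        for it in range(max_newton):
            F = np.zeros(n_unk)
            J = np.zeros((n_unk, n_unk))
            flows = np.empty(len(segs))
            for m, (s, R, K) in enumerate(segs):
                iu, iv = nidx[s.from_node], nidx[s.to_node]
                q, dq = _flow_from_dp(x[iu] - x[iv], R, K)
                flows[m] = q
                F[iu] -= q
                F[iv] += q
                J[iu, iu] -= dq
                J[iu, iv] += dq
                J[iv, iu] += dq
                J[iv, iv] -= dq
            F[inlet_i] += q_in
            for j in range(n_out):
                i_o, jc = nidx[onode[j]], n_nodes + j
                w = wk[j]
                q_o = (x[i_o] - x[jc]) / w.R_c
                F[i_o] -= q_o
                J[i_o, i_o] -= 1.0 / w.R_c
                J[i_o, jc] += 1.0 / w.R_c
                # capacitor balance (backward Euler)
                F[jc] = (w.C * (x[jc] - pc_old[j]) / dt
                         - q_o + x[jc] / w.R_p)
                J[jc, jc] = w.C / dt + 1.0 / w.R_c + 1.0 / w.R_p
                J[jc, i_o] = -1.0 / w.R_c
            scale = max(abs(q_in), abs(q_mean), 1.0)
            if np.max(np.abs(F)) / scale <= newton_tol:
                break
            try:
                x = x + np.linalg.solve(J, -F)
            except np.linalg.LinAlgError as e:
                raise SolverError(f"singular Jacobian at step {k}: {e}")
        else:
            raise SolverError(f"Newton failed to converge at step {k}")
        record(k, x, flows)

    return TransientResult(
        times=times, node_ids=nodes, node_pressure=P,
        segment_ids=seg_ids, segment_flow=Qseg,
        outlet_names=outlets, capacitor_pressure=Pc, outlet_flow=Qout,
        inlet_flow=Qin, inlet_node=network.inlet_node,
        cycles_run=n_cycles, n_steps_per_cycle=n_steps_per_cycle)


def periodicity(result: TransientResult) -> float:
    """Max relative cycle-to-cycle change of the inlet pressure between
    the final two cycles: max_φ |P_k(φ) − P_{k−1}(φ)| / mean |P_k|."""
    if result.cycles_run < 2:
        raise ValidationError("periodicity needs at least 2 cycles")
    p = result.inlet_pressure()
    last = p[result.cycle(result.cycles_run - 1)]
    prev = p[result.cycle(result.cycles_run - 2)]
    denom = float(np.mean(np.abs(last)))
    if denom == 0.0:
        denom = 1.0
    return float(np.max(np.abs(last - prev)) / denom)
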