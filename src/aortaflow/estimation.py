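"""Boundary-condition estimation for diseased aortas.

This module houses the method the package exists for: estimating the
flow division in the branches of a diseased aorta when no measured
branch flows are available.

The procedure anchors healthy-state empirical flow fractions on a
digitally repaired *reference* geometry, converts the reference outlet
pressures into resistance outlet models,

    R_i = (P_mean − (P_in − P_out,i)) / Q_i        [mmHg·s·mL⁻¹]

applies those resistances to the *diseased* geometry, and iteratively
adjusts the mean-pressure level P_mean until the predicted inlet
pressure of the diseased model matches the patient's target aortic
mean pressure to within a 1 % relative threshold.  The flow division
of the converged diseased solve is the estimate.

The patient target is derived from cuff (brachial) pressures through
the standard empirical conversion

    P_sys,ao  = 0.83·P_sys,bra + 0.15·P_dia,bra
    P_dia,ao  = P_dia,bra
    P_mean,ao = 0.4·P_sys,ao + 0.6·P_dia,ao

and the inlet flow is the mean systolic flow of the patient's inlet
waveform.  Downstream three-element Windkessel parameters for the
transient simulation are tuned from the converged division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .network import AorticNetwork, MANDATORY_BRANCHES, ValidationError
from .steady import (BCMode, BloodProperties, OutletBC, SteadyResult,
                     solve_steady)
from .waveform import InletWaveform, mean_systolic_flow

__all__ = [
    "PressureTargets",
    "FlowDivision",
    "IterationTrace",
    "Windkessel3",
    "EstimationConfig",
    "NonConvergenceError",
    "NegativeResistanceError",
    "empirical_division",
    "brachial_to_aortic",
    "mean_systolic_flow",
    "outlet_resistances",
    "estimate_division",
    "tune_windkessel",
    "compare_divisions",
]

# Empirical healthy-subject flow-division constants: 30 % of cardiac
# output to the supra-aortic branches (split in proportion to their
# cross-sectional areas), fixed visceral fractions, 0.5 % to the IMA
# when present, and the remainder split equally between the two sides
# with a 30/70 internal/external iliac split.
SUPRA_AORTIC_TOTAL = 0.30
VISCERAL_FRACTIONS = {"CT": 0.155, "SMA": 0.105, "LRA": 0.105, "RRA": 0.105}
IMA_FRACTION = 0.005
ILIAC_INTERNAL_SHARE = 0.30
ILIAC_EXTERNAL_SHARE = 0.70


@dataclass(frozen=True)
class PressureTargets:
    """Brachial measurements and derived aortic pressure targets (mmHg)."""

    P_sys_bra: float
    P_dia_bra: float
    P_sys_ao: float
    P_dia_ao: float
    P_mean_ao: float

    def __post_init__(self):
        for s, d in ((self.P_sys_bra, self.P_dia_bra),
                     (self.P_sys_ao, self.P_dia_ao)):
            if not (s > d > 0):
                raise ValidationError(
                    f"systolic must exceed diastolic (> 0): got {s}, {d}")


@dataclass
class FlowDivision:
    """Outlet flow fractions; non-negative and summing to 1."""

    fraction: dict[str, float]

    def __post_init__(self):
        for b, f in self.fraction.items():
            if f < 0:
                raise ValidationError(f"negative fraction for {b}: {f}")
        total = sum(self.fraction.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fractions must sum to 1, got {total!r}")

    def __getitem__(self, branch: str) -> float:
        return self.fraction[branch]

    def branches(self) -> list[str]:
        return sorted(self.fraction)

    def as_vector(self, branches=None) -> np.ndarray:
        return np.array([self.fraction[b]
                         for b in (branches or self.branches())])


@dataclass
class IterationTrace:
    """Per-iteration record of the pressure-matching loop."""

    records: list[dict] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def add(self, p_mean: float, p_pred: float, discrepancy: float) -> None:
        self.records.append({"P_mean": p_mean, "P_pred": p_pred,
                             "discrepancy": discrepancy})
        self.n_iter = len(self.records)


@dataclass(frozen=True)
class Windkessel3:
    """Three-element Windkessel: characteristic resistance R_c in series
    with peripheral resistance R_p parallel to compliance C."""

    R_c: float  # mmHg·s·mL⁻¹
    R_p: float  # mmHg·s·mL⁻¹
    C: float    # mL·mmHg⁻¹

    def __post_init__(self):
        if self.R_c < 0 or self.R_p <= 0 or self.C <= 0:
            raise ValidationError(
                f"Windkessel parameters must be positive, got {self}")


@dataclass
class EstimationConfig:
    """Knobs of the iterative estimation and Windkessel tuning."""

    omega: float = 1.0          # relaxation of the P_mean update
    threshold: float = 0.01     # relative inlet-pressure discrepancy
    max_iter: int = 50
    f_c: float = 0.056          # characteristic share of total WK resistance
    tau: float = 1.79           # global RC time constant, s
    venous_pressure: float = 0.0
    use_systolic_branch_flow: bool = False  # WK tuning flow basis

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValidationError("threshold must be in (0, 1)")
        if not (0.0 < self.omega <= 2.0):
            raise ValidationError("omega must be in (0, 2]")
        if not (0.0 <= self.f_c < 1.0):
            raise ValidationError("f_c must be in [0, 1)")
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")


class NonConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace: IterationTrace):
        super().__init__(msg)
        self.trace = trace


class NegativeResistanceError(ValueError):
    """The resistance conversion produced R_i <= 0: the mean pressure
    lies below the geometric drop of some branch."""


# ---------------------------------------------------------------------------


def empirical_division(network: AorticNetwork) -> FlowDivision:
    """Healthy-subject empirical flow division for a 12-branch aorta.

    30 % of cardiac output goes to the supra-aortic branches (BT, LCC,
    LSA) in proportion to their inlet cross-sectional areas; the celiac
    trunk receives 15.5 %, the SMA and both renal arteries 10.5 % each,
    the IMA 0.5 % when present; the remainder is split equally between
    the left and right iliac systems, 70 % external / 30 % internal.
    """
    present = set(network.outlets)
    missing = [b for b in MANDATORY_BRANCHES if b not in present]
    if missing:
        raise ValidationError(f"missing mandatory branches: {missing}")

    frac: dict[str, float] = {}
    supra = ("BT", "LCC", "LSA")
    areas = {b: network.branch_inlet_area[b] for b in supra}
    total_area = sum(areas.values())
    for b in supra:
        frac[b] = SUPRA_AORTIC_TOTAL * areas[b] / total_area
    frac.update(VISCERAL_FRACTIONS)
    allocated = SUPRA_AORTIC_TOTAL + sum(VISCERAL_FRACTIONS.values())
    if "IMA" in present:
        frac["IMA"] = IMA_FRACTION
        allocated += IMA_FRACTION
    per_side = (1.0 - allocated) / 2.0
    for side in ("L", "R"):
        frac[f"{side}EIA"] = ILIAC_EXTERNAL_SHARE * per_side
        frac[f"{side}IIA"] = ILIAC_INTERNAL_SHARE * per_side
    return FlowDivision(frac)


def brachial_to_aortic(P_sys_bra: float, P_dia_bra: float) -> PressureTargets:
    """Convert cuff pressures to aortic targets (mmHg)."""
    if not (P_sys_bra > P_dia_bra > 0):
        raise ValidationError(
            f"require P_sys_bra > P_dia_bra > 0, got {P_sys_bra}, {P_dia_bra}")
    p_sys_ao = 0.83 * P_sys_bra + 0.15 * P_dia_bra
    p_dia_ao = P_dia_bra
    p_mean_ao = 0.4 * p_sys_ao + 0.6 * p_dia_ao
    return PressureTargets(P_sys_bra, P_dia_bra, p_sys_ao, p_dia_ao,
                           p_mean_ao)


def outlet_resistances(ref_result: SteadyResult,
                       P_mean: float) -> dict[str, float]:
    """Convert reference outlet pressures into outlet resistances:
    R_i = (P_mean − dP_i) / Q_i with dP_i = P_in − P_out,i."""
    resistances: dict[str, float] = {}
    for b, q in ref_result.Q.items():
        if q <= 0:
            raise ValidationError(f"branch {b}: reference flow must be > 0")
        r = (P_mean - ref_result.dP[b]) / q
        if r <= 0:
            raise NegativeResistanceError(
                f"branch {b}: mean pressure {P_mean:.3f} mmHg is below the "
                f"geometric drop {ref_result.dP[b]:.3f} mmHg")
        resistances[b] = r
    return resistances


def estimate_division(reference: AorticNetwork,
                      diseased: AorticNetwork,
                      targets: PressureTargets,
                      waveform: InletWaveform,
                      config: EstimationConfig | None = None,
                      blood: BloodProperties = BloodProperties(),
                      ) -> tuple[FlowDivision, IterationTrace,
                                 dict[str, float]]:
    """Iteratively estimate the diseased-aorta flow division.

    Steps: (1) the mean systolic inlet flow is taken from the waveform;
    (2) the reference network is solved once with the empirical
    division prescribed, yielding datum-independent drops dP_i;
    (3)–(6) resistances R_i = (P_mean − dP_i)/Q_i are imposed on the
    diseased network, its inlet pressure P_pred is computed at the same
    inlet flow, and P_mean is updated additively (relaxation ω) until
    |P_pred − P_mean,ao| / P_mean,ao falls below the threshold.

    Returns the converged flow division, the iteration trace and the
    final resistance map.
    """
    cfg = config or EstimationConfig()
    if set(reference.outlets) != set(diseased.outlets):
        raise ValidationError("reference and diseased branch sets differ")

    q_in = mean_systolic_flow(waveform)
    division0 = empirical_division(reference)
    ref_bcs = {b: OutletBC(BCMode.PRESCRIBED_FRACTION, division0[b])
               for b in reference.outlets}
    # the reference solve is needed only once: dP_i is independent of
    # the pressure level in the resistance conversion
    ref_result = solve_steady(reference, q_in, ref_bcs, blood=blood)

    trace = IterationTrace()
    p_mean = targets.P_mean_ao
    resistances: dict[str, float] = {}
    dis_result: SteadyResult | None = None
    for _ in range(cfg.max_iter):
        resistances = outlet_resistances(ref_result, p_mean)
        dis_bcs = {b: OutletBC(BCMode.RESISTANCE, r)
                   for b, r in resistances.items()}
        dis_result = solve_steady(diseased, q_in, dis_bcs, blood=blood,
                                  venous_pressure=cfg.venous_pressure)
        p_pred = dis_result.P_in
        disc = abs(p_pred - targets.P_mean_ao) / targets.P_mean_ao
        trace.add(p_mean, p_pred, disc)
        if disc < cfg.threshold:
            trace.converged = True
            break
        p_mean = p_mean + cfg.omega * (targets.P_mean_ao - p_pred)
    if not trace.converged:
        raise NonConvergenceError(
            f"pressure matching did not converge in {cfg.max_iter} "
            f"iterations (last discrepancy "
            f"{trace.records[-1]['discrepancy']:.3e})", trace)

    division = FlowDivision({b: q / q_in for b, q in dis_result.Q.items()})
    return division, trace, resistances


def tune_windkessel(diseased: AorticNetwork,
                    division: FlowDivision,
                    targets: PressureTargets,
                    waveform: InletWaveform,
                    config: EstimationConfig | None = None,
                    blood: BloodProperties = BloodProperties(),
                    ) -> dict[str, Windkessel3]:
    """Tune per-outlet three-element Windkessel parameters.

    A single steady solve of the diseased network at the mean systolic
    inflow with the division prescribed gives the internal drops dP_i;
    the total outlet resistance is R_i = (P_mean,ao − dP_i)/Q̄_i with
    Q̄_i the cycle-mean branch flow (optionally the mean-systolic
    flow).  R_i is split as R_c = f_c·R_i, R_p = (1 − f_c)·R_i and the
    compliance follows from a global time constant, C_i = τ / R_p,i.
    """
    cfg = config or EstimationConfig()
    q_sys = mean_systolic_flow(waveform)
    q_basis = q_sys if cfg.use_systolic_branch_flow else waveform.cycle_mean()
    if q_basis <= 0:
        raise ValidationError("waveform mean flow must be > 0")
    bcs = {b: OutletBC(BCMode.PRESCRIBED_FRACTION, division[b])
           for b in diseased.outlets}
    result = solve_steady(diseased, q_sys, bcs, blood=blood)

    wk: dict[str, Windkessel3] = {}
    for b in diseased.outlets:
        q_i = division[b] * q_basis
        r_total = (targets.P_mean_ao - result.dP[b]) / q_i
        if r_total <= 0:
            raise NegativeResistanceError(
                f"branch {b}: target mean pressure below geometric drop")
        r_c = cfg.f_c * r_total
        r_p = (1.0 - cfg.f_c) * r_total
        wk[b] = Windkessel3(R_c=r_c, R_p=r_p, C=cfg.tau / r_p)
    return wk


def compare_divisions(a, b) -> tuple[float, float, tuple[float, float]]:
    """Pearson correlation and Bland–Altman agreement of two divisions.

    Accepts :class:`FlowDivision` objects or plain branch→value
    mappings (the latter need not be normalised).  Returns
    ``(pearson_r, mean_difference, (loa_low, loa_high))`` where the
    limits of agreement are mean ± 1.96·SD of the differences.
    """
    fa = a.fraction if isinstance(a, FlowDivision) else dict(a)
    fb = b.fraction if isinstance(b, FlowDivision) else dict(b)
    if set(fa) != set(fb):
        raise ValidationError("divisions cover different branch sets")
    branches = sorted(fa)
    if len(branches) < 3:
        raise ValidationError("need at least 3 branches to compare")
    va = np.array([fa[k] for k in branches])
    vb = np.array([fb[k] for k in branches])
    sa, sb = va.std(), vb.std()
    if sa == 0.0 or sb == 0.0:
        r = 1.0 if np.allclose(va - va.mean(), vb - vb.mean()) else float("nan")
    else:
        r = float(np.corrcoef(va, vb)[0, 1])
    diff = vb - va
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=0))
    loa = (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)
    return r, mean_diff, loa
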