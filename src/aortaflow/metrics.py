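"""Hemodynamic metric suite.

Cycle-integrated wall-shear-stress metrics on sampled WSS series
(trapezoidal quadrature throughout):

    TAWSS = (1/T) ∫ |τ_w| dt
    OSI   = ½ (1 − |∫ τ_w dt| / ∫ |τ_w| dt)           ∈ [0, 0.5]
    RRT   = 1 / ((1 − 2·OSI) · TAWSS)                  Pa⁻¹
    AFI   = cos ∠(τ_w(t_obs), ∫ τ_w dt)               ∈ [−1, 1]

AFI is evaluated at mid-systolic deceleration, operationalised as the
instant of steepest inlet-flow deceleration within systole.  Local
normalized helicity (LNH) is the cosine of the angle between velocity
and vorticity on a structured grid; transmural pressure (TMP) is the
true-minus-false lumen pressure difference at matched stations.

Points where a metric is undefined (zero shear, vanishing velocity or
vorticity) are carried as NaN flags rather than raised, so field
summaries remain computable; an OSI of exactly 0.5 makes RRT +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import units
from .network import AorticNetwork, ValidationError
from .transient import TransientResult
from .waveform import InletWaveform, systolic_interval

__all__ = [
    "WSSSeries",
    "VelocityField",
    "PlanePairSeries",
    "tawss",
    "osi",
    "rrt",
    "afi",
    "mid_systolic_deceleration",
    "poiseuille_wss",
    "lnh",
    "tmp",
    "sample_every_tenth",
]


@dataclass
class WSSSeries:
    """Wall-shear vectors over one cycle: times (n_t,), tau (n_t, n_p, d).

    ``tau`` may be given as (n_t, n_p) of signed scalars; it is lifted
    to 1-component vectors internally.
    """

    times: np.ndarray
    tau: np.ndarray
    point_ids: Optional[list[str]] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.ndim == 2:
            self.tau = self.tau[:, :, None]
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValidationError("WSS series needs >= 1 time sample")
        if self.tau.shape[0] != self.times.size:
            raise ValidationError("tau first axis must match times")
        if not np.all(np.isfinite(self.tau)):
            raise ValidationError("WSS values must be finite")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=2)


@dataclass
class VelocityField:
    """Velocity vectors on a uniform structured grid.

    ``spacing`` is the grid step per axis (m); ``v`` has shape
    (nx, ny, nz, 3), with at least 3 points per differentiated axis.
    """

    spacing: tuple[float, float, float]
    v: np.ndarray

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 4 or self.v.shape[-1] != 3:
            raise ValidationError("velocity field must be (nx, ny, nz, 3)")
        if any(h <= 0 for h in self.spacing):
            raise ValidationError("grid spacing must be > 0")
        if any(n < 3 for n in self.v.shape[:3]):
            raise ValidationError("need >= 3 grid points per axis")


@dataclass
class PlanePairSeries:
    """Paired true/false-lumen pressures (mmHg) at matched stations."""

    p_tl: np.ndarray
    p_fl: np.ndarray

    def __post_init__(self):
        self.p_tl = np.asarray(self.p_tl, dtype=float)
        self.p_fl = np.asarray(self.p_fl, dtype=float)
        if self.p_tl.shape != self.p_fl.shape:
            raise ValidationError("TL/FL series must have equal shapes")


# ---------------------------------------------------------------------------
# WSS metrics


def _integrals(series: WSSSeries) -> tuple[np.ndarray, np.ndarray]:
    """(∫|τ|dt per point, ∫τ dt vector per point)."""
    if series.times.size < 2:
        raise ValidationError("cycle integrals need >= 2 time samples")
    t = series.times
    int_mag = np.trapezoid(series.magnitude(), t, axis=0)
    int_vec = np.trapezoid(series.tau, t, axis=0)
    return int_mag, int_vec


def tawss(series: WSSSeries) -> np.ndarray:
    """Time-averaged WSS magnitude per point, Pa."""
    int_mag, _ = _integrals(series)
    return int_mag / series.period


def osi(series: WSSSeries) -> np.ndarray:
    """Oscillatory shear index per point, in [0, 0.5]; NaN where the
    shear is identically zero."""
    int_mag, int_vec = _integrals(series)
    mag_of_int = np.linalg.norm(int_vec, axis=1)
    out = np.full(int_mag.shape, np.nan)
    ok = int_mag > 0.0
    out[ok] = 0.5 * (1.0 - mag_of_int[ok] / int_mag[ok])
    return np.clip(out, 0.0, 0.5)


def rrt(series: WSSSeries) -> np.ndarray:
    """Relative residence time per point, Pa⁻¹: the reciprocal of the
    magnitude of the time-averaged WSS vector, computed as
    1/((1 − 2·OSI)·TAWSS) on the same quadrature; +inf where OSI = 0.5,
    NaN where OSI is undefined."""
    denom = (1.0 - 2.0 * osi(series)) * tawss(series)
    out = np.full(denom.shape, np.nan)
    ok = ~np.isnan(denom)
    with np.errstate(divide="ignore"):
        out[ok] = np.where(denom[ok] > 0.0, 1.0 / denom[ok], np.inf)
    return out


def mid_systolic_deceleration(waveform: InletWaveform) -> float:
    """Instant of steepest inlet-flow deceleration within systole."""
    _, t_end = systolic_interval(waveform)
    t, q = waveform.time, waveform.flow
    dq = np.gradient(q, t)
    mask = (t > 0) & (t <= t_end)
    if not mask.any():
        raise ValidationError("no samples within systole")
    idx = np.flatnonzero(mask)
    return float(t[idx[np.argmin(dq[idx])]])


def afi(series: WSSSeries, t_obs: float) -> np.ndarray:
    """Aneurysm formation indicator at ``t_obs``: the cosine of the
    angle between the instantaneous and the cycle-mean WSS vector;
    NaN where either vanishes."""
    if not (series.times[0] <= t_obs <= series.times[-1]):
        raise ValidationError(f"t_obs {t_obs} outside the cycle")
    _, int_vec = _integrals(series)
    k = int(np.argmin(np.abs(series.times - t_obs)))
    tau_obs = series.tau[k]
    num = np.einsum("pd,pd->p", tau_obs, int_vec)
    den = (np.linalg.norm(tau_obs, axis=1)
           * np.linalg.norm(int_vec, axis=1))
    out = np.full(num.shape, np.nan)
    ok = den > 0.0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def poiseuille_wss(result: TransientResult,
                   network: AorticNetwork,
                   viscosity: float = 0.0035) -> WSSSeries:
    """Signed axial wall shear at each segment midpoint over the final
    cycle, from the Poiseuille profile: τ(t) = 4 μ Q(t) / (π r³), Pa."""
    sl = result.last_cycle()
    times = result.times[sl] - result.times[sl][0]
    radii = {s.id: s.radius * units.M_PER_CM for s in network.segments}
    cols, ids = [], []
    for j, sid in enumerate(result.segment_ids):
        if sid not in radii:
            continue
        q = result.segment_flow[sl, j] * units.M3_PER_ML
        cols.append(4.0 * viscosity * q / (math.pi * radii[sid]**3))
        ids.append(sid)
    return WSSSeries(times, np.column_stack(cols), point_ids=ids)


# ---------------------------------------------------------------------------
# helicity and transmural pressure


def lnh(field: VelocityField, tol: float = 1e-12) -> np.ndarray:
    """Local normalized helicity v·(∇×v)/(|v||∇×v|) per grid point.

    Curl by central differences (second-order one-sided at the grid
    boundary); NaN where |v| or |∇×v| falls below ``tol``.
    """
    hx, hy, hz = field.spacing
    v = field.v
    grads = [np.gradient(v[..., c], hx, hy, hz, edge_order=2)
             for c in range(3)]  # grads[c][axis] = d v_c / d axis
    curl = np.stack([
        grads[2][1] - grads[1][2],
        grads[0][2] - grads[2][0],
        grads[1][0] - grads[0][1],
    ], axis=-1)
    vmag = np.linalg.norm(v, axis=-1)
    cmag = np.linalg.norm(curl, axis=-1)
    num = np.einsum("...d,...d->...", v, curl)
    out = np.full(vmag.shape, np.nan)
    ok = (vmag > tol) & (cmag > tol)
    out[ok] = num[ok] / (vmag[ok] * cmag[ok])
    return np.clip(out, -1.0, 1.0)


def tmp(pair_series: PlanePairSeries) -> tuple[np.ndarray, list[float]]:
    """Transmural pressure P_TL − P_FL per station (mmHg) and the
    interpolated station indices of its zero crossings (the balance
    points where TL and FL pressures coincide)."""
    d = pair_series.p_tl - pair_series.p_fl
    profile = d if d.ndim == 1 else d.mean(axis=0)
    crossings: list[float] = []
    for i in range(profile.size - 1):
        a, b = profile[i], profile[i + 1]
        if a == 0.0:
            crossings.append(float(i))
        elif a * b < 0.0:
            crossings.append(float(i + a / (a - b)))
    if profile.size and profile[-1] == 0.0:
        crossings.append(float(profile.size - 1))
    return d, crossings


def sample_every_tenth(series: WSSSeries) -> WSSSeries:
    """Decimate a cycle series to every tenth sample (indices 0, 10, …),
    the conventional thinning for temporal statistics."""
    keep = np.arange(0, series.times.size, 10)
    ids = series.point_ids
    return WSSSeries(series.times[keep], series.tau[keep], point_ids=ids)
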