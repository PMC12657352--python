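"""Inlet flow waveforms.

The package ships a documented piecewise-analytic template waveform —
a half-sine systolic pulse over the first third of the cycle followed
by a small reverse-flow notch and a flat diastole — standing in for the
empirical literature waveforms used in aortic simulations, which are
published graphically.  Templates are rescaled to a patient's heart
rate and, optionally, cardiac output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ValidationError

__all__ = [
    "InletWaveform",
    "default_template",
    "scale_waveform",
    "mean_systolic_flow",
    "systolic_interval",
]


@dataclass
class InletWaveform:
    """Sampled periodic inlet flow: time s (monotone, [0, T]), flow mL·s⁻¹."""

    time: np.ndarray
    flow: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.flow.shape:
            raise ValidationError("time and flow must be equal-length 1D")
        if self.time.size < 2:
            raise ValidationError("waveform needs at least 2 samples")
        if self.time[0] != 0.0:
            raise ValidationError("waveform must start at t = 0")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("waveform time axis must be monotone")
        if not np.all(np.isfinite(self.flow)):
            raise ValidationError("waveform flow must be finite")

    @property
    def period(self) -> float:
        return float(self.time[-1])

    def cycle_mean(self) -> float:
        """Cycle-averaged flow (mL·s⁻¹) by trapezoidal quadrature."""
        return float(np.trapezoid(self.flow, self.time) / self.period)

    def interp(self, t: float | np.ndarray) -> np.ndarray:
        """Periodic linear interpolation."""
        return np.interp(np.mod(t, self.period), self.time, self.flow)


def default_template(n_samples: int = 512,
                     peak_flow: float = 400.0,
                     systole_fraction: float = 1.0 / 3.0,
                     notch_fraction: float = 0.1,
                     notch_depth: float = 0.05) -> InletWaveform:
    """Template pulse with period 1 s.

    Half-sine systole of amplitude ``peak_flow`` over
    ``[0, systole_fraction·T]``, a reverse half-sine notch of amplitude
    ``notch_depth·peak_flow`` over the following ``notch_fraction·T``,
    zero flow for the rest of diastole.
    """
    t = np.linspace(0.0, 1.0, n_samples + 1)
    q = np.zeros_like(t)
    ts, tn = systole_fraction, systole_fraction + notch_fraction
    sys_mask = t <= ts
    q[sys_mask] = peak_flow * np.sin(np.pi * t[sys_mask] / ts)
    notch = (t > ts) & (t <= tn)
    q[notch] = -notch_depth * peak_flow * np.sin(
        np.pi * (t[notch] - ts) / (tn - ts))
    return InletWaveform(t, q)


def scale_waveform(template: InletWaveform, heart_rate: float,
                   cardiac_output: float | None = None) -> InletWaveform:
    """Rescale a template to a heart rate (bpm) and optional cardiac
    output (cycle-mean flow, mL·s⁻¹); amplitude preserved otherwise."""
    if heart_rate <= 0:
        raise ValidationError(f"heart_rate must be > 0, got {heart_rate}")
    T = 60.0 / heart_rate
    time = template.time * (T / template.period)
    flow = template.flow.copy()
    if cardiac_output is not None:
        mean = template.cycle_mean()
        if mean == 0:
            raise ValidationError("template cycle mean is zero; cannot scale")
        flow *= cardiac_output / mean
    return InletWaveform(time, flow)


def systolic_interval(waveform: InletWaveform) -> tuple[float, float]:
    """[0, t_end_sys]: systole ends at the first post-peak zero crossing
    of the flow (linearly interpolated), or at the global minimum if the
    flow never crosses zero."""
    t, q = waveform.time, waveform.flow
    if np.all(q == 0.0):
        raise ValidationError("all-zero waveform: no systole detectable")
    i_peak = int(np.argmax(q))
    for i in range(i_peak, t.size - 1):
        if q[i] > 0.0 >= q[i + 1]:
            if q[i + 1] == q[i]:
                return 0.0, float(t[i + 1])
            frac = q[i] / (q[i] - q[i + 1])
            return 0.0, float(t[i] + frac * (t[i + 1] - t[i]))
    # no zero crossing: end systole at the post-peak global minimum,
    # or treat the whole cycle as systolic if the flow never falls
    i_min = i_peak + int(np.argmin(q[i_peak:]))
    t_end = float(t[i_min])
    if t_end <= float(t[i_peak]):
        t_end = float(t[-1])
    return 0.0, t_end


def mean_systolic_flow(waveform: InletWaveform,
                       t_end: float | None = None) -> float:
    """Mean flow over the systolic interval (mL·s⁻¹), trapezoidal.

    ``t_end`` overrides the detected end of systole.
    """
    if t_end is None:
        _, t_end = systolic_interval(waveform)
    if not (0.0 < t_end <= waveform.period):
        raise ValidationError(f"systole end {t_end} outside the cycle")
    t, q = waveform.time, waveform.flow
    grid = np.unique(np.concatenate([t[t < t_end], [t_end]]))
    vals = np.interp(grid, t, q)
    return float(np.trapezoid(vals, grid) / t_end)
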