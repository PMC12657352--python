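# Methods

## Scope and model class

`aortaflow` replaces the 3D CFD forward model conventionally used for
aortic boundary-condition estimation with a 0D (lumped-parameter)
vascular network. A network is a directed graph of cylindrical
segments; the unknowns of a steady solve are nodal pressures, and
segment flows follow from a monotone constitutive law. This keeps the
whole estimation pipeline — digital repair, iterative flow-division
estimation, Windkessel tuning, transient simulation, metric suite —
exercisable in seconds on synthetic anatomies, at the cost of all 3D
flow features (secondary flow, jets, recirculation). Consequences of
that trade-off are listed under *Limitations*.

## Segment constitutive law

Pressure drop across a segment carrying flow Q:

    ΔP = R_pois·Q + K·Q·|Q|
    R_pois = 8 μ L / (π r⁴)
    K      = Kt · (ρ / 2 A_s²) · (A₀/A_s − 1)²,   A_s = area_ratio · A₀

The quadratic term is the classic empirical loss for blunt stenoses;
`Kt` defaults to 1.52 and is configurable per lesion. An
`area_ratio` of 1 makes the term vanish identically, so an "open
stenosis" is hemodynamically a plain tube. Coefficients are computed
from the SI formulas and converted once (1 mmHg = 133.322 Pa) so the
solvers operate throughout on mmHg, mL·s⁻¹ and mmHg·s·mL⁻¹ — every
iterated quantity is then O(1), which is numerically kinder than
mixed-magnitude SI values; all reported quantities are in these
conventional units.

## Steady solver

Newton iteration on nodal pressures with an analytic Jacobian
(dQ/dΔP = (R² + 4K|ΔP|)^(−1/2)), damping factor 0.7 on the first five
iterations, and an initial guess from the linearised (Poiseuille-only)
system — exact for stenosis-free networks, so Newton then terminates
in one step. Convergence is declared at a relative nodal imbalance of
1e−12 (stagnation just above that floor, but below 1e−10, is
accepted as round-off). Outlet modes:

* `PRESCRIBED_FRACTION` — outlet flows fixed at f_i·Q_in (fractions
  must sum to 1); the inlet node is pinned to a reference datum
  (default 0 mmHg), and the reported drops ΔP_i = P_in − P_out,i are
  datum-independent.
* `RESISTANCE` — P_out,i = R_i·Q_i above a venous reference pressure,
  default 0 mmHg (configurable; the physiological venous offset is
  small against aortic pressures and no datum is prescribed by the
  estimation rules themselves).
* `ZERO_PRESSURE` — outlet pinned to the venous reference; the
  division is then set purely by geometric resistance (the
  comparison case that motivates resistance outflow models).
* `WK3` — treated in steady state as the series resistance R_c + R_p.

## Empirical healthy-subject division

30 % of cardiac output to the supra-aortic branches, distributed
proportionally to their inlet cross-sectional areas; celiac trunk
15.5 %; SMA, left and right renal arteries 10.5 % each; IMA 0.5 % when
present; the remainder split equally between the sides and 70/30
between external and internal iliac arteries. With all twelve
branches present the per-side iliac pool is 11.25 % of cardiac
output, i.e. 7.875 % external / 3.375 % internal (printing as 7.9 %
and 3.4 %).

## Iterative flow-division estimation

Inputs: a diseased network, its repaired reference, cuff pressures
(converted to aortic targets by P_sys,ao = 0.83 P_sys,bra +
0.15 P_dia,bra, P_dia,ao = P_dia,bra, P_mean,ao = 0.4 P_sys,ao +
0.6 P_dia,ao) and an inlet waveform, whose mean systolic flow — mean
of Q(t) from t = 0 to the first post-peak zero crossing — drives all
steady solves.

The reference is solved **once**: the drops ΔP_i depend only on
geometry and inflow, not on the pressure level, so the resistance
conversion R_i = (P_mean − ΔP_i)/Q_i separates cleanly into a fixed
geometric part and the adjustable scalar P_mean. P_mean is
initialised at the target P_mean,ao (exact for a lesion-free pair)
and updated additively, P_mean ← P_mean + ω·(P_mean,ao − P_pred),
ω = 1 by default; the loop stops when
|P_pred − P_mean,ao|/P_mean,ao < 0.01 (the 1 % threshold), with a
50-iteration cap. The additive rule was chosen as the simplest
monotone fixed-point update: P_pred is strictly increasing in P_mean
(raising every outlet resistance raises the inlet pressure), with
slope ≤ 1 on the fixtures tested, so the update converges without
relaxation. Requesting a P_mean below any branch's geometric drop
would produce a non-physical negative resistance and raises
immediately.

Identity property: for diseased ≡ reference, substituting the
converted resistances back into the same network reproduces the
prescribed flows and P_in = P_mean exactly, so the loop converges on
its first check with the empirical division — this parameter-recovery
case is asserted in the test suite at 1e−8 per branch.

## Windkessel tuning

From a division (estimated or empirical): one steady solve of the
diseased network at mean systolic inflow with the division prescribed
gives ΔP_i; the total outlet resistance is
R_i = (P_mean,ao − ΔP_i)/Q̄_i with Q̄_i = f_i·Q̄ the cycle-mean branch
flow (a mean-systolic basis is available behind a flag; cycle-mean is
the default since the Windkessel ground path carries the whole
cycle's flow). The split R_c = f_c·R_i, R_p = (1 − f_c)·R_i uses
f_c = 0.056, a characteristic-impedance share in the range reported
for aortic outlet fits; compliance follows a single global time
constant, C_i = τ/R_p,i with τ = 1.79 s, in the range of aortic
diastolic decay constants. Both are configuration knobs and are
recorded in the run manifest; no claim is made that they reproduce
any particular patient's compliance distribution.

## Transient solver

Backward Euler (first-order implicit), Δt = T/1000 by default, five
cycles, final cycle analysed. The Windkessel states are coupled
monolithically: the unknown vector per step is (nodal pressures,
capacitor pressures), with outlet law Q_i = (P_i − P_c,i)/R_c,i and
capacitor balance C_i(P_c^{n+1} − P_c^n)/Δt = Q_i^{n+1} −
P_c^{n+1}/R_p,i solved simultaneously by the same damped Newton.
Initial capacitor pressures come from the steady solve at cycle-mean
inflow through R_c + R_p, which removes most of the start-up
transient. The rigid 0D network stores no volume, so the inlet flow
equals the sum of outlet flows at every step to solver tolerance
(verified at 1e−9).

With the default τ = 1.79 s spanning roughly 2.6 cycles at 87 bpm, a
residual cycle-to-cycle inlet-pressure change of order 1 % remains
after five cycles; `periodicity()` reports it so the adequacy of the
five-cycle protocol can be checked per run.

The template inlet waveform is a documented analytic stand-in for
literature flow waveforms (which are published graphically): a
half-sine systole over the first third of the cycle, a reverse-flow
notch of 5 % amplitude over the next tenth, zero elsewhere; peak
400 mL·s⁻¹ gives a cycle mean of ≈ 83 mL·s⁻¹ (≈ 5 L·min⁻¹) and a mean
systolic flow of ≈ 250 mL·s⁻¹ at rest-like heart rates. It is scaled
to the patient's heart rate and optionally to a cardiac output.

## Metrics

All cycle integrals use trapezoidal quadrature on the given samples
(no resampling). TAWSS = (1/T)∫|τ|dt; OSI = ½(1 − |∫τdt|/∫|τ|dt),
clipped to [0, 0.5] against round-off; RRT is computed as
1/((1 − 2·OSI)·TAWSS) on the same quadrature so the three satisfy
their defining identity to machine precision, with +inf at OSI = 0.5
and NaN where OSI is undefined (identically zero shear) — undefined
points are flags, not exceptions, so field summaries stay computable.
AFI is the cosine between τ(t_obs) and the cycle-integral vector;
t_obs defaults to the instant of steepest inlet-flow deceleration
within systole ("mid-systolic deceleration" made operational; the
instant is overridable). Wall shear for 0D runs comes from the
Poiseuille profile, τ = 4μQ/(πr³), signed by flow direction, per
segment midpoint; temporal statistics conventionally use every tenth
timestep of the final cycle (`sample_every_tenth`).

LNH = v·(∇×v)/(|v||∇×v|) on uniform structured grids, curl by central
differences with second-order one-sided stencils at the boundary;
points with |v| or |∇×v| below 1e−12 are NaN. On a 64³ Beltrami (ABC)
field, where ∇×v = v exactly, the computed LNH is 1 within 5e−5.
TMP is the elementwise P_TL − P_FL at matched stations; zero
crossings of the station profile (linearly interpolated) are reported
as balance points.

## Synthetic anatomy

The healthy template is an abstract 12-branch aortic tree: a 10-
segment trunk (35 cm) whose radius tapers linearly from 1.5 cm
(ascending aorta) to 0.85 cm (aortic bifurcation), branches at fixed
stations (BT/LCC/LSA on the arch, CT/SMA/renals/IMA on the abdominal
trunk, external/internal iliacs off per-side common iliacs), each
branch two equal-radius segments at textbook-scale radii (BT 0.65 cm
… IMA 0.20 cm; full table in `anatomy.DEFAULT_BRANCH_MORPHOMETRY`).
Two choices are deliberate: the *linear* trunk taper makes the repair
rule (re-interpolation from flanking unaffected stations) exactly
inverse to the aneurysm and dissection lesions, and the *two-segment*
branches give every ostial segment an unaffected distal neighbour for
repair. Optional seeded lognormal jitter (σ = 0.03 in the cohort
generator) perturbs trunk scale and branch dimensions while
preserving both properties.

Dissection is modelled as parallel TL/FL resistor chains sharing the
original lumen area (FL area fraction default 0.55), cross-linked by
TEAR segments (radius 0.35 cm, length 0.2 cm ≈ flap thickness) at
specified stations; branches may be re-attached to FL nodes to model
false-lumen perfusion. The repair contraction factor defaults to 1.0
(no contraction) because no quantitative contraction rule exists;
it is configurable. Aneurysm repair is detection-based: runs of
radii exceeding the neighbour interpolation by a 5 % margin are
restored, mirroring "adjust from unaffected segments in the same
region" without hidden lesion markers.

What the synthetic anatomy does **not** emulate: real CTA-derived
lumen irregularity, curvature and 3D embedding, compliant walls and
flap motion, and patient-specific branch take-off variants. Tests
passing on these networks validate the *estimation machinery*
(conservation, monotonicity, identity recovery, steal direction), not
agreement with any patient's measured flows.

## Numerical choices and degenerate inputs

* Steady Newton: tol 1e−12 on relative nodal imbalance, max 100
  iterations, damping 0.7 for 5 iterations; singular Jacobians and
  non-convergence raise with the residual trace attached.
* Fractions are validated to sum to 1 within 1e−9; flow divisions are
  non-negative by construction.
* All-zero waveforms have no detectable systole and are rejected; a
  never-falling waveform treats the whole cycle as systolic.
* A dissection needs at least one tear inside the flap extent; a
  tear outside it is a validation error. An FL chain with a single
  tear is permitted (stagnant false lumen).
* Problem sizes in the test suite are chosen for desk-scale runs:
  the Δt-refinement check compares T/400 against T/800 over three
  cycles, and transient fixtures use 200–1000 steps/cycle; the
  protocol defaults (1,000 steps, 5 cycles) are used where the check
  depends on them (RC decay, metrics pipeline).

## Limitations

* 0D networks carry no secondary or recirculating flow, so OSI/RRT/
  AFI on Poiseuille-mapped shear are structurally tamer than wall
  maps from 3D CFD; the metric implementations are exact for their
  inputs, but those inputs undersell 3D disturbance.
* Windkessel parameters from steady solves neglect compliance during
  tuning; the transient mean inlet pressure therefore deviates
  slightly from the target (≈ 2 mmHg on the template fixture).
* The brachial-to-aortic conversion is an empirical population
  formula; its error enters the target directly.
* Venous reference pressure is assumed 0 mmHg and configurable; no
  autonomic regulation is modelled.
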