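# Methods

`gelshell` models a silicone gel breast implant as a closed axisymmetric
membrane shell filled with an incompressible, liquid-like gel.  This note
records the model, its assumptions, the numerical choices, and what the
synthetic data used in the test suite does and does not establish about
real implants.

## Model

### Geometry

An implant is represented by its meridian — the generating curve of the
surface of revolution — sampled from the apex on the symmetry axis, down
the dome side, across the flat base, back to the axis.  Reference
geometries are built from a printed radius R, height H and nominal volume V
using the superellipse dome family

    r(z) = R * (1 - (z/H)^p)^(1/p),   z in [0, H],

with a flat base.  The shape exponent `p` is solved (bisection) so that the
*discrete* frustum-quadrature volume of the sampled meridian equals V
exactly; radius and height are preserved exactly by construction.  `p = 2`
reproduces a hemisphere; the family spans volumes from near zero up to the
enclosing cylinder's, and an infeasible (R, H, V) triple raises an error
naming the achievable range.  A single exponent proved sufficient: the
volume is strictly monotone in `p`, so one degree of freedom pins the one
remaining constraint.

The four characterization sizes (200, 250, 400, 560 cc; radii
52.87/52.97/62.82/62.51 mm; heights 45.7/57.4/61.6/77.5 mm; shell
thickness 0.5 mm) are built this way.  The loading scenarios use a
representative 125 cc implant; its radius (42 mm) and height (35 mm)
follow the aspect-ratio trend of the four printed sizes, since no nominal
radius/height is published for that size, and its shell thickness varies
linearly from 0.4 mm at the apex to 0.6 mm at the base to represent a
non-uniform-thickness design.

### Constitutive model

The shell is incompressible neo-Hookean with a single coefficient
`C10` (kPa): `W = C10 (I1 - 3)` with `l3 = 1/(l1 l2)`.  The membrane
(plane-stress) closure gives principal Cauchy stresses
`sigma_i = 2 C10 (l_i^2 - 1/(l1^2 l2^2))` and the rupture-risk indicator
is the plane-stress von Mises equivalent
`sqrt(sigma1^2 - sigma1 sigma2 + sigma2^2)`.  The small-strain limit is
`E = 6 C10`, `nu = 1/2`; this identity is exercised in the tests.

The gel is far softer than the shell (its `C10` is bounded at 1/100 of the
shell's, enforced at construction).  Inside the solver it is treated as an
incompressible hydrostatic medium: it contributes its weight and an
enclosed-volume constraint, and stores no shear energy.  The gel `C10`
value (0.025 kPa by default) is retained for reporting and for the ratio
check only.  Gel density defaults to 9.7e-10 tonne/mm^3 (0.97 g/cm^3,
typical of cohesive silicone gel); no density is published for these
devices, and total implant mass is attributed to the gel.

The fat/muscle cover is linear elastic (E = 208 kPa, nu = 0.47) in the
published environment model; in the axisymmetric reduction used here it
enters only as a confinement pressure (below), so these constants are
carried in `MaterialSet` for configuration completeness.

Units are mm-N-MPa internally (densities tonne/mm^3, accelerations
mm/s^2); the API reports stresses and pressures in kPa, the natural scale
of this problem.

### Equilibrium

A deformed configuration minimizes the total potential energy

    Pi = int W(l1, l2) t_ref dA      membrane strain energy
       + int D/2 (dkappa)^2 dA       bending regularization
       + rho g_ax int z dV           gel weight
       + p_conf V_cov                tissue confinement work

subject to the enclosed-volume constraint `V = fraction * V_nominal`
(augmented Lagrangian; the converged multiplier is reported as the gel
pressure) and non-penetration of rigid obstacles — the ground plane, the
ribcage sphere (radius 97.5 mm), and a flat-bottomed indenter disc —
enforced by quadratic penalties whose stiffness is escalated until the
verified penetration is below 0.01 mm.

The bending term uses the physical plate modulus of the incompressible
sheet, `D = (2/3) C10 t^3`, acting on the change of discrete turning angle
relative to the reference meridian.  For a 0.5 mm shell this is ~500x
smaller than the membrane stiffness; it regularizes mesh-scale wrinkling
without affecting the (T, R) summaries at the reported precision.

The confinement pressure represents the fat/muscle cover.  It acts on a
*fixed material region* of the shell — the meridian arc from the apex down
to a configurable cover fraction (default 0.35), smoothly tapered over 5%
of the arc.  An earlier formulation applied the pressure to whatever
surface was currently out of contact; that made the energy landscape
discontinuous along quasi-static sweeps and produced spurious branch
jumps, so the material-region form is used.  The default pressure
(0.5 kPa) together with the default cover fraction was calibrated once so
that the wrapped implant's height reduction in the resting state is 5-15%,
and then left fixed.

### Numerics

Unknowns are the deformed meridian coordinates (~2N for N samples; the two
on-axis points keep r = 0).  Each inner minimization runs a coarse
L-BFGS-B phase (analytic gradients throughout) followed by damped Newton:
the Hessian of the local energy terms is banded in an interleaved node
ordering and is assembled by colored finite differences of the analytic
gradient (11 gradient evaluations), plus the analytic rank-one
augmented-Lagrangian term.  Newton converges the projected gradient to
1e-7 of the force scale `C10 t R`; warm-started steps take ~10-20 ms at
N = 64.

Cold starts probe three deterministic initializations (the reference shape
and two axially squashed copies) and keep the lowest-energy basin: the
landscape holds a near-reference local minimum separated from the physical
settled branch by a dome snap-through barrier, and on finer meshes plain
descent from the reference gets trapped on the wrong side.  With the
basin probe the 200 cc resting summaries change by <0.2% between 64 and
128 samples.

The volume constraint is driven to 1e-9 relative violation.  That is far
tighter than any physical claim; it is what makes warm-started sweeps
hysteresis-free (detached compression phases reproduce the resting stress
to ~3e-8 kPa) and the characterization objective smooth at the 1e-4 mm
scale the optimizer needs.  All solves are deterministic: no random
initialization anywhere, and quasi-static sweeps warm-start from the
previous step.

Degenerate inputs: stretches are floored at 1e-6 (the neo-Hookean energy
is a natural barrier against collapse), zero-length segments are rejected
at profile construction, and a non-convergent solve raises an error
carrying the last iterate.  The meridian may be supplied apex-first or
base-first; the solver orients the signed volume internally and the two
directions agree to 1e-14 mm.

## Inverse characterization

The flat-resting forward simulation (ground plane, full gravity, no
confinement) maps a property vector `x = (C10, fraction_1..fraction_n)` to
per-size height/width summaries `(T_i, R_i)`: T is the maximum height above
the support plane, R the maximum radial extent from the axis (half the
overall width — the radial convention is assumed, as the printed widths'
convention is not stated).  The objective is the weighted absolute
mismatch summed over sizes,

    f(x) = sum_i [ w_T |T_i(x) - That_i| + w_R |R_i(x) - Rhat_i| ],

with default weights w_T = w_R = 1 per mm (no weight values are published;
equal weighting is the neutral choice and both are configurable).

Minimization is bounded Nelder-Mead on scaled variables (C10/100 and the
raw fractions) with up to three deterministic restarts, each rebuilding a
4x smaller simplex around the incumbent.  The restarts matter: C10 and the
fractions partly compensate (a stiffer shell with less fill produces
nearly the same summaries), leaving a valley where f changes by only
~0.005 mm per 2% of C10.  A plain simplex stalls there at ~3% stiffness
error; the restarted search with tight tolerances (fatol 1e-4 mm,
xatol 2e-4) recovers noise-free synthetic parameters to <0.01%.  Forward
solves warm-start per size along the search path, so a full four-size
characterization (~4000 solves) runs in a few minutes on one core.

The same valley geometry limits noise robustness: the summaries move only
~0.02 mm per kPa of C10, so millimetre-scale summary errors translate into
tens of percent of stiffness uncertainty.  The test suite therefore checks
10% recovery at 0.1 mm summary noise — the accuracy class of a
structured-light scanner — and not at larger noise, where the parameter is
genuinely unidentifiable from two summaries per size.

## Gait processing and walking loads

Vertical chest-marker trajectories are reduced to a single harmonic: the
signal is de-meaned, the largest non-DC bin of the magnitude spectrum is
taken, its location is refined first by 3-point quadratic interpolation
and then by directly minimizing the least-squares residual of a
cos/sin fit over frequency within +-0.6 bin, and the amplitude is the
fitted quadrature norm.  On-bin frequencies are recovered exactly (the
exact-bin fit is kept whenever it matches the refined fit's residual);
off-bin presets round-trip to <0.15% and a flat spectrum (peak-to-median
ratio < 3) raises a "no dominant component" error.  The estimated phase is
discarded: the walking displacement is the pure cosine
`Dy = A cos(2 pi t / T)` with `Dx = v t`, per the published loading form.

Three presets (slow/medium/fast) carry the published walking conditions:
v = 240/549/986 mm/s, A = 6.385/11.070/17.313 mm, T = 1.474/0.851/0.609 s.
The synthetic gait generator emulates the source data as the fundamental
plus harmonics decaying as A/3^k plus white noise.

Walking loads the implant as an effective axial gravity: prescribing the
support motion Dy(t) is equivalent, in the implant frame, to
`g_eff(t) = g + (2 pi/T)^2 A cos(2 pi t/T)`; the uniform forward velocity
contributes no acceleration and is carried as metadata.  The 15 deg
standing tilt of the implant axis enters as the axial component
`sin(15 deg)` of every vertical acceleration — the transverse component
cannot be represented axisymmetrically and is a documented limitation.

## Loading scenarios

Both scenarios first settle the implant on the ribcage sphere under
gravity and confinement (Stage 1).  Compression then drives the indenter
(radius 45 mm disc; only its bottom face can contact in the working range)
with raised-cosine travel of `standoff + depth_max` = 20 mm peak: the
printed protocol fixes both the 10 mm standoff and the 10 mm maximum
depth, which a zero-mean sinusoid cannot satisfy simultaneously, so the
raised-cosine form preserving both printed facts is used.  The device is
farthest at t0 = 0 and deepest at t2 = half period; t1 marks the midpoint
of the descending contact phase.  Since the confinement model carries no
stress state of its own, the published re-referencing between stages
(zeroing residual tissue stress while keeping the implant state) is
automatic here: shell stresses are always measured from the implant's own
reference shape.

Stress histories are recorded at tracked material points — arc-length
fractions of the reference meridian, linearly interpolated.  Defaults:
0.33 (the front-side ring where indentation concentrates stress), 0.70
(rear side facing the ribcage), 0.95 (bottom region, the walking
hot spot).  Under indentation the front ring stress overtakes the rear
point after being lower at shallow depth, reproducing the front/rear
crossover reported for the compression protocol; under walking the
fluctuation amplitude grows strictly with speed, tracking the inertial
amplitude `(2 pi/T)^2 A` (ratios ~1 : 4.5 : 11 across the presets).

Quasi-static sweeps use 32 steps per cycle by default (16 in the lighter
test configurations); halving the step changes peak stresses by <1%.
Failed steps retry through up-to-8-fold halved increments before raising.

## What the synthetic data shows — and does not

The synthetic scans are forward simulations of this same model plus
optional vertex noise, and the synthetic gait is the single-harmonic form
plus harmonics and noise.  Closed-loop tests on them establish that the
inverse machinery is correct and well-conditioned under the model's own
assumptions (an inverse-crime design, used deliberately).  They do not
validate the membrane model against real implants: real shells ripple and
wrinkle (no axisymmetric membrane can), real scans carry alignment and
segmentation error beyond vertex noise, and the absolute stress levels of
a full 3D continuum model with a meshed tissue cover are not reproduced by
this reduction — the published peak values (~0.06 MPa compression,
~0.04 MPa walking) additionally depend on unpublished densities and
tissue calibration, so only the qualitative stress orderings and
locations are asserted here.  Within the model, the compression peak at
the contact ring (~0.03-0.05 MPa for the 125 cc implant) lands in the
same order of magnitude.

## Known limitations

- No bending-dominated phenomena: rippling, wrinkling and fold contact are
  outside the model; the bending term is a regularizer, not a shell theory.
- Axisymmetry: oblique resting, half-symmetric 3D contact and the
  transverse gravity component are not representable; the tilt enters only
  through the axial projection.
- The tissue cover is a pressure field, not an elastic body: its stiffness
  constants are carried but only the calibrated pressure acts.
- The gel is elastic-equivalent and massless apart from weight: no
  viscosity, no sloshing, no rate effects; walking inertia is rigid-frame
  only.
- Fractions near the lower bound (< ~0.8 at full gravity) approach the
  regime where a real shell would fold; the membrane solution there is
  smooth by construction and increasingly artificial.
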