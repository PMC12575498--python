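# gelshell

Mechanics of silicone gel breast implant shells: inverse material
characterization from 3D-scan shape summaries, and quasi-static stress
analysis of the shell under compression and walking loads.

Silicone gel implants fail by shell rupture, typically after years of
fatigue accumulation in regions of concentrated stress.  Predicting where
those regions are requires (i) material parameters for the shell and gel —
which cannot both be measured directly, because the gel is untestable in
specimen form — and (ii) simulations of the implant inside a simplified
anatomical environment under everyday loads.  `gelshell` implements both
steps for an axisymmetric membrane model of the implant, small enough to
run on a laptop yet faithful enough to reproduce the qualitative stress
behavior of full 3D finite-element studies.

## Model and method

An implant is a closed axisymmetric shell (meridian from apex to base)
filled with gel.  The shell is an incompressible neo-Hookean membrane,
W = C10 (I₁ − 3) with λ₃ = 1/(λ₁λ₂); the gel is an incompressible
hydrostatic medium that fixes the enclosed volume V = fraction × V_nominal
and contributes its weight.  Equilibrium minimizes the total potential
energy under rigid-obstacle contact (ground plane, ribcage sphere of
radius 97.5 mm, indenter disc), with the volume constraint handled by an
augmented Lagrangian whose multiplier is the gel pressure.  Shell stress
is reported as the plane-stress von Mises equivalent
√(σ₁² − σ₁σ₂ + σ₂²), with σᵢ = 2 C10 (λᵢ² − 1/(λ₁²λ₂²)).

**Characterization.**  Given scanned flat-resting shapes of several
implant sizes, reduced to height/width summaries (T̂ᵢ, R̂ᵢ), the property
vector x = (C10, fraction₁…fractionₙ) is found by bounded, restarted
Nelder-Mead minimization of the weighted absolute mismatch

f(x) = Σᵢ [ w_T |Tᵢ(x) − T̂ᵢ| + w_R |Rᵢ(x) − R̂ᵢ| ],

where each evaluation runs the forward equilibrium solver per size.

**Loading scenarios.**  Compression: a 45 mm rigid disc indents the
ribcage-mounted, tissue-confined implant with raised-cosine travel
(10 mm standoff, 10 mm maximum depth), alternating contact and
detachment.  Walking: the vertical gait harmonic Dy = A cos(2πt/T)
(extracted from marker trajectories by FFT peak + least-squares fit)
loads the implant as an effective gravity g + (2π/T)² A cos(2πt/T).
Both are warm-started quasi-static sweeps recording von Mises histories
at tracked material points.

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

The 200 cc implant (radius 52.87 mm, height 45.7 mm, shell 0.5 mm)
resting flat under gravity, with the characterized shell coefficient and
its reported gel volume fraction:

```python
from gelshell import (
    GelFill, MaterialSet, ObstacleSet, Plane,
    build_reference_profile, solve_equilibrium,
)

profile = build_reference_profile(52.87, 45.7, 200_000.0, implant_id="200cc")
state = solve_equilibrium(
    profile,
    MaterialSet(C10_shell=100.702),                      # kPa
    GelFill(volume_fraction=0.930, nominal_volume=200_000.0),
    ObstacleSet([Plane(0.0)]),                           # ground plane
)
T, R = state.summary()
print(f"deformed height T = {T:.2f} mm (undeformed 45.70 mm)")
print(f"deformed width  R = {R:.2f} mm (undeformed 52.87 mm)")
print(f"gel pressure      = {state.gel_pressure:.3f} kPa")
```

prints

```
deformed height T = 31.24 mm (undeformed 45.70 mm)
deformed width  R = 52.76 mm (undeformed 52.87 mm)
gel pressure      = 0.251 kPa
```

The implant slumps by about a third of its height while the enclosed
volume is conserved to 10⁻⁹ relative; the 0.25 kPa gel pressure is the
hydrostatic scale ρg·height.  These (T, R) pairs, one per size, are
exactly what the characterization loop matches against scan summaries:

```python
from gelshell import ForwardModel, ObjectiveSpec, PropertyVector, characterize

forward = ForwardModel([profile])
scans = forward.simulate(PropertyVector(100.702, [0.930]))   # or from STL scans
result = characterize(scans, ObjectiveSpec(),
                      PropertyVector(91.547, [0.9]), forward=ForwardModel([profile]))
print(result.x_star.C10_shell)    # -> 100.70... (recovered from 91.547 start)
```

A command-line interface wraps the same functionality:

```sh
gelshell synth-scan --size 200cc --fraction 0.93 --out scans/200cc.stl
gelshell characterize --scans scans/ --out report.json
gelshell compress --out results/compress
gelshell walk --speed fast --duration 5 --out results/walk
```

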