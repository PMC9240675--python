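# Model and numerical methods

`peeldyn` simulates the forced peeling of two identical vesicles held
together by an adhesion patch of mobile, transient molecular bonds.
The membranes are fluid, so decohesion can proceed by *moving* bonds
(lateral transport), by *breaking* them (reactions), or both; which
channel dominates is set by the ratio of diffusive and reaction time
scales.  This note records the model equations as implemented, the
default parameters and why, every consequential numerical choice, and
the known limitations.

## Geometry and mechanical model

The system is two-dimensional: each membrane is a line (arc-length
coordinate `s`), made a ribbon of depth `ℓ_lat` so that areal number
densities map to line densities (`ℓ_lat = 1 μm` by default, making the
mapping numerically trivial).  By symmetry only one half-vesicle is
simulated: the adhesion patch occupies `s ∈ [0, ŝ(t)]`, the free
membrane continues to the loading device.

**Vesicle scale (capillary limit).**  At the tensions of a mature
patch, the bending length `ℓ1 = √(κ/γ) ≈ 20 nm` is far below the
vesicle size, so the free contour is a circular arc (uniform tension γ
and Laplace pressure `P = γ/R` imply constant curvature).  The closure
used here: the arc leaves the patch edge `(ŝ, 0)` at the contact angle
θ and meets the symmetry axis at the load apex with tangent angle β,
where the device force balance of the two membrane leaves gives
`F = 2γ·sinβ`.  The enclosed area is held at its prepared value `A0`
(circle of radius `R0` truncated by the patch chord), which closes the
problem: θ is the unique root of the area equation in `(β, π/2)`,
found by bracketed `brentq` to `1e-13` in θ.  At `F = 0` this reduces
to `sinθ = ŝ/R` exactly.  A constant-θ mode bypasses the solve to
reproduce the assumptions of the analytic similarity and
travelling-front solutions; in that mode the pressure is taken as
`P = γ/R` with `R = ŝ/(sinθ − sinβ)` (its effect on the nanometric
contact layer is negligible: the interior indentation is
`P/(k·c1) ≲ 0.03 nm`).

**Patch scale (micro-mechanics).**  The separation `h(x)` of the
membrane from the unstressed bond length minimizes

    F[h] = γ∫√(1+h'²) + (κ/2)∫ h''²/(1+h'²)^{5/2}
           + ∫₀^ŝ (k c1/2) h² + ∫₀^ŝ P h − γ sinθ h(αŝ),

on `[0, αŝ]` (`α = 1.3`; results are insensitive to α, enforced by a
regression test at α = 1.5).  The default solver is the small-slope
stationarity ODE `κh⁗ − γh″ + k c1 h·𝟙[x≤ŝ] = −P·𝟙[x≤ŝ]` with symmetry
(`h' = h''' = 0`) at `x = 0` and free-end conditions (`h'' = 0`,
`κh''' − γh' = −γ sinθ`) at `x = αŝ`, discretized with cubic-Hermite
finite elements (nodal `h` and `h'`, 4-point Gauss per element, banded
Cholesky).  The grid is graded so the boundary layer
`ℓ2 = [4κ/(k c1)]^{1/4} ≈ 25 nm` carries ≥ 10 nodes.  The small-slope
form is the production path because separations are a few
`xγ = √(kBT/k) ≈ 4 nm` over `ℓ2`-scale distances; the full nonlinear
functional (exact metric and curvature) is retained as a damped-Newton
verification mode and agrees with the linear solve to < 1% whenever
`max|h'| < 0.1`.  The symmetry condition is imposed by exact
elimination of the `h'(0)` degree of freedom.  Sign convention:
`h > 0` means a stretched bond; `P > 0` presses the membrane onto the
bonds.

## Thermodynamics and kinetics

Dilute chemical potentials (bond μ1 on the patch, free binder μ2 on
the whole vesicle):

    μ1 = μ1⁰ + kBT ln(c1/c0) + kBT (h/xγ)²,   μ2 = μ2⁰ + kBT ln(c2/c0),

with `μ1⁰ = 0` and `μ2⁰ = (kBT ln K̄)/2` so that chemical equilibrium
`μ1 = 2μ2` reproduces the mass action `K̄ = c0 c1/c2²`.  Rates:
`kon(h) = k̄on·exp[−(h/xγ)²]` (partner proximity under thermal
fluctuations) and the Bell slip-bond law `koff(h) = k̄off·exp(h/xβ)`
with `xβ = fβ/k`, signed (compression slows unbinding); ideal bonds
have `fβ = ∞`.  `k̄on` is always derived from `K̄ = c0·k̄on/k̄off`.
The bond osmotic tension is `Π = kBT·c1` (van't Hoff).

**Crowding (Flory–Huggins lattice, saturation `cmax`).**  The bond
potential gains `−2kBT·ln v` with vacancy fraction
`v = (cmax − c1 − c2)/cmax`, and the osmotic tension becomes
`Π = −kBT(2cmax·ln[(cmax−c1)/cmax] + c1)`, which diverges at
saturation and reduces to van't Hoff for `c1 ≪ cmax`.  The
concentration term of μ1 is logarithmic — the unique choice consistent
with this Π through the Gibbs–Duhem relation (enforced by a property
test integrating `c·∂μ1/∂c` numerically to 1e-8).

Two crowding variants are implemented, switched by `mu2_vacancy`:

* default (`mu2_vacancy = False`): μ2 stays ideal, so the reaction
  affinity `μ1 − 2μ2` grows by `−2kBT ln v` under crowding, and the
  matching Boltzmann factor `v⁻²` multiplies the off-rate.  A crowded
  patch therefore unbinds faster — the mechanism by which crowding
  weakens adhesion and lowers the patch strength.  This is the
  production choice: with the cancelling alternative the crowded
  equilibrium is concentration-for-concentration identical to the
  dilute one and the force balance is *easier* to satisfy (Π ≥ kBT·c1),
  i.e. crowding would strengthen the patch, contrary to what the
  crowded model exists to capture.
* `mu2_vacancy = True`: μ2 carries a single-site vacancy term; the
  vacancy contributions then cancel in the affinity and bonds keep
  plain mass-action kinetics (crowding acts through transport and the
  edge force balance only).

In both variants the *transport* of free binders in crowding mode
includes the single-site vacancy drift: the Flory–Huggins mobility
couples every species to the volume constraint, so unbinding debris is
pushed out of nearly saturated zones.  (Without this cross-effect the
debris accumulates at the peeling edge, drives `v → 0`, and the
unbinding factor blows up in finite time.)  The `v⁻²` factor is
clipped at `v = 0.01` (≤ 10⁴·k̄off), purely to bound stiffness while a
step iterates through transiently saturated states.

## Transport on the moving patch

    ∂t c1 = D1 [c1' + c1 ((h/xγ)²)']' + kon c2² − koff c1   on (0, ŝ(t)),
    ∂t c2 = D2 c2'' − kon c2² + koff c1                      on (0, ŝ(t)),
    ∂t c2 = D2 c2''                                          on (ŝ(t), L0),

with `D2 = 2 D1` by default (a bond ties one binder of each membrane,
so its mobility is half a binder's).  Free binders cross the patch
edge (concentration and flux continuous); bonds cannot, so the
diffusive+drift bond flux at the edge is carried entirely by edge
motion:

    −D1{c1' + c1[(h/xγ)²]'}|ŝ = c1(ŝ)·v̂,     v̂ = dŝ/dt,

and the edge force balance sets the bond concentration there:

    Π(c1(ŝ)) = 2γ(1 − cosθ)    (kBT·c1(ŝ) = 2γ(1−cosθ) when dilute).

Zero species flux at `s = 0` (symmetry) and `s = L0`.  The membrane
length `L0` is fixed for transport even though the device exchanges
membrane with a reservoir; reservoir membrane carries no binders, so
the total binder number is `Ntot = c0·L0`.

## Discretization

* **Front fixing.**  The patch maps to `ξ = s/ŝ(t) ∈ [0,1]`, the outer
  region to `η = (s−ŝ)/(L0−ŝ)`; both grids are graded geometrically
  (ratio 1.2) toward the edge with minimum spacing
  `min(ℓ2/10, ℓ3/4)` (compliant / reacting runs) or `ŝ0/2000` (purely
  diffusive runs), where `ℓ3 = √(D1/k̄off)` is the reaction–diffusion
  process zone.
* **Finite volumes, Scharfetter–Gummel.**  Vertex-centred conservative
  volumes with exponentially fitted edge fluxes whose drift potential
  collects the stretching bias `(h/xγ)²`, the crowding vacancy terms,
  and the ALE mesh-motion advection.  This is positivity-preserving
  and reduces to central differencing for pure diffusion.
* **Conservative interface treatment.**  The zero-relative-bond-flux
  condition is imposed exactly on the edge control volume, and v̂ is
  the scalar unknown of a secant iteration (bisection fallback, both
  search directions) that drives the edge node onto the force-balance
  value.  The target is evaluated at the *end-of-step* patch size
  inside the iteration, so an accepted step lands exactly on its own
  target and the next step starts mismatch-free — otherwise a sharp dt
  reduction would demand a diverging bridging velocity.  Bond number
  is then conserved to machine precision when reactions are off, and
  total binder number to machine precision in every mode (the same
  per-cell reaction integral is applied with opposite signs to c1 and
  c2).
* **Time stepping.**  Backward Euler; unbinding implicit, binding
  (`kon c2²`) explicit in c1 and the exchanged integral explicit in
  c2.  In crowding mode the vacancy drift and the `v⁻²` unbinding sink
  are fully implicit in the solved field via a damped tridiagonal
  Newton iteration; cross-species and quasi-static-mechanics couplings
  are refreshed by 2–3 Picard sweeps per step.  Adaptive dt limited by
  (a) interface CFL `|v̂|·dt < 0.2·Δs_min`, (b) a reaction-resolution
  cap `dt ≤ fr/max(koff_eff)` (`fr = 0.2` by default; the long mixed
  and crowded runs use `fr = 1`, leaning on the error control), and
  (c) step-doubling error control with a volume-weighted RMS norm at
  relative tolerance 1e-5 (3e-5–3e-4 in the scaled presets).  The
  weighted norm lets the nanometric process-zone cells carry their
  share of the error rather than a max-norm veto.  Negative
  concentrations or saturation overflow reject the step and halve dt.
* **Quasi-statics.**  Shape and separation profile are recomputed from
  the current `(ŝ, c1)` at each step (and at the half-step midpoint of
  the error estimator).
* **Impulsive starts.**  A force-schedule jump makes the edge value
  jump discontinuously; the continuum solution has a zero-width
  concentration jump at the edge at `t = 0⁺`, which is applied
  directly to the interface node before integrating (measure-zero in
  the continuum; one half-cell of mass discretely, accounted before
  any conservation bookkeeping).
* **Compliant preparation.**  The non-compliant equilibrium is not an
  equilibrium for compliant bonds (edge stretching raises μ1), so
  compliant runs first relax at `F = 0` until
  `max|dc1/dt| < 1e-6·c0/τdiff,1`, with a loosened path tolerance
  (only the fixed point matters).  Constant-θ runs skip relaxation:
  their long-time travelling/similarity behaviour is independent of
  the initial transient.

## Prepared equilibrium and parameters

Closed form: with `x = c2/c0`, mass action plus binder conservation
give `K̄ ŝ0 x² + L0 x − L0 = 0`, hence `c1 = 1.575 c0`,
`c2 = 0.887 c0` at the defaults; `θ0 = arcsin(ŝ0/R0)` and
`γ = Π(c1)/[2(1−cosθ0)]` (crowded Π in crowding mode, so the prepared
state satisfies the same force balance that will be integrated).

Defaults (the reference study conditions): `kBT = 4.11e-21 J`,
`κ = 1e-19 J`, `k = 2.5e-4 N/m`, `K̄ = 2`, `c0 = 2.5e3 μm⁻²`,
`R0 = 10 μm`, `ŝ0 = 2.5 μm`, `L0 = 35 μm`, `k̄off = 10 s⁻¹`,
`D2 = 2D1 = 0.5 μm²/s` (mobile regimes) or `0.5e-3 μm²/s`
(cytoskeleton-limited regime), `fβ = 4·fγ` for the slip-bond runs with
`fγ = √(k·kBT) ≈ 1.0 pN`.  Internally all numerics run in
(μm, s, pN, pN·μm = 1e-18 J): every model quantity is then within a
few orders of magnitude of unity, which keeps the FEM/FV assemblies
well conditioned; the public API accepts the conventional mixed units
above.

## Regime presets and scaled-down problem sizes

The bundled drivers reproduce the three regimes at problem sizes
chosen for a single CPU; the full-resolution settings are available
via `scaled=False`.

* **Diffusion-dominated** (`k̄on = k̄off = 0`): constant-θ runs at
  U ∈ {1.5, 2, 3} to τ = 0.05 on the default graded grid; the
  simulated interface matches `ŝ0(1+2λ√τ)` to ≲ 0.03% and the rescaled
  bond profiles collapse on the similarity solution to ≲ 0.3% — well
  inside the 2%/3% documented bounds.
* **Reaction-dominated** (`D1 = 0.25e-3 μm²/s`, `k̄off = 10 s⁻¹`,
  compliant slip bonds): constant-θ runs of 4 s develop travelling
  fronts (trailing-window R² > 0.999) with speeds a factor ~2–4 of
  `v0 = √(D1 k̄off) = 50 nm/s`, increasing with sinθ and with
  decreasing fβ/fγ.
* **Mixed** (`D1 = 0.25 μm²/s`, `k̄off = 10 s⁻¹`, compliant ideal
  bonds): the scaled failure-time sweep uses six forces on a geometric
  ladder (ratio 1.08) above the estimated threshold `Fc ≈ 0.36·γ` of
  this model variant, grid spacing `ℓ2/6` at the edge, horizon
  `120·τdiff,1`.  The measured lifetimes span 21–386 s and fit
  `t_fail ∝ (F−Fc)^a` with `a ≈ −2.4`.
* **Crowding** (mixed parameters, ideal bonds, `F/γ = 0.3`,
  `cmax/c0 ∈ {5, 20, 500}`): the scaled preset uses non-compliant
  bonds — compliance is orthogonal to the saturation physics and its
  relaxation stage dominates the cost.  `cmax = 5c0` fails in ≈ 134 s
  while `cmax = 500c0` (near-dilute) survives the horizon, and the
  patch shrinkage at fixed early time is ordered monotonically in
  crowding.

## What the simulations do and do not represent

The model is a mechanistic idealization, not a data generator: a 2D
ribbon geometry; membranes without thermal undulations (appropriate at
high tension, not during low-tension spreading); quasi-static
mechanics; slip or ideal bonds only (no catch or switching behaviour);
no cytoskeleton coupling, endocytic turnover, inactive crowders or
hydraulic effects; a membrane reservoir that carries no binders.
Passing tests demonstrate internal consistency with the governing
equations and their analytic limits — they do not validate the model
against any experimental peeling data.

## Numerical tolerances and degenerate inputs

λ(U) residual < 1e-12 on U ∈ (0, 50] (bisection + Newton, `erfc`
formulation to avoid cancellation); θ solve `xtol 1e-13`; crowded edge
concentration by `brentq` to machine relative tolerance; v̂ secant to
1e-10 of the target concentration; vacancy Newton residual 1e-12
relative.  Degenerate inputs fail loudly: non-positive constants name
the offending field, `c1 ≡ 0` with `γ = 0` is a singular stiffness,
`c1(ŝ) = 0` makes the interface velocity undefined, concentrations at
`cmax` are a hard error in the potentials.  `μ(c=0)` returns −∞ as a
sentinel and is never fed to arithmetic.

## Known limitations

* The exact force→shape map of the loading device is a reconstruction
  (single circular arc, apex attachment, `F = 2γ sinβ`); all
  quantitative comparisons avoid depending on it (they use `F = 0`
  limits, closed formulas, or constant-θ mode).  Consequently the
  patch strength of this implementation (`Fc ≈ 0.36·γ` for the mixed
  preset) need not coincide with other realizations of the same
  physics, and force ladders are expressed relative to the measured
  threshold.
* `t_fail` is defined by the first crossing of
  `ŝ_min = max(5ℓ2, 0.01·ŝ0)`.  Because the terminal phase of failure
  decelerates (the last concentrated bonds bleed off by reactions),
  the failure time carries a definitional sensitivity: halving `ŝ_min`
  lengthens lifetimes by tens of percent near threshold and moves the
  fitted exponent by a few tenths.  `experiments.s_min_sensitivity`
  quantifies this per configuration; strength exponents should always
  be quoted together with the threshold convention.
* Bell slip-bond kinetics deliberately break detailed balance under
  load (the separation-dependent equilibrium constant
  `K(h) = K̄·e^{−(h/xγ)²}` is a statement about `kon`, not `koff`);
  the package keeps the kinetic and equilibrium statements separate,
  as is standard.
* Non-compliant dynamics are not the `k → ∞` limit of compliant
  dynamics (both `h` and `xγ` vanish in that limit while their ratio
  does not); the two modes are independent and first-class.
* The travelling-front and crowding observables are order-of-magnitude
  and ordering statements by construction; only the diffusion-regime
  similarity quantities and the closed-form preparation are
  percent-level.
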