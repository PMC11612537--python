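# Methods

## Model

The community consists of a basal resource with semi-chemostat renewal
`dR/dt = ρ(K − R) − ingestion`, a consumer population structured by body
length `l`, and an unstructured predator biomass `P`. Consumers are born
at `lb = 7 mm`, become invulnerable to predation at `lv_T` (27 mm at the
20 °C reference), mature at `lmat_T` (110 mm) and approach the
food-limited asymptote `l_max = l∞_T · σ(R)` with `σ(R) = R/(Rh+R)` and
`l∞ = 300 mm`. Ingestion and fecundity scale with `l²·σ(R)`; growth is
von Bertalanffy in the scaled resource; background mortality `μ_C` is
size-independent; the predator feeds on the vulnerable biomass
`Cv = ∫ ω l³ c(t,l) dl` (integrated up to `lv_T`) through a Holling
type-II response `f(Cv) = f_T·a·Cv/(1+ahCv)` and converts intake with
efficiency ε against a biomass loss rate `μ_P`.

Predation mortality of vulnerable consumers is implemented as
`p = f_T·a·P/(1+ahCv)`, the unique per-capita rate consistent with mass
balance: the predator's biomass gain `ε·f(Cv)·P` then equals ε times the
vulnerable biomass removed. `p` is treated as a free environmental input
inside the life-history layer, which linearises the whole equilibrium
problem (see below).

## Temperature dependence

Three mechanisms, each switchable per species (scenario definitions 1–12):

* **Thermal performance curves** — the rate constants `I_T, G_T, B_T`
  (consumer) and `f_T` (predator) are the 20 °C reference values times
  the Rosso factor `(T−Tmin)(T−Tmax) / [(T−Tmin)(T−Tmax) − (T−Topt)²]`,
  clamped to zero outside (Tmin, Tmax) = (5, 25) °C and equal to 1 at
  Topt = 20 °C. The curve is evaluated exactly in this printed form; it
  is already left-skewed for the default niche.
* **Loss rates** — `μ_C` and `μ_P` equal
  `μ0·(1 + exp(|E|·(T−Topt)/(k(T+T0)(Topt+T0))))` with `μ0 = 5·10⁻³
  day⁻¹` and `|E| = 0.55 eV`: exactly `2μ0` at the optimum (matching the
  temperature-independent variant) and strictly increasing in `T`. The
  printed source formula is typographically ambiguous in its sign; the
  implemented orientation is forced jointly by the `2μ0` anchor and the
  stated exponential *increase* of losses with temperature. The opposite
  orientation is incompatible with the reproduced mismatch boundaries
  (it kills warm-shifted consumers through inflated mortality) but would
  move the lower bistability boundary from ≈7.4 °C to ≈10 °C — the one
  published number this implementation does not reproduce (see
  Limitations).
* **Temperature–size rule** — size thresholds scale as
  `l_i,T = l_i·exp(β(T−T_ref)/3)` with `β = −0.05 °C⁻¹` (a 5 %·°C⁻¹ mass
  reduction converted to length via `w ∝ l³`). `T_ref = 20 °C` by
  default, including under niche shifts; `tsr_reference="optimum"`
  instead anchors each species' sizes at its own (shifted) optimum.
  Both conventions give identical results without shifts.

Thermal-niche mismatch shifts one species' (Tmin, Topt, Tmax) uniformly
by ΔTPC; the shifted optimum is also used inside that species' loss-rate
exponent. TSR pushing the size ordering out of
`lb < lv_T < lmat_T < l∞_T` raises an explicit degenerate-configuration
warning (unreachable with default parameters inside the niche).

## Closed-form life history

At fixed `(R̃, p, T)` the length-at-age curve is
`l(a) = l_max + (lb − l_max)e^{−G_T a}`, stage-transition ages follow by
inversion (infinite when the asymptote lies below a threshold), and
survival is piecewise exponential with rates `μ_C + p` before and `μ_C`
after the vulnerability age `a_v`. Because `l(a)ⁿ` expands into
`e^{−kG_T a}` terms, the lifetime reproductive success
`R0 = ∫_{a_mat}^∞ B_T l² σ S da`, the lifetime ingestion `θ_I` and the
time-integrated stage biomasses `θ_v, θ_j, θ_a` are finite sums of
exponential integrals — evaluated exactly, with no quadrature error. An
independent adaptive-quadrature path (`method="quadrature"`, truncated
where survival falls 10¹⁶-fold below its value at the interval start)
reproduces every integral to better than 10⁻⁸ relative and serves as the
oracle in the test suite.

## Equilibria and thresholds

* `K_C(T)`: the resource density solving `R0(R̃, 0) = 1`; at consumer
  invasion the resource sits at carrying capacity, so the threshold is
  exactly this root. `R0` is strictly increasing in `R̃`, so bracketed
  bisection (relative tolerance 10⁻¹²) is globally convergent.
* CR equilibrium: `R̃` as above (independent of K), birth-rate flux
  `b = ρ(K − R̃)/θ_I`, stage biomasses `b·θ_*`.
* `K_P(T)`: the predator's break-even vulnerable biomass is the closed
  form `Cv* = μ_P/(a(εf_T − hμ_P))`; since `Cv` is linear in `K` along
  the CR branch, `K_P = R̃ + Cv*·θ_I/(ρθ_v)`.
* Trophic-chain branch: parameterised by predation pressure `p` rather
  than arclength — the predator balance pins `Cv = Cv*`, leaving one
  scalar root `R̃(p)` from `R0(R̃, p) = 1`, after which
  `b = Cv*/θ_v`, `P = p(1+ahCv*)/(f_T a)` and the supporting
  productivity `K(p) = R̃ + bθ_I/ρ` are explicit. `K(0) = K_P`
  identically.
* `K_A(T)`: the fold of the branch, `min_p K(p)`, located by a 60-point
  log-spaced scan over `p ∈ [10⁻⁴, 10²] day⁻¹` plus bounded scalar
  minimisation in `log p`; `K_A = K_P` when the branch leaves the
  invasion point non-decreasing (no Allee effect).

Stability labels are structural, not spectral: the CR state is invadable
above `K_P`, and branch points on the low-`p` side of the fold are the
saddles. Thresholds that do not exist are encoded as `+inf`; sweeps
declare non-existence relative to a productivity ceiling
`K_max = 10⁻² g·L⁻¹` (20× the default K).

Mismatch sweeps use a 0.1 °C shift grid with bisection refinement of all
boundary shifts to 0.01 °C. For predator sweeps the existence boundary is
also available analytically (`ΔTPC = T_env − Tmax`) and the sweep
verifies its detection against it. The sweep additionally reports the
smallest shift at which `K_P` and `K_C` coincide within a relative
tolerance (default 10⁻³); for the printed model this detection is
provably empty — `K_P − K_C = Cv*·θ_I/(ρθ_v)` is bounded away from zero
because `μ_P ≥ μ0` — and the sweep reports that honestly (see
Limitations).

## Cohort simulator

The forward integrator discretises the consumer PDE into cohorts
`(n_i, l_i)` sharing one length. Newborns accumulate in a boundary
cohort whose number and first length moment are integrated alongside
(`dπ/dt = g(lb)n_b − G_T π − (μ_C+p)π`); every renewal interval
(default 1 day) it is closed into an internal cohort at
`l = lb + π/n_b`. Internal dynamics use classical Runge–Kutta substeps
(default 0.25 day) with step halving on negativity. Cohorts below
10⁻³⁰ L⁻¹ or 10⁻¹⁵ of total biomass are dropped, and neighbours closer
than 0.4 mm — dynamically indistinguishable — are merged
number-conservingly, which keeps cohort counts near 300. Halving the
renewal interval and substep demonstrably reduces the deviation from
the semi-analytic equilibria.

`run_to_attractor` integrates until the 500-day window means of
`(R, P, total consumer biomass)` change by less than a relative
tolerance, returning the time-averaged state and a convergence flag.

## Dynamic behaviour: cohort cycles

The consumer–resource fixed point of this model is dynamically unstable
to juvenile-driven single-cohort cycles essentially everywhere above
`K_C` (saturated resource amplitude about ±15 % already close to the
threshold, growing to roughly −40/+10 % at higher productivity). The
cycles are refinement-robust — identical amplitude at half the renewal
interval and a quarter of the merge tolerance — and are therefore a
property of the model, not of the discretisation. The time-averaged
cycling attractor tracks the fixed point to within 5–10 % in `R` and a
few percent in total biomass. Predation damps the cycles: the
trophic-chain equilibrium is dynamically stable and the simulator holds
it stationary to 0.2–0.5 % over 30 000 days. Initial-condition
dependence inside `[K_A, K_P)` is confirmed dynamically: a rare predator
seeded on the consumer attractor dies out, while the branch state
persists; above `K_P` the predator invades from rare. Because the
equilibrium analysis is the object of interest, the toolkit makes no
attempt to characterise the cycles beyond flagging non-convergence.

## Problem sizes and defaults

Threshold triples evaluate in ~20 ms, so full sweeps (≈200–300 shift or
temperature points at 0.1 °C with bisection refinement) complete in
seconds; simulator verification runs use 2 000–8 000 model days at the
default resolution. Default grids: temperature 5–25 °C at 0.25 °C for
phase maps (0.1 °C for boundary scans), productivity on a log grid
spanning 10⁻⁵–10⁻² g·L⁻¹, shifts ±16 °C at 0.1 °C.

## Known limitations

* **Threshold coincidence under predator niche shifts.** The reported
  merge of the predator invasion and consumer establishment thresholds
  for warm-shifted predators cannot occur in the model as printed: the
  gap `K_P − K_C` is strictly positive and never falls below ~10× `K_C`
  along the sweep, under either sign reading of the loss-rate exponent
  and either TSR reference convention. The sweep's coincidence detector
  returns "not found" for these sweeps.
* **Lower bistability boundary.** With losses increasing in temperature
  (the stated orientation), the emergent Allee effect vanishes below
  ≈7.4 °C rather than ≈10 °C; the opposite (literal-print) orientation
  recovers ≈10 °C but contradicts the stated temperature dependence and
  degrades the consumer-shift window boundary from ≈14.1 °C to ≈12.6 °C.
  The two published numbers are mutually inconsistent within the printed
  model; this implementation keeps the stated orientation.
* **TSR compensation in `K_C`.** Scaling `lmat` and `l∞` jointly leaves
  `K_C(T)` unchanged only to ≈0.5 % (the birth length does not follow
  the TSR), so the exact-compensation statement holds at figure
  precision, not to machine precision.
* The analysis is equilibrium-based: limit cycles are flagged, not
  continued; no spectral (eigenvalue) stability analysis of the
  structured model is performed; predator biomass units follow the
  source convention (intake per unit predator biomass).
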