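# tritherm

Equilibrium analysis of a temperature- and size-dependent tri-trophic food
chain: a semi-chemostat basal resource (e.g. *Daphnia*), a size-structured
consumer population (a roach-like planktivore characterised by body length
*l*), and an unstructured top predator (a perch-like piscivore) feeding on
the juvenile consumers it can swallow.

The toolkit is aimed at theoretical community ecologists who want to map
how community structure — which trophic levels persist, and whether
alternative stable states exist — changes along gradients of habitat
productivity *K*, environmental temperature *T*, and thermal-niche
mismatch between consumer and predator.

## The model

Individual consumer vital rates follow the standard size-structured
(Kooijman–Metz-type) parameterisation:

* ingestion `I(l,R) = I_T · l² · R/(Rh+R)` and von Bertalanffy growth
  `dl/da = G_T (l∞_T · R/(Rh+R) − l)`,
* reproduction `B(l,R) = B_T · l² · R/(Rh+R)` for mature individuals
  (`l > lmat_T`),
* mortality `μ_C` plus predation mortality while vulnerable (`l ≤ lv_T`),
* predator intake by a Holling type-II response on the vulnerable biomass
  `Cv`, with biomass dynamics `dP/dt = (ε·f(Cv) − μ_P)·P`.

Temperature enters through three channels, switchable per scenario
(1–12): a unimodal (Rosso) thermal performance curve scaling the rate
constants `I_T, G_T, B_T, f_T`; a Boltzmann–Arrhenius factor on the loss
rates `μ_C, μ_P` (equal to `2μ0` at the thermal optimum); and the
temperature–size rule `l_i,T = l_i · exp(β(T−20)/3)` on the size
thresholds. Scenarios 11/12 additionally shift one species' whole thermal
niche by ΔTPC.

At a fixed environment the consumer life history is available in closed
form, which reduces every equilibrium computation to scalar
root-finding:

* `K_C(T)` — consumer establishment threshold, from `R0(R̃, p=0) = 1`;
* `K_P(T)` — predator invasion threshold, where the consumer–resource
  equilibrium first supplies the break-even vulnerable biomass
  `Cv* = μ_P / (a(εf_T − hμ_P))`;
* `K_A(T)` — predator persistence threshold, the fold of the
  trophic-chain equilibrium branch. `K_A < K_P` marks an **emergent Allee
  effect**: an established predator persists at productivities where it
  could not invade, producing alternative stable states (PCR/CR).

A cohort-based (escalator-boxcar-train style) forward simulator provides
an independent dynamic check of every semi-analytic equilibrium.

## Worked example

```python
import tritherm as tt

params = tt.ModelParameters()              # published defaults, 20 °C reference
scen = tt.scenario_parameterization(10)    # all temperature effects active

for T in (13.0, 20.0, 24.0):
    th = tt.thresholds(T, params, scen)
    tag = tt.classify_from_thresholds(params.K, th)
    print(f"T={T:4.1f} degC  K_C={th.K_C:.3e}  K_A={th.K_A:.3e}  "
          f"K_P={th.K_P:.3e}  community at K=5e-4: {tag}")
```

prints

```
T=13.0 degC  K_C=9.035e-06  K_A=6.598e-05  K_P=1.413e-04  community at K=5e-4: PCR
T=20.0 degC  K_C=8.857e-06  K_A=8.848e-05  K_P=2.536e-04  community at K=5e-4: PCR
T=24.0 degC  K_C=1.145e-05  K_A=1.271e-04  K_P=1.501e-04  community at K=5e-4: PCR
```

i.e. at the default productivity of 5×10⁻⁴ g·L⁻¹ the full trophic chain
is feasible across the niche, while the bistable band `[K_A, K_P)` is
widest at the joint thermal optimum. The same analyses are available from
the shell:

```sh
tritherm thresholds --scenario 4 --out curves        # K_C/K_P/K_A vs T (CSV)
tritherm phase      --scenario 10 --out phasemap     # region matrix over (T, K)
tritherm mismatch   --species predator --temperature 20 --out sweep
tritherm simulate   --scenario 1 --days 2000 --out traj
tritherm validate                                    # built-in invariant checks
```

`tritherm mismatch` also reports the persistence window along the shift
axis and, for predator sweeps, the analytic existence boundary
`ΔTPC = T_env − Tmax` at which the predator's shifted niche excludes the
environmental temperature.

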