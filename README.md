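# proteocell

Mechanistic modelling of how a protein-conditioned biomaterial surface
recruits cells.  The package couples two models that biomaterials groups
usually treat separately:

1. **Protein adsorption/desorption** on a hydroxyapatite (HA) disk under a
   quiescent medium column — 1D diffusion of serum albumin with Langmuir
   attach/detach kinetics at the disk face:

       dc/dt  = D d²c/dz²,                      dc/dz = 0 at z = h,
       dc_s/dt = k_a c(0,t) (c_sᵐ − c_s) − k_d c_s     at z = 0,

   with exact fluid+surface mass conservation and the monolayer capacity
   tied to an observed equilibrium by c_sᵐ = c_s^f (1 + k_d / (k_a c^f)).

2. **Osteoblast attachment** as a two-compartment model — seeded cells are
   free or attached, a fraction γ is viable, and attachment follows
   dc_a/dt = k (γc₀ − c_a)(c_m − c_a) with the closed-form logistic
   solution evaluated at the cumulative exposure K(t) = ∫ k dt′.

The one-way coupling maps the simulated protein coverage into the adhesion
coefficient through a saturating transfer function k(c_s) = a (1 − e^{−b c_s})
with k(0) = 0, reproducing the observation that bare surfaces recruit cells
poorly while pre-incubated (protein-conditioned) surfaces recruit them
fast.

Estimation mirrors the original study design: exhaustive (k_a, k_d) grid
search against adsorption + desorption concentration series, 1D fitting of
a constant adhesion rate per experiment with a 50%-error-increase
uncertainty interval, and exhaustive (a, b) search across pre-incubation
scenarios.  A synthetic-data module generates replicate-noise measurement
series so every fitting stage is testable by parameter recovery without
external data.  The fitters are scikit-learn-style estimators
(`LangmuirGridSearch`, `AdhesionRateFit`, `TransferFunctionFit`) with thin
functional wrappers.

## Worked example

```python
import numpy as np
from proteocell import *

# capacity implied by the observed adsorption equilibrium
# (fluid 5300 ug/mL, coverage 29.04 ug/mm^2) at the fitted rates
csm = steady_state_capacity(6.2e-4, 0.2,
                            SteadyState(c_final=5300.0, c_s_final=29.04))
print(round(csm, 2))                     # 30.81  (ug/mm^2)

# desorption: conditioned disk transferred into protein-free medium
params = ProteinParams(k_a=6.2e-4, k_d=0.2, c_s_max=csm, D=0.3)
traj = solve_protein_kinetics(params, DEFAULT_GEOMETRY,
                              initial_fluid=0.0, initial_surface=29.04,
                              t_end=80.0)
released = (traj.mean_fluid[-1] * DEFAULT_GEOMETRY.volume_mL
            / (DEFAULT_GEOMETRY.area_mm2 * 29.04))
print(round(100 * released, 1))          # 20.3   (% of the layer released)

# mean coverage over the culture window after 48 h pre-incubation
print(round(scenario_mean_cs(Scenario(pre_incubation_h=48.0)), 1))  # 29.3

# coupled prediction: cells seeded on the 48 h pre-conditioned disk
tr = coupled_attached_cells(Scenario(pre_incubation_h=48.0),
                            TransferFunction(),  # a=1.32e-5, b=0.213
                            t_culture=np.array([0.5, 1, 2, 4, 6]))
print(np.round(tr.attached, 0))
# [1432. 1933. 2171. 2204. 2205.]  cells/cm^2 -> plateau gamma*c0 = 2205
```

The desorption run says a fifth of the adsorbed albumin re-enters solution
within 80 h; the coupled run shows attachment saturating at the viable
seeded density (0.63 × 3500 cells/cm²) within ~4 h on a well-conditioned
surface.

## Command line

```bash
proteocell synth -o out --seed 42          # synthetic dataset + manifest
proteocell fit-protein -c run.yaml \
    --adsorption-csv ads.csv --desorption-csv des.csv
proteocell couple -o out                   # coupled per-scenario predictions
proteocell recover -o out --seed 0         # full parameter-recovery loop
```

Runs are configured by a schema-validated YAML/JSON file with unit-suffixed
keys; every run writes its resolved configuration, tidy CSVs, a JSON
summary and a log.  Identical config + seed reproduces outputs byte for
byte.

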