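# evbkit

A toolkit for two-state **empirical valence bond (EVB)** free-energy
calculations: mapping-potential free energy perturbation, umbrella-sampling
reconstruction of adiabatic and diabatic profiles on the energy-gap
coordinate, post-hoc calibration and perturbation of the EVB parameters, and
**computational Arrhenius plots** that decompose activation free energies
into ΔH‡ and ΔS‡.

It is aimed at people who study the temperature dependence of chemical
reactions in solution and in enzymes with reactive force fields, and at
anyone who wants a compact, fully oracle-checked reference implementation of
the EVB free-energy machinery. A built-in one-dimensional solvent-coordinate
model with closed-form free energies stands in for atomistic MD, so every
estimator in the package can be validated end to end on a laptop.

## The model

A reaction step is a 2×2 Hamiltonian whose diagonal elements U1, U2 are
classical force fields for the reactant and product bonding patterns, with a
constant coupling H12 and a gas-phase shift Δα added to the product state.
The adiabatic ground state is

    Eg = ((U1 + U2) − sqrt((U1 − U2)² + 4 H12²)) / 2,

sampled indirectly via the mapping potential U_map(λ) = (1−λ)U1 + λU2.
Free energies along λ come from Zwanzig's formula; the profile along the
energy gap ΔU = U1 − U2 comes from the umbrella-sampling estimator

    ΔG_g(X) = Σ_m p_m [ ΔG(λ_m) − RT ln ⟨ e^{−(Eg − U_map)/RT} 1[ΔU ∈ X] ⟩_m ].

H12 and Δα are calibrated so the profile reproduces target (ΔG‡, ΔG0);
because neither parameter changes the relative within-window sampling
weights, the same trajectories can be re-analysed exactly under any
(H12, Δα) — the basis of the parameter-perturbation studies. Repeating the
analysis over a temperature grid and regressing ΔG‡/T on 1/T (or ΔG‡ on T)
yields ΔH‡ and ΔS‡ with asymptotic standard errors.

See `docs/methods.md` for the full methods note, including estimator
resolution caveats and what the toy model does and does not emulate.

## Worked example

Simulate the symmetric charge-transfer toy (reorganization energy
148 kcal/mol, diabatic crossing 37 kcal/mol), reconstruct the profile,
re-analyse it under calibrated parameters, and extract activation
enthalpy/entropy:

```python
import numpy as np
from evbkit import (
    ArrheniusSeries, BinSpec, EVBParameters, HarmonicDiabatModel, SamplingSpec,
    arrhenius_fit, extract_stationary_points, gap_profile, generate_dataset,
    reweight_profile,
)

model = HarmonicDiabatModel.symmetric()          # Marcus toy, crossing 37 kcal/mol
spec = SamplingSpec(temperatures=(280.0, 290.0, 300.0, 310.0, 320.0),
                    n_steps=60_000, n_burnin=6_000, n_replicates=1, seed=1)
dataset = generate_dataset(model, spec)

windows = dataset.select(temperature=300.0, replicate=0)
profile = gap_profile(windows, model.parameters, bins=BinSpec(301))
summary = extract_stationary_points(profile)
print(f"uncoupled barrier:      dG_act = {summary.dg_act:.2f} kcal/mol")

par = EVBParameters(h12=20.0, delta_alpha=20.0)
_, cal = reweight_profile(windows, model.parameters, par, bins=BinSpec(301))
print(f"(h12, dalpha) = (20, 20): dG_act = {cal.dg_act:.2f}, dG0 = {cal.dg_rxn:.2f}")

dg_act = []
for temp in dataset.temperatures:
    w = dataset.select(temperature=temp, replicate=0)
    _, s = reweight_profile(w, model.parameters, par, bins=BinSpec(301))
    dg_act.append(s.dg_act)
fit = arrhenius_fit(ArrheniusSeries(np.array(dataset.temperatures), np.array(dg_act)),
                    mode="auto", t_ref=300.0)
print(f"Arrhenius ({fit.mode}): dH_act = {fit.dh:.2f} +/- {fit.se_dh:.2f}, "
      f"T dS_act(300 K) = {fit.tds_at:.2f} kcal/mol, R^2 = {fit.r_squared:.4f}")
```

Output:

```
uncoupled barrier:      dG_act = 36.81 kcal/mol
(h12, dalpha) = (20, 20): dG_act = 30.30, dG0 = 19.24
Arrhenius (gOverT_vs_invT): dH_act = 30.39 +/- 0.35, T dS_act(300 K) = 0.06 kcal/mol, R^2 = 0.9996
```

Reading the numbers: with no coupling the barrier is the diabatic crossing
(37 kcal/mol, entirely solvent reorganization; 36.81 here, within the
histogram resolution and Monte-Carlo noise). Setting H12 = 20 and Δα = 20 on
the *same trajectories* lowers the barrier to 30.3 and lifts the reaction
free energy to 19.2 kcal/mol — the closed-form values are 30.31 and 19.24 —
and the Arrhenius fit shows this barrier is almost purely enthalpic, as it
must be for a temperature-independent model (k1 = k2).

## Command line

Every step is also a subcommand of `evbkit`:

```sh
evbkit simulate  --config config.yaml --out run/          # trajectory tables
evbkit profile   --traj run/ --h12 20 --dalpha 20 --bins 301
evbkit diabats   --traj run/ --h12 0 --out diabats.tsv
evbkit reweight  --traj run/ --h12 20 --dh12 10 [--importance]
evbkit calibrate --traj run/ --target-dgact 19.7 --target-dgrxn 0
evbkit arrhenius --summaries dg_by_temperature.tsv --mode auto --tref 300
evbkit decompose --traj run/ --h12 20 --coordinate c2sq
evbkit pipeline  --config config.yaml --out run/ --seed 1
```

A full configuration file (YAML; every run writes its resolved copy and a
manifest with the sub-seed table next to its outputs):

```yaml
model:            # harmonic diabats: U1 = k1 x^2 / 2, U2 = k2 (x-d)^2 / 2 + delta_alpha
  k1: 8.222222222222221
  k2: 8.222222222222221
  d: 6.0
  delta_alpha: 0.0
  h12: 20.0
sampling:
  lambda_schedule: [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5,
                    0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0]
  temperatures: [280.0, 290.0, 300.0, 310.0, 320.0]
  n_steps: 200000
  n_burnin: 20000
  step_size: 0.5
  seed: 1
  n_replicates: 3
bins:
  n_bins: 51
  gap_range: null     # auto: observed range padded by 1% per side
  min_frames: 10
evb: null             # analysis (h12, delta_alpha); null = the model's values
t_ref: 300.0
arrhenius_mode: auto
perturbations: []     # e.g. [[10.0, 0.0], [0.0, -10.0]] for a reweight sweep
log_level: INFO
```

Trajectory tables are plain TSV (`frame  lambda  temperature  x  U1  U2raw`,
one file per temperature and replicate, units in a leading comment line), so
energies from any other source can be analysed by writing that format.

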