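# Methods

## The model

An elementary chemical step is represented as a two-state valence-bond
problem. The diagonal elements of the 2×2 Hamiltonian are classical
force-field energies of the reactant (U1) and product (U2) bonding patterns;
the constant off-diagonal coupling H12 mixes them, and the adiabatic ground
state is the lower eigenvalue

    Eg = ((U1 + U2) − sqrt((U1 − U2)² + 4 H12²)) / 2.

Standard force fields carry no information about the absolute
heat-of-formation difference between the two bonding patterns, so a constant
gas-phase shift Δα is added to the product state: U2 = U2_raw + Δα. H12 and
Δα are the model's two free parameters; together they are calibrated so that
the activation free energy ΔG‡ and reaction free energy ΔG0 reproduce target
data, after which enthalpy/entropy decompositions are *predictions*, not
fits. The squared components of the normalized ground-state eigenvector,
c1² + c2² = 1, measure reactant/product character along the path.

Units are kcal/mol and kelvin throughout, with R = 1.987204×10⁻³
kcal/(mol·K). The generalized reaction coordinate is the energy gap
ΔU = U1 − U2 (reactant frames sit at negative ΔU when the reactant is the
lower state).

## Free-energy machinery

Sampling is performed on the mapping potential
U_map(λ) = (1−λ) U1 + λ U2 over an ordered schedule of λ windows
(default 21, endpoints included). The free energy along the schedule is
accumulated by forward exponential (Zwanzig) averaging between adjacent
windows; all exponential averages are computed in log space with a max
shift, and an effective-sample-size diagnostic warns (`WARN:` prefix on
stderr) when window overlap is poor.

The ground-state profile on ΔU is reconstructed with the umbrella-sampling
expression

    ΔG_g^(m)(X) = ΔG(λ_m) − RT ln ⟨ exp(−(Eg − U_map)/RT) · 1[ΔU ∈ X] ⟩_m,

where the bin indicator sits *inside* the window average (so the histogram
factor n_bin/N_m is retained; in the uncoupled single-window limit the
profile correctly reduces to −RT ln p(X) + const). Bins are pieced together
over windows with weights p_m equal to each window's share of the bin's
frames; windows contributing fewer than `min_frames` (default 10) frames to
a bin are excluded, and bins with no contributor are flagged absent (NaN),
never zero. Diabatic profiles replace Eg by U1 or U2 with identical binning
and weights. Profiles are anchored so the ground-state reactant minimum is
zero. Stationary points are located by a local three-point quadratic fit
around the discrete extrema; the transition-state bin's frame-averaged
(c1², c2²) is reported with the summary. When several interior maxima are
candidates (noisy profiles whose edges rise above the barrier), the one with
the largest two-sided barrier is chosen.

### Binning resolution

The default histogram is 51 bins over the observed ΔU range padded by 1% of
the span on each side. One caveat matters: the histogram estimator assigns
each bin roughly the *minimum* free energy inside it (Laplace/edge
domination of the within-bin Boltzmann integral), a deflection of order
(w/2)·|dA/dΔU| that also scales with RT. Smooth coupled extrema are
insensitive to this, but cusp-like features — the uncoupled (H12 = 0)
crossing, whose flanks have slope 1/2 — are deflected by ~2 kcal/mol at the
default width, and the RT scaling of the deflection can leak into
temperature decompositions as spurious entropy. Analyses of barrier-top
quantities therefore use a finer grid (301 bins) where stated; this is a
resolution requirement of the estimator, not a tuning knob, and the
diabatic-intersection and uncoupled-barrier checks quantify it.

### Post-hoc reparametrisation

`reweight_profile` re-evaluates Eg, U2, ΔU and every mapping/umbrella
quantity under new (H12, Δα) on unchanged trajectories. For this parameter
family the protocol is *exactly* consistent, not an approximation: H12 never
enters U_map, and a Δα change shifts U_map by the frame-independent constant
λ·δα per window, which cancels identically between the Zwanzig accumulation
and the umbrella exponent. An importance-reweighting mode (per-frame weights
exp(−(U_map_new − U_map_old)/RT), normalized per window, with ESS warnings)
is provided for generality; for H12/Δα changes the weights are uniform and
the two modes coincide, which the tests assert.

Calibration of (H12, Δα) to target (ΔG‡, ΔG0) is a two-dimensional bounded
least-squares root find (H12 ≥ 0) whose every residual evaluation re-analyses
the same trajectories; convergence requires residuals ≤ 0.05 kcal/mol within
200 evaluations.

## Computational Arrhenius plots

Free energies computed on a temperature grid (default 280–320 K in 10 K
steps) are regressed either as ΔG/T vs 1/T (slope ΔH, intercept −ΔS) or as
ΔG vs T (slope −ΔS, intercept ΔH); `auto` picks the mode with the higher R².
The default is unweighted ordinary least squares on per-temperature replicate
means, with asymptotic standard errors; weighting by 1/sem² is available
behind a flag. T·ΔS is reported at a configurable reference temperature,
default 300 K ("room temperature"; this value reproduces the −RT ln 55 =
−2.39 kcal/mol standard-state correction to two decimals, whereas 298 K does
not). The standard-state helper implements −RT ln(c₂/c₁) for bimolecular
reactions (1 M → 55 M gives −2.39 kcal/mol at 300 K; at 1 M a molecule
roams ~1661 Å³, a sphere of radius ~7.3 Å).

The entropy decomposition along the path fits, per position, an Arrhenius
regression to the free energy relative to the reactant reference: along λ,
the mapping free energies ΔG(λ_m, T); along c2², the ground-state profile
binned on the product weight (default 16 bins on [0.1, 0.9], re-anchored at
the first bin occupied at every temperature). Bins missing at any
temperature are flagged absent.

## The synthetic-data generator

The toy system is a one-dimensional solvent coordinate with harmonic
diabats, U1 = k1 x²/2 and U2_raw = k2 (x−d)²/2, standing in for the
solvent-reorganization statistics of atomistic MD: each λ window samples a
Gaussian band of the energy gap, adjacent windows overlap, and window free
energies are temperature dependent. Closed forms make it a complete oracle:

* window free energies G(λ) − G(0) = U_map(x*(λ)) + (RT/2) ln(k(λ)/k1),
  with k(λ) = (1−λ)k1 + λk2;
* reaction entropy S(1) − S(0) = −(R/2) ln(k2/k1);
* for k1 = k2 the binned profile equals the adiabatic curve Eg(x(ΔU))
  exactly (the gap map is linear), so barrier and ΔG0 have closed forms.

Two presets are used. The *symmetric* preset (k1 = k2, d = 6 Å,
reorganization energy λ_reorg = k d²/2 = 148 kcal/mol) is a Marcus-type
charge-transfer model whose diabats cross at λ_reorg/4 = 37 kcal/mol; with
(H12, Δα) = (20, 0) the adiabatic barrier is 19.70, with (0, 20) the
reaction free energy is exactly 20, and with (20, 20) ΔG‡ = 30.3 and
ΔG0 = 19.2 (all closed form). The *asymmetric* preset (k2 = 2 k1, H12 = 20)
adds a nonzero reaction entropy, T·ΔS = −0.207 kcal/mol at 300 K, for
temperature-decomposition studies.

Sampling is Metropolis Monte Carlo on U_map with Gaussian proposals; the
step size is tuned during burn-in toward 40% acceptance and then frozen, and
a warning is emitted if the production acceptance rate leaves [0.15, 0.7].
Only equilibrium averages enter the estimators, so no dynamics beyond a
correct stationary law is needed. Sub-seeds are derived by counter-based
splitting (`SeedSequence(seed, spawn_key=(T index, replicate, λ index))`),
making replicates independent by construction and every dataset reproducible
bit-for-bit; the sub-seed table is written to the run manifest.

Defaults: n_steps = 2×10⁵ per window with 2×10⁴ burn-in, 21 λ windows,
5 temperatures, 3 replicates. Analyses in the test suite and the
reproduction script use explicitly stated smaller or larger sizes chosen by
error analysis: the per-temperature noise of a free energy maps into the
fitted T·ΔS roughly as 9.5σ on the 280–320 K grid, so decomposition checks
with 0.3 kcal/mol tolerances use ~10⁶ pooled frames per (λ, T), while
profile-shape checks need only ~5×10⁴ frames per window.

### What the toy does and does not emulate

It reproduces the statistical structure the estimators care about —
overlapping Gaussian gap bands per window, temperature-dependent window free
energies, replicate scatter — so passing tests validates the estimator
chain, the reparametrisation identities, and the Arrhenius decomposition.
It does not contain anharmonicity (within-window gap fluctuations are
exactly Gaussian), multi-dimensional solvent relaxation, or any real
force-field entropy. One consequence worth stating: in one dimension the
ground-state-coordinate entropy profile TΔS_g(c2²) is dominated by the
coordinate-Jacobian term −R ln|dc²/dx|, which is why it does not track
TΔS(λ) here the way it does in high-dimensional solvent ensembles, where
that geometric term is shared between coordinates. The decomposition is
therefore validated against the toy's closed-form quadrature rather than
against cross-coordinate agreement. The activation-entropy *invariance*
under (H12, Δα) shifts — the headline property — does transfer, and is
asserted end to end.

## Numerical choices

* Exponential averages: log-space with max shift (`scipy.special.logsumexp`),
  grouped per bin by a stable sort.
* Window-inclusion threshold compared with a 10⁻⁶ epsilon so that float
  effective counts (importance mode) cannot flip inclusion at the boundary.
* Quadratic refinement falls back to the discrete extremum when the fitted
  vertex leaves the three-point bracket or curvature vanishes.
* Degenerate eigenvector (H12 = 0 with U1 = U2) raises an explicit error in
  the scalar API; inside profile engines the h12 = 0 weights are the
  lower-diabat indicator (ties at 0.5), since equality is measure-zero for
  continuous sampling.
* Monte-Carlo kernel is JIT-compiled with numba (pure-Python fallback kept);
  chains are reproducible bit-for-bit for a given seed.

## Known limitations

* Forward-only Zwanzig accumulation (overlap diagnostics rather than
  bidirectional estimators); no WHAM/MBAR global estimator.
* Constant H12 only; no distance- or gap-dependent coupling, no >2-state
  Hamiltonians.
* The histogram estimator's resolution caveat above applies to any sharply
  curved feature; use more bins rather than trusting barrier values whose
  3-point quadratic refinement disagrees with neighbouring bins.
* Absolute T·ΔS‡ values from the toy are small (|T·ΔS| ≲ 1 kcal/mol) and
  noise-limited at desk-scale sampling; parameter-shift *differences* are
  far more precise because all re-analyses share the same trajectories.
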