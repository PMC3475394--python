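# Methods

`denitmod` is a mechanistic model of a facultative denitrifier
(*Agrobacterium tumefaciens*) switching from aerobic respiration to
denitrification in sealed serum flasks.  The organism oxidizes succinate
with O₂ while it lasts, then sequentially with nitrate (Nap), nitrite
(NirK) and nitric oxide (NorB); lacking N₂O reductase, it finishes at N₂O.
The model couples three layers: growth stoichiometry, enzyme kinetics with
transcription-level regulation, and closed-flask gas–liquid mass balances.

## Growth stoichiometry

Each pathway converts one mole of succinate (dianion, C₄H₄O₄²⁻, degree of
reduction γ = 14) into biomass (CH₁.₈O₀.₅N₀.₂, 24.6 g/C-mol, γ = 4.2 with
ammonium-derived nitrogen) plus CO₂, water and the reduced acceptor.  The
biomass yield *x* (C-mol per mol succinate) solves a self-consistent
chemiosmotic balance: catabolic electrons `14 − 4.2x` flow as pairs, each
translocating a regime-dependent number of protons (aerobic: 10 per
NADH-level pair, 8 per FADH₂-level; anoxic: 6 and 4), ATP synthesis costs 4
H⁺ per ATP, and growth returns 9.1 g dry weight per mol ATP:

    x = (14 − 4.2 x)/2 · H_pair/4 · 9.1/24.6

This gives x = 2.20 aerobically and x = 1.79 under denitrification.  The
fraction of electron pairs entering at the FADH₂ level is configurable
(`nadh_fadh2_split`); the default routes all pairs at NADH level, and a
1-in-7 FADH₂ split rounds to the same one-decimal yields, so the choice is
immaterial at the reported precision.

Given the yield, `close_stoichiometry` fixes the acceptor coefficient from
the electron balance (O₂ accepts 4 e⁻, NO₃⁻→NO₂⁻ 2, NO₂⁻→NO 1, NO→½N₂O 1),
NH₄⁺ from nitrogen, CO₂ from carbon, H⁺ from charge and H₂O from hydrogen;
the oxygen balance then closes identically, and every equation is verified
to 0.02 mol/mol.  The feasible yield is bounded by the electron balance at
14/4.2 ≈ 3.33 C-mol/mol (biomass is more reduced per carbon than
succinate), not by the carbon balance at 4.

The reactor uses the canonical two-decimal coefficients (1.2 O₂, 3.23 NO₃⁻,
6.45 NO₂⁻ and NO, yields 2.2/1.8), with one deliberate exception: the N₂O
coefficient is defined as half the NO coefficient (3.225) instead of being
rounded independently to 3.23.  Rounding it separately would create
nitrogen from nothing — about 0.15% of the N-oxide pool over a complete
nitrite-to-N₂O conversion — and the conservation audits are meant to
detect exactly that class of error.  The fully unrounded derivation-based
set is available via `ReactionCoefficients.from_derivation()`.

## Kinetics and regulation

All rates are expressed per liter of liquid with concentrations in mol/L
and time in hours; tabulated micromolar constants are converted once at
load.  The four succinate-consumption rates share a single maximum specific
uptake rate `q_m = 0.066 mol succ (C-mol X)⁻¹ h⁻¹` and are linear in
biomass:

* **Aerobic**: Monod in O₂ (K = 8.28 µM) with competitive NO inhibition of
  the terminal oxidase (K_I = 0.0174 µM).
* **Nap / NirK**: Monod in NO₃⁻ (K = 13 mM) / NO₂⁻ (K = 880 µM), scaled by
  the enzyme saturation E_sat, times a steep power-law oxygen inhibition
  term Kⁿ/(Kⁿ + C_O₂ⁿ) with n = 4 (Nap, K = 4 µM) and n = 3.7 (NirK,
  K = 3.58 µM) — the apparent inhibition by preferential electron flow to
  the oxidase, not direct enzyme inhibition.
* **NorB**: second order in NO (two NO condense to one N₂O), written as a
  squared Haldane term C²/[C(1 + C/K_I) + K]² with K = 0.0081 µM and
  substrate inhibition K_I = 20 µM, times first-order oxygen inhibition
  (K = 1.0 µM).  The rate peaks at C_NO = √(K·K_I) ≈ 0.40 µM.

Enzyme synthesis lumps transcription and translation into one
substrate-activated Michaelis–Menten ODE per reductase with a (1 − E_sat)
ceiling and no decay.  NirK and NorB are induced by their own substrates
(K = 50 µM and 0.054 µM; v_max = 1/15 h⁻¹ and 1 h⁻¹ — NorB expression is
fast); Nap induction is oxygen-repressed (K_I = 1.0 µM) with a nitrate term
whose affinity constant (10⁻⁵ µM) makes it effectively always saturated; it
is kept as tabulated rather than simplified away.  An optional extra O₂
factor on NorB synthesis (K = 400 µM) exists for nitrate scenarios; because
only its constant is documented, its functional form is selectable
(saturation or inhibition in C_O₂) and it is **off by default** — results
using it should say so.

Rates clip concentrations that underflow below zero by solver round-off
(tolerance 10⁻¹⁵ M scale) and raise on genuinely negative input.

## Flask mass balances

Geometry is fixed by the experiment: 0.05 L liquid under 0.07 L headspace,
initial biomass 0.25 mC-mol/L, enzymes absent, nitrite or nitrate at
0.2–2 mM, headspace O₂ at 1% or 7% with the liquid in Henry equilibrium
(H_O₂ = 33, H_NO = 21, H_N₂O = 1.74, H_CO₂ = 1.2, dimensionless gas/aq
ratios).  Headspace percentages convert to molar with the ideal gas law at
293.15 K and 1 atm; temperature and pressure are configurable and affect
only that conversion (they are not part of the kinetics).  Gas–liquid
exchange is k_L a (c/H − C) with k_L a = 19.8 h⁻¹; the headspace sees only
exchange, scaled by V_L/V_G.  pH is buffered at 7.5; the CO₂/HCO₃⁻ pair
(pK_a 6.36) therefore sits at a fixed ratio of 10^(7.5−6.36) ≈ 13.8.

Two carbonate treatments are implemented.  The default (`algebraic`)
replaces the stiff interconversion by its fast-equilibrium reduction: total
dissolved inorganic carbon is integrated and split at the fixed ratio.
The `kinetic` mode integrates the literal hydration rate law with
k_car = 10¹⁴ h⁻¹ (which exists only to enforce equilibrium) and serves as a
cross-validation; the two agree on headspace CO₂ to better than 10⁻⁴%.

Integration uses `scipy.integrate.solve_ivp` with LSODA (BDF in the
kinetic-carbonate mode) at rtol 10⁻⁸, atol 10⁻¹² M.  Succinate is in
excess and not a state, but its cumulative consumption per pathway is
integrated for the audits.  Two conservation laws hold analytically and
are asserted over every simulation:

* **N-oxide nitrogen**: V_L(NO₃⁻+NO₂⁻+NO+2N₂O) + V_G(NO+2N₂O) is constant
  (pathway terms telescope; transfer terms cancel between phases),
* **Carbon**: 4 × succinate consumed = biomass-C + Δ inorganic carbon
  (liquid CO₂+HCO₃⁻ plus headspace CO₂).

Both close to machine precision on the reference run; the acceptance
thresholds (0.1% and 0.5%) allow for solver drift at looser tolerances.
Solver-accuracy checks compare trajectories as sup-norm differences
relative to each species' trajectory maximum, since pointwise relative
error is meaningless for concentrations that decay through zero; halving
both tolerances moves no headspace species by more than ~10⁻³% of its peak.

## Fitting and sensitivity

Model–data agreement uses the mean-normalized SSE,
`Σ_species Σ_t (C_obs − C_model)²/mean(C_obs)`, over headspace O₂, NO, N₂O
and CO₂ — the normalization stops millimolar species from drowning out
nanomolar NO — and per-species R² = 1 − SSE/TSS.  TSS is taken about the
observation mean (the conventional definition); a variant about the model
mean is available behind `tss_about="model"` for comparison with sources
that print the formula that way.

`fit_parameters` minimizes SSE_total over a named parameter subset with box
bounds, simulating per candidate and interpolating the model to the
observation times.  The optimizer is bounded Nelder–Mead on internally
rescaled parameters (each start value mapped to 1), optionally multi-start
with log-uniform draws from a seeded generator; it never reports a point
worse than its start, and failed candidate simulations are penalized rather
than fatal.  The problem class (smooth, 1–4 free parameters) does not favor
gradient-based SQP enough to require it.

One-at-a-time sensitivity scales each parameter by 0.9 and 1.1 (linear
multiplicative, in the parameter's own units), re-simulates, and reports
100·(SSE_perturbed − SSE_fit)/SSE_fit per species and in total.  Entries
are signed — a perturbation may improve one species' fit — and a parameter
with no influence on the scenario (e.g. any nitrate-pathway constant in a
nitrite-only flask, where Nap is never induced) yields exactly zero.  On
synthetic reference data `q_m` dominates the ranking, `K_O2` is the clear
runner-up, and the NorB substrate-inhibition constant `K_I_NO` is flat
(NO never approaches 20 µM in that scenario) — the identifiability
structure the experimental design implies.

## Synthetic data

`denitmod.synthetic` emulates the 2×2×3 factorial flask design ({1%, 7%}
O₂ × {nitrite, nitrate} × {0.2, 1, 2} mM) with the reference preset
`nitrite_1mM_o2_1pct`.  Measurements are the simulated headspace series
sampled every 0.5 h over 50 h (the experiments span tens of hours;
the true instrument cadence and detection limits are not part of the
model, so these defaults are explicit placeholders) and corrupted with
proportional Gaussian noise, σ = 5% of the per-species mean, truncated at
zero.  The noise model is a pragmatic stand-in chosen to resemble published
flask scatter, not an instrument error model; it has no autocorrelation,
no detection floor, and no flask-to-flask biological variability.  Passing
parameter-recovery tests on these data therefore demonstrates correctness
of the estimation machinery and local identifiability under idealized
noise — not that real gas-chromatography series would constrain the same
parameters equally well.

## Known limitations

* Enzyme decay, pH dynamics, N₂O reduction and succinate limitation are
  deliberately absent (matching the modeled organism and conditions).
* The bioenergetic derivation reproduces the printed reaction coefficients
  through electron balances; maintenance energy and transport costs are not
  resolved separately, so intermediate quantities (ATP per pair, P/O-like
  ratios) should not be over-interpreted.
* The nitrite coefficient of NirK computed at the unrounded anoxic yield is
  6.47 to two decimals; the canonical rounded set uses 6.45, and the two
  differ below the precision of any downstream conclusion.
* Gas-phase NO has no abiotic loss channel; the flask is assumed perfectly
  sealed and sampling-volume effects are ignored.
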