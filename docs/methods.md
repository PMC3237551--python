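# Methods

This note documents the model behind `mase-kinetics`, the synthetic data
generator, the estimator, the numerical choices, and the known limitations.
All units: time in seconds, concentrations in arbitrary consistent units,
k_off in s⁻¹, k_on in conc⁻¹ s⁻¹.

## 1. Model and assumptions

### Reaction system

A heterodimeric complex A + B ⇌ AB with association rate k_on and
dissociation rate k_off. Two lysates are prepared:

- **unlabeled-tagged**: subunit A carries an affinity tag, both subunits are
  isotopically light (A<sup>T</sup><sub>U</sub>, B_U);
- **labeled-untagged**: no tag, both subunits metabolically heavy
  (A_L, B_L).

Mixing them 1:1 yields 8 species (4 free subunits + 4 complex
combinations). The measured quantity is the hybrid-to-original ratio among
tagged complexes,

    R(t) = [A_TU·B_L](t) / [A_TU·B_U](t).

Assumptions of the forward model:

1. Isotope labeling and the affinity tag are kinetically silent: all four
   A·B pairings share the same k_on and k_off.
2. Each lysate is at binding equilibrium before mixing; mixing is
   instantaneous and changes only concentrations (default dilution factor 2).
3. Mass action holds (well-mixed, dilute); no synthesis, degradation or
   other reactions during the exchange time course.
4. The purification/quantification step reads complex abundances without
   perturbing them (purification is treated as a snapshot).

### Equivalent lysates and the closed form

Call the lysates *equivalent* when they contain the same total A and total B
(so the mixed system starts at its own binding equilibrium). Then three
properties hold, each verified numerically by `verify_propositions` against
the full ODE system:

1. every free-subunit concentration is constant in time;
2. the summed tagged-complex concentration [A_TU·B_U] + [A_TU·B_L] is
   constant;
3. R(t) → 1 as the labels fully scramble.

With free [B_U] = [B_L] = β constant, the tagged complexes obey a linear
two-state relaxation: the original decays losing half its dissociation flux
to the hybrid pool and vice versa, giving

    [A_TU·B_L](t) = C·(1 − e^(−k_off·t))/2,
    [A_TU·B_U](t) = C·(1 + e^(−k_off·t))/2,

hence

    R(t) = (1 − e^(−k_off·t)) / (1 + e^(−k_off·t)) = tanh(k_off·t/2).

k_on and all concentrations cancel. The package uses this closed form as the
primary predictor (`predict_R`) and cross-checks it against the full
8-species mass-action ODE: maximal absolute deviation below 1e−6 over an
8-hour grid for k_off ∈ {1e−5, 1e−4, 1e−3}, and invariance of the simulated
curve to k_on over 1e4–1e8 at the same tolerance (see
`scripts/acceptance.py`).

When the lysates are *not* equivalent (the package's negative control doubles
total B in the labeled lysate), free-subunit constancy fails and R no longer
relaxes to 1 — the closed form does not apply and the ODE simulator must be
used.

### Identifiability and design

Since R depends on the product k_off·t only,

    ∂R/∂k_off = (t/2)·sech²(k_off·t/2)

is maximal at k_off·t ≈ 1.5434 (root of x·tanh(x/2) = 1, computed once with
a bracketing root-finder and cached). `default_design` places sampling
times to cover a target rate window [k_low, k_high]: t = 0 plus
geometrically spaced points from 0.1/k_high to min(3/k_low, horizon), with
the point nearest t* = 1.5434/√(k_low·k_high) snapped exactly onto t* so the
most informative time is always sampled. The default horizon is 8 h.

## 2. Simulators

### Deterministic (`simulate_exchange`)

The 8-species mass-action ODE integrated with `scipy.integrate.solve_ivp`
(LSODA). The system is stiff whenever k_on·[subunit] ≫ k_off (binding
relaxes much faster than exchange), which is the regime of interest, hence a
stiffness-switching method and tight tolerances rtol = 1e−9, atol = 1e−12 —
chosen so the integration error (≲1e−8 in R) sits well below the 1e−6
agreement tolerance and far below measurement noise. Initial state: each
lysate analytically pre-equilibrated, summed, divided by the dilution
factor. Mass conservation of total A and total B is checked to 1e−8
relative.

### Stochastic (`simulate_exchange_stochastic`)

An exact event-driven simulation (Gillespie direct method) in integer copy
numbers: a `volume_scale` converts concentrations to copies, propensities
are (k_on/volume_scale)·n_A·n_B for each association channel and k_off·n_AB
for each dissociation. Copy number is conserved exactly. Waiting times are
drawn in chunks for speed; the state recorded at each grid time is the state
immediately before the first event past that time.

**Regime choice for the deterministic/stochastic consistency study.** The
study uses k_on = 0.01, k_off = 1e−3 (K_d = 0.1 at unit totals) and 1000
copies per tagged complex, which keeps free-subunit copy numbers in the
hundreds. This choice is made on mean-field-validity grounds: mass action
requires many free copies of each species. At tight binding (e.g.
k_on = 1e6, same totals), free copies fall far below one per volume and the
stochastic system exchanges dramatically more slowly than mass action — a
dissociated pair almost always rebinds before any other free partner exists
(geminate rebinding). Because the closed form is k_on-independent, testing
at moderate affinity still tests the same predicted curve. The study runs
200 replicates and compares the ensemble mean to tanh(k_off·t/2) in units of
the standard error of the mean.

### Geminate-rebinding limitation

The previous paragraph doubles as a caveat about the assay itself: in
compartments or complexes with very few free subunit copies, observed
exchange can be much slower than the mass-action prediction, and a k_off
inferred via the closed form would be an underestimate. The package
documents but does not correct for this regime; the stochastic simulator can
be used to explore it.

## 3. Synthetic measurement model

`sample_series` emulates label-ratio quantification by mass spectrometry:

- Each time point's true ratio R is multiplied by `n_peptides` independent
  log-normal deviates (median-centered, σ_log = √ln(1 + cv²)), one per
  quantified peptide; the reported value is the **median** across peptides
  and the reported uncertainty is the scaled median absolute deviation
  (1.4826·MAD), mirroring robust peptide-to-protein roll-up.
- t = 0 is passed through as an exact 0 (no hybrid signal exists to
  mis-quantify at mixing).
- Values at or below a detection floor are flagged `censored` but never
  dropped; the estimator excludes them with a logged count.

Defaults: cv = 0.15 (typical peptide-level ratio CV for label-based
quantification), n_peptides = 5 (a modest, common peptide count per
protein). Multiplicative log-normal noise is used because MS ratio errors
are heteroscedastic and roughly constant on the log scale.

What the generator does **not** emulate: missing peptides/points, ratio
compression from co-isolation, incomplete metabolic labeling, tag effects on
kinetics, protein synthesis/degradation during the time course, and
purification losses (assumed to cancel in the within-sample ratio).

## 4. Estimator

`ExchangeModel(series).fit()` minimizes the (optionally 1/σ²-weighted) sum of
squared residuals of the untransformed R against tanh(k_off·t/2), over
log10 k_off:

1. coarse 21-point grid on log10 k ∈ [−8, −1];
2. bounded scalar minimization around the best grid point (expanding window
   within [−10, 0], xatol = 1e−11);
3. polish by bracketing root-finding on the analytic objective gradient
   (xtol = 1e−14), which recovers noiseless data to machine precision —
   bounded minimization alone stalls at ~√ε relative accuracy.

Fitting in log10 k respects the parameter's natural scale; fitting R (not a
transform of it) keeps the objective well defined at R = 0 and R ≥ 1.
Censored points are excluded; at least two points with t > 0 are required.
If every usable point is 0, the fit reports non-convergence with a
detection-limit-based upper bound on k_off instead of a point estimate.

**Uncertainty** is a residual bootstrap on the log scale: residuals
ln(R_i/R̂_i) over points with positive data and prediction are resampled with
replacement and reapplied multiplicatively, each replicate refit on a dense
801-point grid with parabolic vertex refinement (vectorized), and the 95% CI
taken from the 2.5/97.5 percentiles (widened, if needed, to contain the
point estimate). The log-scale scheme matches the multiplicative
heteroscedastic noise; a coverage study run before freezing defaults (100
datasets at each of k_off = 1e−5, 1e−4, 1e−3, cv = 0.1, the 9-point default
design) showed an additive-residual bootstrap badly undercovers
(42–80%), while the log-scale scheme achieves ≥95% empirical coverage with
median relative errors of 3–5%. Default n_boot = 500 (percentile CIs
stabilize by a few hundred replicates at this noise level).

## 5. Numerical choices

- `invert_R` uses the exact inverse k_off = [ln(1+R) − ln(1−R)]/t via
  `log1p`, accurate for small R; a log-space bisection serves as an
  independent oracle in the tests.
- `sensitivity` computes sech² as 2e^(−u)/(1 + e^(−2u)) squared-free form to
  avoid overflow deep in saturation.
- `equilibrium_split` solves the binding quadratic with two
  cancellation-free branches: the standard stable root for weak binding,
  and, when the complex takes more than half the limiting subunit, a
  reformulated quadratic in the limiting *free* concentration — this keeps
  detailed balance (k_on·[A][B] = k_off·[AB]) satisfied to 1e−10 relative
  even at k_on/k_off ratios of 1e14.
- All CSV output uses `%.17g` so round trips are bit-exact.

## 6. Study sizes

The bundled verification (`scripts/acceptance.py`) uses: a 17-point 8-hour
grid for ODE agreement at 3 rates × 3 k_on values; a 41-point horizon of
15/k_off for the propositions; 200 stochastic replicates at 1000 copies per
complex; and 3 × 100 noisy datasets (each with 500 bootstrap replicates) for
the recovery/coverage study. These sizes were chosen so the whole script
completes in under a minute while keeping Monte-Carlo error small relative
to the effects measured.

## 7. Known limitations

- Heterodimers only; higher-order stoichiometries and multi-step assembly
  pathways are out of scope.
- The closed form requires equivalent lysates; unequal totals need the ODE
  simulator and lose the concentration-free property.
- No modeling of synthesis/degradation, incomplete labeling, tag-perturbed
  kinetics, or purification artifacts (Section 3).
- Mean-field exchange breaks down at very low free-subunit copy numbers
  (Section 2); inferred k_off is then a lower bound on the true rate.
- k_off outside roughly [1e−7, 1e−2] s⁻¹ is poorly identified by practical
  sampling horizons (hours): too slow gives R ≈ 0 everywhere, too fast
  saturates before the first sample.
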