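# mase-kinetics

Forward models and estimation tools for measuring the **dissociation rate
constant k_off of a protein complex from subunit exchange**, the readout of a
metabolic-labeling / affinity-tag / mass-spectrometry assay.

## The problem

Protein complexes constantly dissociate into, and reassemble from, free
subunits. The dissociation rate constant k_off (s⁻¹) carries structural and
functional information, but classical measurements (surface plasmon
resonance, stopped flow) need highly purified, specifically modified
complexes, so k_off is known for very few complexes. A proteomics-friendly
alternative is to let two variants of a heterodimeric complex *AB* exchange
subunits in a mixed lysate: one lysate carries an affinity-tagged, isotopically
unlabeled variant (subunits A<sup>T</sup><sub>U</sub>, B<sub>U</sub>), the other an untagged, metabolically
labeled variant (A<sub>L</sub>, B<sub>L</sub>). After 1:1 mixing, dissociation/re-association
shuffles partners and produces hybrid complexes; affinity purification plus
quantitative mass spectrometry measures, at each sampling time,

R(t) = [A<sup>T</sup><sub>U</sub>·B<sub>L</sub>] / [A<sup>T</sup><sub>U</sub>·B<sub>U</sub>],

the hybrid-to-original abundance ratio among the tagged complexes.

## The model

For the reversible reaction A + B ⇌ AB with rate constants k_on
(conc⁻¹ s⁻¹) and k_off (s⁻¹), mixing *equivalent* lysates (complex at equal
concentrations in both) leaves the reaction at equilibrium: every free-subunit
concentration stays constant and the summed tagged-complex concentration is
conserved. The hybrid complex then grows by a linear first-order relaxation,
giving the closed-form progress curve

R(t) = (1 − e^(−k_off·t)) / (1 + e^(−k_off·t)) = tanh(k_off·t / 2).

R rises from 0 at mixing to 1 at exchange equilibrium and depends on k_off
**only** — neither k_on nor any concentration enters — so a measured R(t)
series identifies k_off directly: a complex with k_off = 10⁻³ s⁻¹ equilibrates
(R = 1) within two hours, while one with k_off = 10⁻⁵ s⁻¹ reaches only
R = 0.14 after eight hours.

The package provides:

- `mase.kinetics` — the closed form `predict_R`, its analytic inverse
  `invert_R`, the sensitivity ∂R/∂k_off (maximal at t ≈ 1.5434/k_off), and the
  equilibrium free/bound split of a lysate;
- `mase.simulate` — the full 8-species mass-action system (stiff ODE) and an
  exact event-driven stochastic engine, plus numerical verification of the
  equivalent-lysate propositions;
- `mase.measurement` — synthetic noisy ratio series (log-normal peptide-level
  noise, median-summarized) and sampling-time design;
- `mase.model` — `ExchangeModel.fit()` → `ExchangeResults`: least squares on
  the untransformed R scale with a log-scale residual bootstrap 95% CI;
- `mase.cli` — the `mase` command (`simulate`, `simulate-stochastic`,
  `sample`, `fit`, `curves`, `verify`).

## Worked example

Generate a synthetic 9-point, 8-hour exchange series for a complex with true
k_off = 10⁻⁴ s⁻¹ (10% peptide-level CV, 5 peptides per protein), then fit it:

```sh
mase sample --k-off 1e-4 --cv 0.1 --seed 11 --out series.csv
mase fit --input series.csv --n-boot 500 --seed 7 --out fit.json
```

which prints

```
Subunit exchange progress-curve fit
===================================
k_off             9.977921e-05 s^-1
95% CI (bootstrap) [8.836576e-05, 1.064957e-04] s^-1
half-exchange time 1.101e+04 s (3.058 h)
RSS               1.563135e-03
n points used     9
weighted          False
n_boot / seed     500 / 7
converged         True
```

The true rate 1.0×10⁻⁴ s⁻¹ is recovered within 0.3% and falls inside the
bootstrap interval; the half-exchange time ln(3)/k_off ≈ 3.1 h says when the
hybrid complex reaches half the original's abundance. The same pipeline is
available in Python:

```python
from mase import ExchangeModel, NoiseModel, default_design, sample_series

design = default_design(1e-5, 1e-3, n_points=9)          # seconds, starts at 0
series = sample_series(1e-4, design, NoiseModel(cv=0.1, seed=11))
res = ExchangeModel(series).fit(n_boot=500, seed=7)
print(res.summary())
res.plot()                                               # data + curve + band
```

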