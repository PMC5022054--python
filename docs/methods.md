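# Methods

## The model

`iltox` predicts the toxicity of an ionic liquid (IL) — treated as a fully
dissociated cation/anion pair — on the common response scale
`log10(1/C)` with C in mM, so larger values mean higher toxicity and the
five pooled endpoint kinds (EC50, LC50, IC50, MIC, MBC) share one axis.

The intrinsic (system-free) part is a linear free energy relationship
(LFER) over split cation/anion Abraham-type descriptors:

```
log 1/C = e_c·E_c + s_c·S_c + a_c·A_c + b_c·B_c + v_c·V_c + j⁺·J⁺
        + e_a·E_a + s_a·S_a + a_a·A_a + b_a·B_a + v_a·V_a + j⁻·J⁻ + c
```

where E is excess molar refraction (cm³ mol⁻¹/10), S dipolarity/
polarizability, A/B hydrogen-bond acidity/basicity, V the McGowan volume
(cm³ mol⁻¹/100) and J⁺/J⁻ the ionic-interaction descriptors. Descriptor
values are *inputs*: the package does not compute them from structures.

Different biological test systems respond with different sensitivity.
Pooling many systems into one regression therefore adds one indicator
(dummy) column Z_x per non-reference system, whose coefficient z_x is the
system's additive sensitivity offset. The system contributing the most
data points is the reference (z = 0); ties break lexicographically. In
sample, OLS with dummy coding makes z_x exactly the mean difference
between a system's observations and its intrinsic values — the package
asserts this identity in its tests.

Descriptor terms are screened by their two-sided t-test p-values:
backward elimination removes the single worst descriptor with p > 0.05
and refits, until all remaining descriptors are significant. The
intercept and the dummy columns are never candidates. Removing one term
per round is the conservative variant; with near-orthogonal descriptor
columns it coincides with removing all offenders at once.

On top of the pooled model, each system gets a linear calibration

```
observed ≈ α_x · (intrinsic + z_x) + β_x
```

fitted by simple OLS. The predictor *includes* z_x: that convention makes
the reference system's calibration exactly (α, β) = (1, 0) and makes the
calibrated predictor a strict refinement of the uncalibrated one (an OLS
projection can never raise the in-sample sum of squared errors, so
per-system identity-line R² never decreases). The z-free alternative is
available behind a flag (`eq5_predictor: without_z`) but is not the
default. Note that (z, α, β) are not jointly identifiable from
α·(v + z) + β alone — only the composite slope and offset are — so the
package fixes the convention z = mean(observed − intrinsic) first and
fits (α, β) second; α is identified either way.

The same two-stage procedure onboards a brand-new test system from a
handful of measurements (default minimum 5) against a frozen model.

## Packaged published model

The package ships the published nine-term pooled model
(E_c 2.254, S_c −2.545, A_c 0.646, B_c −1.471, V_c 1.650, J⁺ 2.917,
E_a −0.201, V_a 0.418, J⁻ 0.131, intercept −0.709; n = 1633, R² = 0.880,
SE = 0.465) and the 58-row per-system catalogue (R², SE, z, α, β, N) as a
CSV asset. Rows 45–52 are the exceptional systems that the pooled model
does not cover; rows 53–58 are the six algal growth-rate systems used as
the small-sample onboarding example. The catalogue is stored verbatim,
including the anomalous β = −1.05 of row 42.

Coverage screening uses R² ≥ 0.6, with a low-scatter exemption
(R² ≥ 0.55 and SE ≤ 0.35) that reproduces the retained MBC system with
R² = 0.59 / SE = 0.34; both knobs are configurable.

## Validation metrics

Observed-vs-predicted agreement uses the identity-line R²
(1 − SSE/SStot), which penalises bias, rather than the squared Pearson
correlation (available behind `kind="pearson"`), and SE = √(SSE/(n−2));
the fit SE convention √(RSS/(n−k)) is switchable to √(RSS/n) since
published SE conventions are often unstated. External predictions are
summarised by the trimmed MAE: the floor(0.05·n) points with the largest
absolute residuals are removed (ties by input order) and the MAE and SD
of the kept absolute residuals are classified against thresholds stated
as fractions of the training response range — good when
MAE ≤ 0.1·range and MAE + 3·SD ≤ 0.2·range, bad when MAE > 0.15·range or
MAE + 3·SD > 0.25·range, moderate otherwise. The thresholds are
config-exposed and always reported alongside the class.

## Synthetic data generator

The generator draws descriptor tables and multi-system panels with the
exact structure the pooled model assumes:

```
y = α_x · (x·coeffs + c + z_x) + β_x + ε,   ε ~ N(0, noise_sd²)
```

Defaults: the published coefficients with the three eliminated anion
terms at zero; noise_sd = 0.45 log units (the pooled residual scale of
multi-assay IL panels); z drawn uniformly on [−1.9, 2.8] (the span of the
catalogued sensitivities); α = 1 and β = 0 unless the calibration stage
is being exercised. Ion pairs are sampled uniformly with replacement;
everything is reproducible from the seed.

Cation descriptors: E ~ U(0, 1.3), S ~ U(0.6, 2.6), A ~ U(0, 0.6),
B ~ U(0, 0.9), J⁺ ~ N(1.0, 0.25²), and V = 0.6 + 0.1409·(chain length)
with chain length uniform on 2…14 CH₂ units plus small jitter — the
homologous side-chain effect, one CH₂ adding one McGowan increment.
Anion descriptors: E ~ U(−0.6, 0.3) (two-thirds of the mass at or below
zero, since anion excess molar refraction is near zero or negative),
S ~ U(0, 2), A ~ U(0, 0.5), B ~ U(0, 1.5), V ~ U(0.3, 2.2),
J⁻ ~ N(−0.3, 0.4²). Descriptors are drawn independently apart from the
chain-length device; real homologous series correlate V with E and S,
which the generator does not emulate. Study-scale runs use 200 cations
and 57 anions, matching the diversity of the curated IL database the
published model was built from.

What passing tests show: the estimators invert the generative model —
exact recovery without noise, nominal confidence-interval coverage with
noise, correct elimination behaviour, calibration recovery, metric
identities. What they do not show: performance on real assay data, where
descriptor errors, endpoint heterogeneity, inter-laboratory scatter and
mechanistically exceptional systems (enzyme inhibition, some
antimicrobial MIC/MBC panels) violate the single-surface assumption.

## Numerical choices and edge cases

- OLS via statsmodels; rank deficiency raises an error naming the
  collinear columns; constant descriptor columns are dropped with a
  warning before fitting.
- A perfectly fitted, exactly-zero coefficient has a 0/0 t statistic; its
  p-value is treated as 1 (not significant), so inert terms are
  eliminated rather than crashing the screen.
- Fitting requires n ≥ (number of columns + 2), the minimum for one
  residual degree of freedom.
- CSV I/O writes floats with 17 significant digits and reads with
  round-trip parsing, so write∘read is exact.
- Calibration requires ≥ 3 points and a non-degenerate predictor; a
  zero-variance intrinsic range is an error, not a silent α = 0.
- Ranking uses competition ranking (ties share the smaller rank, next
  rank skipped) with deterministic ion-id tie-breaking of the output
  order.
- The large-cation applicability flag defaults to V_c > 3.5 (a
  repository convention, roughly the volume of a trihexyl-substituted
  phosphonium head); it warns, never blocks.

## Problem sizes

The test suite and the acceptance script run on panels of 1 500–2 000
records over 8–44 systems, 50-replicate Monte-Carlo loops for elimination
and coverage rates, and 200-replicate loops for small-sample onboarding —
sizes at which every Monte-Carlo assertion has comfortable margins while
a full run stays in the seconds-to-minutes range.

## Known limitations

- The exact-recovery rate of the three-null-term elimination experiment
  is bounded near 0.95³ ≈ 0.86: each inert term independently survives a
  5 % significance screen with its type-I rate, so "exactly the three
  null terms eliminated" cannot be pushed to ≥ 0.9 at p = 0.05 no matter
  the sample size.
- The published per-system α/β cannot be re-derived here because the
  underlying curated measurements are not redistributed; they are carried
  as a packaged catalogue and used as ground truth for simulations.
- Hydrolysis, biodegradability and other secondary anion effects are not
  modelled; exceptional systems are flagged, not explained.
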