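# Methods

## The binding model

The injection-amount-dependent method treats the immobilized receptor as
a single class of *n*ₐ moles of homogeneous binding sites in fast
equilibrium with the mobile phase (longitudinal diffusion neglected).
For an injection of *n*_b = *c*·*V*_inj moles, the capacity factor
*k*′ = (*t*_R − *t*₀)/*t*₀ satisfies the linearization

    k' n_b / (1 + k') = n_a − k' V_m / K_A                (model line)

with *V*_m = *t*₀·*F*/1000 the void volume in litres. Ordinary
least-squares of *y* = *k*′*n*_b/(1+*k*′) on *x* = *k*′*V*_m over a
concentration series yields slope = −1/*K*_A and intercept = *n*ₐ.

Two limits anchor the model. As *n*_b → 0 the quadratic obtained by
inverting the line,

    V_m k'^2 + (V_m + n_b K_A − n_a K_A) k' − n_a K_A = 0,

factors as (V_m k' − n_a K_A)(k' + 1), recovering the
linear-chromatography retention *k*′ = *K*_A *n*ₐ / *V*_m. As *k*′ → ∞,
*y* → *n*_b: a heavily retained injection deposits its whole load on the
sites. The positive root of the quadratic is unique (the constant term
is negative), strictly decreasing and continuous in *n*_b — retention
falls monotonically with load, which is the qualitative signature the
simulator reproduces and the analysis flags when absent.

### Assumptions and their reach

- one site class, rapid equilibration, no site–site interaction;
- apex (peak-maximum) retention is the operative *t*_R. A tailing band's
  centroid elutes later than its apex; `peak_centroid` is exposed as an
  alternative retention measure but the pipeline defaults to the apex.
- the fit is unweighted OLS: no error model for the transformed points
  is assumed. Both Pearson's *r* and *r*² are reported, since either
  convention may be meant by a "correlation coefficient" in a fit report.

### Parameter extraction and uncertainty

`derive_parameters` maps (slope, intercept) to (*K*_A, *n*ₐ) and rejects
non-negative slopes (no saturable binding) and non-positive intercepts.
The standard error of *K*_A is propagated to first order (delta method):
se(*K*_A) = se(slope)/slope². These diagnostics never gate results.

Units: the intercept of the model line has dimension of moles, so *n*ₐ
is carried in mol throughout. Reports of binding-site amounts per
mobile-phase volume (mol·L⁻¹) found in the affinity-chromatography
literature correspond to *n*ₐ/*V*_m; this package does not perform that
division.

## Tunable parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| `t0` | min | 0.298 | sodium nitrite marker retention on the studied column |
| `flow_rate` | mL/min | 0.6 | binding-run flow rate |
| `V_inj` | L | 1e-5 (10 µL) | study injection volume |
| `snr_threshold` | — | 5 | peak must exceed 5× baseline-window SD |
| specificity `threshold` | — | 0.1 | control k′ above 10% of test k′ flags nonspecific retention |
| `sigma` | min | 0.05 | Gaussian width of simulated peaks |
| `tau` | min | 0.15 | exponential tail constant; τ>0 gives asymmetry>1 |
| `dt` | min | 0.002 | rendering grid step |
| `rel_sd_tr` | fraction | 0 | multiplicative retention-time noise SD |
| `detector_sd` | signal | 0 | additive white detector noise SD |

Minimum series size is 3 points (the studies used 8–10 concentrations
between 0.1 and 1.1 mM).

## The synthetic-data generator

`simulate.generate_series` inverts the model line exactly (the quadratic
above) to obtain the true *k*′ at each injected amount, perturbs the
retention time multiplicatively, *t*_R = *t*₀(1+*k*′)(1+ε) with
ε ~ N(0, `rel_sd_tr`) — matching the RSD-style repeatability metric used
for column QC — and optionally renders each injection as an
exponentially modified Gaussian (EMG) whose *mode* is placed at *t*_R,
with apex height proportional to *n*_b and additive white detector
noise. Replicate injections (the studies used triplicates) are averaged
at the *k*′ level, giving one point per concentration. All randomness
flows from one integer seed through `numpy.random.default_rng`;
identical seeds give bit-identical series.

What the generator emulates: load-dependent retention loss, tailing
peaks, a void-marker peak, retention and detector noise. What it does
not: band-profile physics (the EMG is a rendering convenience, not a
transport model — mass-overload band shapes from Wade–Thomas-type models
are out of scope), gradient elution, column ageing, mobile-phase
composition effects, or site heterogeneity. Passing recovery tests
therefore demonstrate the correctness of the estimator under the model's
own assumptions, not robustness to real columns that violate them.

## Numerical choices

- **Quadratic root**: solved with the cancellation-free branch of the
  quadratic formula (switching branch on the sign of the linear
  coefficient), so the positive root is accurate for all loads.
- **EMG placement**: the mode offset of an EMG relative to its Gaussian
  center has no closed form; it is found once per (σ, τ) by bounded
  scalar minimization of the negative density (`xatol` 1e-12, cached).
  With τ = 0 the shape degenerates to an exact Gaussian.
- **Baseline**: pooled median of the first and last 5% of samples —
  robust, deterministic, adequate for isocratic traces whose peak sits
  inside the middle of the window.
- **Apex**: global maximum of the baseline-corrected signal; exact ties
  resolve to the earliest sample. Detection requires ≥ 50 samples and a
  peak above 5× the baseline-window SD.
- **Integration bounds**: area (QC only) is trapezoidal between the
  first and last samples above 1% of apex height; asymmetry is the
  right/left half-width ratio at 10% height with linear interpolation of
  the crossings.
- **Degenerate inputs**: *t*_R < *t*₀ is an error for binding analysis
  but permitted (`allow_early=True`) in QC, where control-column runs
  legitimately elute at the void; *k*′ ≤ 0 points are excluded from the
  transform; duplicated *x* values degrade *r* but do not abort the fit;
  a non-negative fitted slope returns a fit with *K*_A/*n*ₐ unset rather
  than raising.

## Design choices where the design was open

- **Void time at the analysis flow rate.** Characterization and binding
  runs used different flow rates (0.2 vs 0.6 mL/min); the pipeline
  requires *t*₀ measured at the flow rate of the series being analyzed
  and takes it as an explicit input.
- **File dialect**: plain delimited text (comma or tab, optional single
  header line, time unit declared, default minutes). Vendor binaries are
  out of scope; users convert to text.
- **Immobilization yield** takes total supernatant protein as an
  explicit input: the published 18.42 mg g⁻¹ figure is not derivable
  from band fractions alone, and inventing the missing mass would bake
  an unverifiable constant into the code.
- **Stability probe** is a parameter, not a constant: the QC module is
  probe-agnostic.
- **Monte-Carlo recovery conditions**: 200 replicate studies of 10
  concentrations (0.2–1.1 mM at 10 µL) with 1% relative retention noise
  — a study size matching the experimental design, small enough that the
  whole suite runs in seconds.

## Known limitations

- The zafirlukast numbers in the source data are internally
  inconsistent: the published slope −4.02 × 10⁻⁶ implies
  *K*_A ≈ 2.49 × 10⁵ L·mol⁻¹, while 2.193 × 10⁵ is reported (≈13%).
  MK-571 shows smaller inconsistencies (≈3.7% in *K*_A, ≈0.8% in *n*ₐ).
  The extraction is algebraically exact, so these discrepancies are
  reported as-is and not tuned away.
- Raw experimental chromatograms are not available; retention times,
  correlation coefficients and stability RSDs can only be validated on
  synthetic data with known truth.
- Apex-based *k*′ on strongly tailing, noisy peaks is grid-limited: with
  the default 0.002-min step the end-to-end recovery error is ~0.01–1%,
  shrinking with the step.
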