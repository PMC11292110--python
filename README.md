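# affinichrom

Estimation of drug–receptor binding parameters from immobilized-receptor
chromatography by the **injection-amount-dependent method**, applied to
ligands of the cysteinyl leukotriene receptor type 1 (CysLTR1): the
reference antagonists zafirlukast, pranlukast and MK-571, and the plant
phenolic rosmarinic acid.

## The science

A receptor immobilized on a chromatographic support carries a fixed pool
of binding sites, *n*ₐ (mol). When a ligand is injected in amounts
*n*_b = *c*·*V*_inj comparable to *n*ₐ, the column is overloaded: part of
the site pool is occupied, the effective retention weakens, and the
capacity factor

&nbsp;&nbsp;&nbsp;&nbsp;*k*′ = (*t*_R − *t*₀) / *t*₀

falls as the injected amount rises (peaks also tail). For homogeneous,
fast-equilibrating sites this load dependence is linear in transformed
coordinates:

&nbsp;&nbsp;&nbsp;&nbsp;*k*′*n*_b / (1 + *k*′) = *n*ₐ − *k*′*V*_m / *K*_A

so a plot of *y* = *k*′*n*_b/(1 + *k*′) against *x* = *k*′*V*_m over a
concentration series is a straight line with slope −1/*K*_A and intercept
*n*ₐ. Here *t*₀ is the void time (sodium nitrite marker), *V*_m = *t*₀·*F*
the void volume, and *K*_A (L·mol⁻¹) the association constant. One
ordinary least-squares fit per ligand yields both parameters without
saturating the column, the method's advantage over frontal analysis.

The package covers the full path:

- `affinichrom.chromatogram` — two-column text chromatogram I/O, robust
  baseline, apex detection (with tailing asymmetry), centroid option;
- `affinichrom.column` — void time/volume and capacity factors;
- `affinichrom.binding` — the linearized transform, OLS fit, parameter
  extraction (*K*_A = −1/slope, *n*ₐ = intercept) and ligand ranking;
- `affinichrom.qc` — retention-time repeatability (RSD) and specificity
  against a bare-silica control column;
- `affinichrom.immobilization` — receptor load (mg per g of gel) from
  SDS-PAGE densitometry fractions;
- `affinichrom.simulate` — a synthetic-chromatogram generator with known
  ground truth (exact algebraic inversion of the overload model, tailing
  exponentially-modified-Gaussian peaks, retention and detector noise)
  used to validate parameter recovery end to end.

## Worked example

Extract the binding parameters from the published best-fit line for
rosmarinic acid (*y* = −1.376 × 10⁻⁶ *x* + 1.24 × 10⁻⁸):

```python
>>> from affinichrom import derive_parameters
>>> K_A, n_a = derive_parameters(slope=-1.376e-6, intercept=1.24e-8)
>>> print(f"K_A = {K_A:.4g} L/mol, n_a = {n_a:.3g} mol")
K_A = 7.267e+05 L/mol, n_a = 1.24e-08 mol
```

That is an association constant of 7.27 × 10⁵ L·mol⁻¹ — rosmarinic acid
binds the immobilized receptor more tightly than any of the three
reference antagonists — on a column carrying 1.24 × 10⁻⁸ mol of
accessible sites.

The numbered scripts under `analysis/` run the complete study on
synthetic data and write small tables under `results/`:

```sh
python analysis/01_simulate_studies.py    # render synthetic studies (scratch/)
python analysis/02_fit_binding.py         # detect peaks, fit, score recovery
python analysis/03_published_parameters.py# desk extraction + ligand ranking
python analysis/04_column_qc.py           # stability RSD, specificity report
python analysis/05_noise_recovery.py      # 200-replicate Monte-Carlo recovery
```

`02_fit_binding.py`, for example, prints per ligand the recovered
parameters and their relative error against the generating truth:

```
rosmarinic_acid: K_A = 7.291e+05 L/mol (truth 7.268e+05, err +0.32%),
                 n_a = 1.234e-08 mol (err -0.21%), r = -0.9999
```

i.e. with realistic retention noise (0.5% RSD) and a 0.002-min sampling
grid the full render → detect → fit pipeline recovers both parameters to
well under 1%.

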