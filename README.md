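# nmrmetab

Serum ¹H-NMR metabonomic profiling for group discrimination: a tested,
reusable implementation of the classic CPMG-serum workflow used to ask
whether tumour grade (or any group structure) leaves a readable signature in
the circulating metabolome.

The package is aimed at metabolomics practitioners who have frequency-domain
serum spectra (or want a fully synthetic, ground-truthed stand-in) and need
the complete chain:

1. **Synthetic cohort** — grade-labelled 500-MHz CPMG-style serum spectra
   built from a bundled 47-signature assignment library (45 metabolites plus
   residual-water/urea region markers), with known per-sample concentrations
   so every downstream stage can be validated against ground truth.
2. **Preprocessing** — chemical-shift referencing to the lactate doublet at
   δ1.33; integration into 0.002-ppm buckets over δ9.0–0.5 with removal of
   the residual-water (δ6.40–5.50) and urea (δ5.19–4.36) windows; total-sum
   normalization of each spectrum.
3. **Chemometrics** — mean-centred PCA and Pareto-scaled PLS-DA for the
   overview; pairwise OPLS-DA (one predictive + one orthogonal component)
   with R²X/R²Y, stratified 10-fold cross-validated Q² = 1 − PRESS/SS,
   a 200-label response permutation test, and CV-ANOVA.
4. **Differential metabolites** — per-bucket back-calculated correlation
   loadings r = corr(bucket, t_predictive), thresholded at the analytic
   Pearson critical value r_crit = t / √(t² + df) (0.576 at α = 0.05,
   df = 10), assigned to library metabolites by chemical-shift proximity and
   aggregated into a signed per-metabolite coefficient table.
5. **Pathway enrichment** — self-contained hypergeometric
   over-representation of the significant set against a bundled curated
   pathway annotation (raw p < 0.01 filter, BH-FDR reported alongside).

## Worked example

```python
import nmrmetab as nm

library = nm.load_library()
spectra, truth, manifest = nm.generate_cohort(nm.default_design(seed=1))
matrix = nm.preprocess_spectra(spectra, manifest)
res = nm.compare_groups(matrix, "BxPC-3", "SW1990", library)
```

Running `python examples/03_pairwise_differential.py` (which does exactly
this) prints:

```
BxPC-3 vs SW1990:  R2Y = 0.993   Q2 = 0.983
permutation test (n=200): p(Q2) = 0.0050
CV-ANOVA: F = 590.8, p = 3.48e-19
cutoff: |r| > 0.576

37 significant metabolites; strongest ten:
abbreviation                   name                  category         r  ambiguous
         Lac                Lactate glycolysis_glutaminolysis  0.974191       True
         Thr              Threonine      essential_amino_acid  0.974191       True
       β-Glc              β-Glucose glycolysis_glutaminolysis -0.959387      False
...
```

R²Y ≈ 0.99 and Q² ≈ 0.98 say the two-group model fits and cross-predicts
almost perfectly; p(Q²) = 1/201 means no permuted labelling matched the real
one, and CV-ANOVA agrees. Positive r means a higher level in SW1990 (the
second-named, +1-coded group): lactate, amino acids and glycolysis
participants are up in the well-differentiated group, glucose and choline
species down — matching the designed ground truth. The shared lactate /
threonine resonance at δ1.33 is reported with an `ambiguous` flag rather
than silently attributed.

The other example scripts cover cohort simulation (`01`), preprocessing and
the PCA/PLS-DA overview (`02`), and pathway enrichment (`04`). A thin CLI
(`nmrmetab simulate|preprocess|diff|enrich|run-all`, see
`nmrmetab --help`) wraps the same functions; `nmrmetab run-all --out DIR`
writes the normalized matrix, score tables, per-comparison diagnostics,
coefficient tables, enrichment tables and a JSON run manifest,
byte-identically for a fixed seed.

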