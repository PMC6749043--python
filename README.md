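# nmrmetab

A tested, reusable Python pipeline for ¹H-NMR serum metabolomics of the
spontaneously hypertensive rat (SHR) model: spectral preprocessing,
OPLS-DA-based multivariate modelling with honest validation statistics,
univariate biomarker selection, and pathway-impact screening. Because no
raw spectra are deposited for this kind of study, the package ships a
synthetic-cohort generator whose group-level fold changes are
parameterized from the published biomarker tables, so every stage of the
analysis is exercised end to end on data with known ground truth.

It is written for metabolomics analysts who want the standard serum-NMR
workflow as a scriptable library rather than a point-and-click tool, and
for methodologists who want each step testable in isolation.

## The analysis

Given spectra `(δ, intensity)` with group labels, the pipeline applies:

1. **Water-region exclusion** — points with δ ∈ [4.33, 5.50] ppm dropped.
2. **Adaptive binning** — variable-width bins targeting a mean width of
   0.015 ppm, with boundaries moved to local minima of the cohort-mean
   spectrum so peaks are not split; each cell is a trapezoidal integral.
3. **Probabilistic quotient normalization (PQN)** — each sample divided by
   the median of its feature-wise quotients against the median reference
   spectrum, correcting dilution differences.
4. **Mean centering + pareto scaling** — each column centered and divided
   by √s, leaving variance equal to the pre-scaling standard deviation s.
5. **PCA and OPLS-DA** — the supervised model splits X-variation into one
   class-predictive component and k class-orthogonal components (NIPALS
   orthogonal signal correction). Reported statistics: R²X, R²Y, Q² from
   repeated stratified two-fold cross-validation, and a permutation test
   (default n = 2000) with p = (1 + #{Q²_perm ≥ Q²_obs})/(n + 1).
6. **Biomarker selection** — per-metabolite window integrals, two-sample
   t-tests with Benjamini–Hochberg adjustment, fold changes FC =
   mean(case)/mean(reference), VIP from the OPLS-DA model (mean VIP² = 1),
   and the selection rule p < 0.05 ∧ VIP > 1. Potential treatment
   biomarkers are metabolites selected in both the disease and treatment
   contrasts whose FC crosses 1 in opposite directions (the reversal rule).
7. **Pathway screening** — hypergeometric over-representation plus a
   topology impact score (sum of relative betweenness centralities of
   matched compounds); pathways with impact > 0.1 are retained.

## Worked example

Applying the selection and reversal rules to the packaged biomarker tables
(the transcribed disease and treatment contrasts) and screening pathways:

```python
from nmrmetab import biomarkers as bm, pathways as pw
from nmrmetab.data import fixture_path, TABLE1, TABLE2

t1 = bm.load_biomarker_table(fixture_path(TABLE1), "SHR-N_vs_WKY-N")
t2 = bm.load_biomarker_table(fixture_path(TABLE2), "SHR-H_vs_SHR-N")
print(len(bm.select_biomarkers(t1)), len(bm.select_biomarkers(t2)))
shared = bm.shared_reversed(t1, t2)
print(len(shared.metabolites), sorted(shared.metabolites))
for r in pw.screen_pathways(pw.analyze_pathways(shared.metabolites))[:2]:
    print(f"{r.name}: impact={r.impact:.2f}, p={r.enrichment_p:.3f}")
```

prints

```
28 20
13 ['Alanine', 'Asparagine', 'LDL/VLDL', 'glucose', 'glutamate',
    'glutamine', 'lactate', 'methionine', 'myo-Inositol', 'serine',
    'threonine', 'tyrosine', 'valine']
D-Glutamine and D-glutamate metabolism: impact=1.00, p=0.039
Alanine, aspartate and glutamate metabolism: impact=0.58, p=0.027
```

i.e. all 28 disease-contrast and all 20 treatment-contrast records pass
the p/VIP rule, 13 metabolites are shared with a reversed fold-change
direction (the plain intersection has 17 — the reversal requirement
removes isoleucine, lysine, pyruvate and N,N-dimethylglycine, whose
changes do not flip under treatment), and glutamine/glutamate metabolism
tops the impact screen because its central node is a matched biomarker.

A full synthetic run — simulate a three-group cohort, preprocess, model,
select, screen — is one call:

```bash
nmrmetab run-all --out runs/demo --seed 1
```

which writes spectra, feature matrices at each stage, model summaries
(R²X/R²Y/Q²/permutation p per contrast), biomarker tables, pathway results
and a manifest with per-file checksums for reproducibility.

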