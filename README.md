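# crossdecomp

Side-by-side comparison of three multivariate two-block methods — canonical
correlation analysis (CCA), partial least squares correlation (PLSC) and
partial least squares regression (PLSR) — for brain-behavior style analyses:
an n × p "brain" block against an n × m "behavior" block, with confound
residualization, permutation-based component significance, structure
coefficients (loadings), explained-variance profiles, and a quantitative
cross-method convergence/divergence report.

A synthetic-cohort generator is included that emulates the structure of a
large pediatric neuroimaging study (87 regional gray-matter volumes = 68
cortical + 19 subcortical; 4 mutually orthogonal psychopathology dimensions:
general, ADHD, conduct, internalizing; covariates for age, sex,
race/ethnicity, scanner manufacturer and optionally intracranial volume),
with planted cross-block components and full ground truth for recovery
tests.

## Layout

| module | contents |
| --- | --- |
| `crossdecomp.blocks` | `DataBlock`, `ConfoundTable`, sample-ID alignment |
| `crossdecomp.preprocess` | confound encoding/residualization, standardization, VIF |
| `crossdecomp.decomposition` | `fit_cca` / `fit_plsc` / `fit_plsr`, shared `CrossFit` model, structure coefficients |
| `crossdecomp.inference` | per-component rho, permutation testing, explained variance |
| `crossdecomp.comparison` | component alignment across methods, divergence report |
| `crossdecomp.synthetic` | generator spec, planted components, confound model, ground truth |
| `crossdecomp.pipeline` / `crossdecomp.cli` | `RunConfig`, end-to-end driver, `crossdecomp` CLI |

Method semantics in brief: CCA maximizes the *correlation* of paired latent
scores (whitened; invariant to invertible within-block re-mixing), PLSC
maximizes their *covariance* (one SVD of the cross-covariance, no
deflation), and PLSR is the asymmetric predictive variant (sequential
X-weights with X-only deflation, exposing a p × m coefficient matrix).
Components are permutation-tested by refitting on row-shuffled behavior
blocks; p-values use the add-one convention `(1 + #{null >= obs}) / (1 + B)`.

## CLI

```bash
# generate a synthetic cohort (writes brain.csv, psych.csv, confounds.csv, truth.json)
crossdecomp simulate --n 2000 --seed 1 --out sim/

# full pipeline on those files: preprocess, fit + permutation-test all three
# methods, write the cross-method comparison
crossdecomp run-all --x sim/brain.csv --y sim/psych.csv \
    --confounds sim/confounds.csv -B 1000 --seed 1 --out run/

# or in one step from the built-in generator
crossdecomp run-all --synthetic-n 2000 --seed 1 -B 1000 --out run/

# individual stages
crossdecomp fit      --x sim/brain.csv --y sim/psych.csv --method cca --out run/
crossdecomp permtest --x sim/brain.csv --y sim/psych.csv --method plsc -B 1000 --out run/
crossdecomp compare  --x sim/brain.csv --y sim/psych.csv --figures --out run/
```

Outputs: per-method fit JSONs and loading TSVs, permutation reports
(JSON + TSV), VIF tables, and `comparison.json` /
`comparison_cosines.tsv` with pairwise component alignments. Every artifact
embeds the config hash and seed; identical config + seed reproduces results
byte-for-byte. Exit codes: 0 success, 2 validation error, 3 numerical
failure.

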