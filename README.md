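# exposome

Analysis toolkit for multidimensional social-exposome studies of brain
health: questionnaire-to-composite scoring, a one-factor maximum-likelihood
structural equation model (SEM) of clinical outcomes, bootstrap
meta-regression comparing the cumulative latent score against individual
dimensions, summary-statistics group comparisons, and ROI-to-ROI
connectivity association with per-ROI FDR and binarized degree centrality.
A seeded synthetic-cohort generator makes the whole pipeline testable
without any external data.

## Modules

| module | what it does |
|---|---|
| `exposome.synthetic` | seeded cohorts: items on heterogeneous native scales loading on one latent adversity factor, outcomes, demographics, missingness (MCAR / MAR-on-age), connectomes, motion traces |
| `exposome.scoring` | chained predictive-mean-matching imputation, min-max scaling with polarity flips, ten dimension composites in [0, 1], outcome inversion, per-group feature rescaling |
| `exposome.sem` | RAM-parameterized one-latent ML SEM with analytic gradients: standardized solutions, CFI/TLI/RMSEA/SRMR, factor scores (regression / Bartlett), modification indices, case bootstrap |
| `exposome.compare` | cross-validated Lasso per outcome, effect metrics (R², Cohen's f², MSE, MAE), paired bootstrap of SEM path vs Lasso R², fixed-effect meta-regression with moderator Wald test |
| `exposome.group_stats` | one-way ANOVA, eta-squared, Pearson chi-square, pooled moments and proportions straight from published (n, mean, SD) summaries |
| `exposome.connectome` | Fisher z, per-edge OLS with nuisance covariates, per-ROI Benjamini–Hochberg masks, degree centrality, FD scrubbing and SNR/tSNR quality control |

## Command line

```bash
exposome simulate   --spec cohort.yaml --seed 7 --out cohort/
exposome score      --items cohort/items.csv --meta cohort/meta.tsv --out scores.csv --seed 7
exposome sem        --scores scores.csv --outcomes cohort/outcomes.csv --bootstrap 400 --seed 7
exposome compare    --scores scores.csv --outcomes cohort/outcomes.csv --bootstrap 400 --seed 7 --out table2.csv
exposome table1     --summaries summaries.csv
exposome connectome --matrices conn.npz --scores scores.csv --q 0.05 --out degree.tsv
```

`cohort.yaml` holds the generator parameters (`n_per_group`,
`latent_mean_by_group`, `loading_by_dimension`, `path_by_outcome`,
optional `missingness`, ...); see `tests/test_cli.py` for a worked
example.

## Conventions

* Scaled items and dimension scores follow "higher = less adversity";
  items coded the other way are polarity-flipped during scaling.
* Functional-ability and neuropsychiatric outcomes are inverted
  (`max − value`) so all outcome associations share a direction.
* Covariances use the n − 1 denominator; the SEM chi-square is
  (n − 1) · F_ML, and RMSEA uses n − 1.
* The latent factor is identified by fixing the `access_healthcare`
  loading to 1; standardized solutions rescale to unit latent variance.
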