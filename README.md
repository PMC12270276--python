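# gutbrainlink

A tested, reusable implementation of a multistage microbiota–gut–brain
linkage analysis: untargeted-metabolomics QC filtering, first-component
PLSR between a microbe abundance and the metabolite matrix (with a
permutation null and top-20% loading selection), resting-state fMRI
metrics (ALFF, fALFF, ReHo, FCD, VMHC), covariate-adjusted partial
Spearman correlation screens with BH-FDR, bootstrap mediation analysis,
and hypergeometric pathway over-representation — plus a synthetic-cohort
generator that plants every effect the analysis is designed to detect, so
the whole chain is testable without external data.

## Modules

| Module | Purpose |
| --- | --- |
| `gutbrainlink.synth_cohort` | Synthetic subject tables, peak-area panels, and band-limited 4D volumes with known ground truth (planted group shifts, microbe→metabolite loadings, mediation chains, labeled QC-filter failures) |
| `gutbrainlink.metabolome_qc` | Filter cascade (QC/blank ratio < 3 removes, QC RSD > 30% removes, presence ≥ 80% keeps), zero imputation (min positive / 5), QC-mean normalization, glog, z-scoring |
| `gutbrainlink.rsfmri_metrics` | The five spontaneous-brain-function maps on masked 4D data, whole-mask standardization to mean 1, band-pass utility, cluster-mean extraction |
| `gutbrainlink.plsr_link` | Closed-form first PLS component for a univariate response, one-sided permutation p (add-one formula), contribution loadings, PLSR+/PLSR− selection |
| `gutbrainlink.assoc_stats` | Mann–Whitney U (tie-corrected normal approximation + exact enumeration), partial Spearman on rank-residualized data, BH-FDR, correlation screens |
| `gutbrainlink.mediation` | Three-model OLS mediation (a, b, c, c′ with c = a·b + c′ exactly), percentile bootstrap CI, screen over chained candidates |
| `gutbrainlink.enrichment` | Upper-tail hypergeometric over-representation against a user-supplied annotation map |
| `gutbrainlink.pipeline` / `gutbrainlink.cli` | End-to-end orchestration with a YAML config, per-stage TSV/JSON outputs, and a SHA-256 manifest |

Notable conventions (documented in each module): zeros are the missingness
code in peak tables; the glog λ defaults to each column's minimum positive
value; ALFF/fALFF use a single-sided `2|FFT|/T` amplitude spectrum with the
DC bin excluded; FCD counts strictly-greater correlations with self
excluded; ReHo uses Kendall's W without tie correction; VMHC mirrors across
the first array axis midline.

## CLI

```bash
# generate a fully synthetic study with known ground truth
gutbrainlink simulate --seed 7 --out cohort/

# QC cascade on a raw peak-area panel (TSV with a role column: sample|qc|blank)
gutbrainlink qc --panel cohort/panel_positive.tsv --mode positive --out qc/

# metric maps from a 4D NIfTI + mask (+ optional cluster labels)
gutbrainlink metrics --bold bold.nii.gz --mask mask.nii.gz --tr 2.0 \
    --metric alff,falff,reho,fcd,vmhc --out maps/

# PLSR linkage between a microbe column and the processed z-matrix
gutbrainlink link --zmatrix qc/qc_positive_zmatrix.tsv \
    --subjects cohort/subjects.tsv --genus microbe --n-perm 5000 --seed 7 \
    --out link/

# correlation screen, mediation, enrichment
gutbrainlink correlate --features f.tsv --targets t.tsv --covars c.tsv --out screen.tsv
gutbrainlink mediate --subjects s.tsv --candidates c.tsv --n-boot 5000 --seed 7 --out med.tsv
gutbrainlink enrich --selected sel.txt --annotations map.tsv --out enr.tsv

# the whole pipeline from one YAML config (add --validation to repeat the
# adjusted analyses with extra nuisance covariates)
gutbrainlink run --config cfg.yaml --out results/
```

A minimal pipeline config:

```yaml
subjects_path: cohort/subjects.tsv
panel_paths:
  positive: cohort/panel_positive.tsv
  negative: cohort/panel_negative.tsv
annotation_path: cohort/annotations.tsv
microbe_column: microbe
n_perm: 5000
n_boot: 5000
seed: 7
```

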