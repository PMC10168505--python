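# waverep

Unsupervised representation learning on physiological waveforms
(spirograms and photoplethysmograms) with a downstream genetic-discovery
pipeline, plus a fully synthetic cohort simulator so every stage is
testable at desk scale.

The pipeline has three steps:

1. **Encode** — a convolutional VAE learns low-dimensional encodings of
   waveforms. Three presets: `spinc` (2-channel volume-time + flow-time
   spirogram, 5 latents), `rspinc` (flow-volume curve with the five
   spirogram expert-defined features — FEV1, FVC, FEV1/FVC, PEF,
   FEF25-75 — injected at the decoder input, 2 latents, decoder input
   width 7, so the latents carry only residual signal), and `plenc`
   (100-sample PPG pulse, 5 latents). A PCA baseline provides the
   reconstruction-error comparison.
2. **Associate** — per-coordinate GWAS with covariate adjustment
   (per-variant OLS with covariates projected out of phenotype and
   dosage), optional rank-based inverse-normal transform, greedy LD
   clumping at p <= 5e-8 / r^2 < 0.1, and 250 kb locus merging.
3. **Combine** — per-coordinate pruning+thresholding PRSs are linearly
   combined into a disease-specific PRS by logistic (or linear)
   regression on a labeled cohort; evaluation covers AUC-ROC, AUC-PR,
   correlations, top/bottom percentile prevalence, and paired-bootstrap
   method comparison (300 reps, 95% CI).

The `synthetic` module generates cohorts with the statistical structure
the method assumes: genotypes with block LD (calibrated Gaussian-copula
thresholding), heritable latent factors with retained ground truth,
parametric spirogram/PPG shapes driven by those factors, covariates, and
liability-threshold disease labels.

No GPU or deep-learning framework is required: the VAE runs on a small
reverse-mode autodiff engine over numpy (`waverep/_autodiff.py`),
deterministic given a seed.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance suite
(VAE-vs-PCA reconstruction, GWAS calibration, causal-variant recovery
through learned encodings, the encoding-PRS-beats-EDF-PRS comparison,
few-label robustness, residual-encoding correlation bounds, and oracle
cross-checks). It trains several small VAEs and takes ~10-15 minutes on
one CPU; the unit suites run in ~2 minutes.

## CLI

```bash
waverep simulate --n 2000 --m 200 --n-factors 3 --h2 0.4 \
    --prevalence 0.1 --seed 1 --out-dir cohort/

waverep preprocess-spiro --in cohort/spiro_volume.tsv \
    --out cohort/flow_volume.tsv --qc-report cohort/spiro_qc.tsv
waverep preprocess-ppg --in cohort/ppg.tsv --out cohort/ppg_clean.tsv \
    --edfs cohort/ppg_edfs.tsv

waverep train --modality spinc --curves cohort/spiro_volume.tsv \
    --curves2 cohort/spiro_flow.tsv --seed 1 --out model.npz
waverep encode --model model.npz --curves cohort/spiro_volume.tsv \
    --curves2 cohort/spiro_flow.tsv --out encodings.tsv
waverep traverse --model rspinc.npz --edfs 3.1,4.0,0.78,7.5,3.2 \
    --coordinate 0 --out traversal.tsv
waverep pca --curves cohort/ppg.tsv --k 5 --out basis.npz

waverep gwas --dosages cohort/dosages.tsv --variants cohort/variants.tsv \
    --phenotypes encodings.tsv --phenotype coord1 --inverse-normal \
    --out sumstats.tsv
waverep clump --dosages cohort/dosages.tsv --variants cohort/variants.tsv \
    --sumstats sumstats.tsv --out loci.bed
waverep prs score --dosages cohort/dosages.tsv \
    --variants cohort/variants.tsv --betas betas.tsv --out scores.tsv
waverep prs combine --profile profile.tsv --labels cohort/covariates.tsv \
    --label-column disease --out weights.tsv
waverep prs evaluate --scores scores.tsv --labels cohort/covariates.tsv \
    --label-column disease
waverep prs compare --scores-a a.tsv --scores-b b.tsv \
    --labels cohort/covariates.tsv --label-column disease --seed 1
```

All tabular I/O is plain TSV; genotypes can also be written/read as VCF
with a DS (dosage) FORMAT field; loci are exported as 0-based half-open
BED.

## Notes on scope

- Association uses covariate-adjusted per-variant OLS (synthetic cohorts
  have no relatedness or population structure; mixed-model machinery is
  deliberately out of scope), and PRSs use raw clumped-hit betas.
- QC conventions: spirogram flow/volume ranges [-10, 20] L/s and
  [-5, 10] L inclusive; >= 20% nonzero flow samples; acceptability flag
  filtering before the 0.5% FEV1/FVC/PEF tail filter; PPG cohort QC keeps
  waveforms whose min/max/mean/median all fall within the cohort's
  [0.1, 99.9] percentile bounds.
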