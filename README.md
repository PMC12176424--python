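# conjradiomics

Color-free radiomic analysis of conjunctiva photographs for anemia
screening — with a synthetic conjunctiva-phantom cohort generator so the
entire analysis is reproducible and testable without clinical data.

## The problem

Anemia screening from smartphone photos of the conjunctiva (the inner
eyelid and the white of the eye) usually relies on *pallor*: color-based
estimates that are fragile across devices and lighting. An alternative is
to discard color entirely and ask whether the **spatial texture** of the
conjunctival microvasculature — visible as fine dark vessel structure —
separates anemic from nonanemic individuals. This package implements that
analysis end to end for researchers in mHealth imaging and radiomics:

- **texture radiomics** on grayscale photos within a region-of-interest
  mask: first-order statistics and the four standard gray-level matrix
  families (GLCM, GLRLM, GLSZM, GLDM), computed on the original image and
  on Laplacian-of-Gaussian and undecimated Haar wavelet filtered images
  (510 features per photo with the default configuration);
- **stability feature selection**: random-forest Gini-importance rankings
  across seeds; the 20 features that persistently rank high are kept;
- **classification**: a fully connected 20-50-50 ReLU network trained
  with ADAM on SMOTE-balanced training data;
- **evaluation statistics**: WHO age/sex hemoglobin cutoffs, Mann-Whitney
  AUC with DeLong/Wald confidence intervals, the DeLong test for
  correlated ROC curves, Kruskal-Wallis across device subgroups,
  chi-square/Fisher tables, and multivariate linear/logistic association
  models (odds ratios per radiomic feature);
- a **phantom cohort generator** producing conjunctiva-like grayscale
  photos + masks + metadata with a controllable ground-truth class
  effect (anemic = sparser, fainter vessel strokes), three smartphone-like
  device profiles, and bit-identical reproducibility under a seed;
- an **edge-method resolution estimator** (FWHM of the line spread
  function derived from the edge spread function).

The core ROC statistic is the Mann-Whitney AUC
`AUC = (wins + ties/2) / (n_pos * n_neg)` with DeLong
structural-component variance for Wald CIs and paired model comparison;
selection stability is defined as appearing in the importance top-k in at
least a fraction θ of seeded forest fits.

## Worked example

```bash
python examples/04_run_pipeline.py
```

simulates 60 participants (6 photos each), runs both conjunctival regions
separately, and prints:

```
palpebral  test AUC 0.992 [0.980, 1.000] (54 anemic / 54 nonanemic photos)
           top features: ['Wavelet-H|GLCM|Correlation', 'LoG-sigma-1|GLDM|DependenceEntropy', 'Wavelet-H|GLCM|Idmn']
bulbar     test AUC 0.992 [0.977, 1.000] (54 anemic / 54 nonanemic photos)
           top features: ['Wavelet-H|GLCM|Correlation', 'LoG-sigma-1|GLDM|DependenceEntropy', 'Wavelet-H|GLCM|DifferenceAverage']
palpebral vs bulbar DeLong p = 0.944
```

Reading: with the phantom's strong planted class effect (anemic
participants rendered with ~half the vessel density and contrast), both
regions' held-out photo-level AUCs are high, high-pass wavelet texture
features dominate the stable selection, and the two regions' ROC curves
do not differ significantly — the signal is present in both. Other
examples cover cohort simulation (`01`), single-photo feature extraction
(`02`), the resolution estimator (`03`), and the statistics toolbox
(`05`).

A thin CLI mirrors the stages:

```bash
conjradiomics simulate --out out_cohort --seed 1     # photos + masks + CSV
conjradiomics run-all  --out out_run    --seed 1     # full pipeline
conjradiomics evaluate --scores out_run/scores_palpebral.csv --out out_eval
```

`extract`, `select` and `train` run the stages individually; `select` and
`train` resume from the feature tables `extract` writes, and every stage
derives its seed from the master seed, so stage-wise and `run-all`
executions produce identical outputs.

## Layout

```
src/conjradiomics/
  phantom.py      # synthetic cohort + photo renderer + device profiles
  image_prep.py   # grayscale, standardization, LoG/wavelet, quantization, FWHM
  texture.py      # GLCM/GLRLM/GLSZM/GLDM + first-order features
  features.py     # table assembly, split, imputation, scaling, selection
  classifier.py   # SMOTE, 20-50-50 network, randomized search
  stats.py        # WHO labels, AUC/DeLong/Kruskal-Wallis, regressions
  pipeline.py     # seeded end-to-end orchestration, manifests, access log
  cli.py          # simulate | run-all | evaluate
docs/methods.md   # models, parameters, conventions, limitations
examples/         # one short narrative script per capability
```

See `docs/methods.md` for the full model description, parameter defaults
and the phantom's scope and limitations.
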