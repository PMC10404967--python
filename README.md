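# hiset

Hybrid strategies for respiratory sound (crackle / wheeze / normal)
classification, built as a tested, reusable library and CLI. Everything runs
on synthetic labeled respiratory cycles generated by the package itself, so
no dataset download is required; real ICBHI-format recordings (WAV +
4-column cycle annotations) are supported too.

## What is inside

| Module | Contents |
| --- | --- |
| `hiset.signal_io_synth` | ICBHI-format WAV/annotation loading, cycle segmentation under 2/3/4-class label schemes, min-max normalization, seeded synthetic cycle/dataset generation |
| `hiset.decomposition` | EMD sifting, paired-noise ensemble EMD (SEEMD), spectral-domain VMD with dual ascent, five distance-metric similarity indices, similarity-threshold mode-number selection |
| `hiset.granger_mvar` | L2 multivariate autoregressive fitting (normal equations with a pseudo-inverse fallback) and Granger coefficient features over IMF channels |
| `hiset.feature_selection` | per-mode descriptors, ensemble Granger+IMF feature assembly, SVM-RFE ranking |
| `hiset.metaheuristics` | Harris Hawks optimization, pliable (self-adaptive scale) differential evolution with binary mode, the nested HHO-tuned DE hybrid, grey wolf and grasshopper optimizers |
| `hiset.classifiers` | extreme learning machine (+ residual regression mode), K-SVD, realm-revamping sparse-representation classifier, KL-sparse autoencoder, GWO-tuned SVC, sensitivity/specificity/accuracy reports |
| `hiset.pipelines` | the six end-to-end strategies under stratified seeded K-fold CV |

## CLI

```bash
hiset synth --scheme three_class --n 50 --seed 7 --out data/
hiset decompose recording.wav --method dmvmd --metric manhattan
hiset optimize --algo hho-sfpde --objective sphere --dim 10 --seed 1
hiset run --strategy dmvmd_elm --scheme three_class --n 50 --folds 10 --seed 1
hiset eval preds.csv truth.csv
```

`hiset run` generates a synthetic dataset, runs one strategy under
cross-validation and prints aggregate sensitivity/specificity/accuracy;
`--config config.yaml` overrides any generator or strategy parameter.

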