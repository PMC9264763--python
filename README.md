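# rsibreast

Three-compartment restriction spectrum imaging (RSI) analysis of breast
diffusion-weighted MRI (DW-MRI), as a tested, reusable Python pipeline.

## The problem and who this is for

Dynamic contrast-enhanced breast MRI is sensitive but not specific: many
suspicious-looking benign lesions end up biopsied. DW-MRI measures water
mobility without contrast agent, and multi-shell acquisitions (here b = 0,
500, 1500, 4000 s/mm²) carry enough information to separate slowly
diffusing ("restricted") water — a signature of densely cellular tumor
tissue — from faster extracellular and flow-like water. This package is
for imaging scientists who want to run, test or extend the
fixed-spectrum three-compartment RSI analysis on simulated or real
multi-shell breast DWI, including the paired three-tissue
(malignant / benign / healthy) statistical comparison.

## The model

The voxel-wise signal versus diffusion weighting b is modeled as a linear
combination of three exponential decays with *fixed* diffusivities:

    S(b) = C1 + C2·exp(−b·D2) + C3·exp(−b·D3),
    D1 = 0 mm²/s (restricted), D2 = 1.5×10⁻³ mm²/s (hindered),
    D3 = 10.8×10⁻³ mm²/s (pseudo-diffusion)

Because the Dᵢ are fixed, only the non-negative signal contributions
C = (C1, C2, C3) are estimated, per voxel, by non-negative least squares
(NNLS) on the shell-averaged signal. Derived outputs are the combination
maps C1·C2 and √(C1·C2) and a conventional mono-exponential ADC map from
shells with b ≤ 1500 s/mm². Per-patient ROI medians (malignant lesion,
pooled benign lesions, 500-voxel contralateral healthy control) feed a
ranked two-way repeated-measures ANOVA and paired Wilcoxon signed-rank
tests with Bonferroni correction (α = 0.05).

Since no patient images are distributed, the package ships a first-class
synthetic-data module: multi-shell phantoms with known compartment maps,
log-normal tissue distributions matched to the published median/IQR
tissue contrast, ellipsoidal lesions, and Rician magnitude noise with its
natural background noise floor.

## Worked example

Noiseless round trip through the estimator — synthesize the 29-acquisition
series from the malignant median triple (0.32, 2.6, 0.13), shell-average,
and invert by NNLS:

```python
import numpy as np
from rsibreast import BREAST_PROTOCOL, synthesize_voxel_signal, DwiSeries
from rsibreast.preprocess import average_shells
from rsibreast.fit import build_design_matrix, fit_nnls_voxel

signal = synthesize_voxel_signal((0.32, 2.6, 0.13))
series = DwiSeries(signal.reshape(1, 1, 1, -1), BREAST_PROTOCOL.acquisition_bvals)
avg = average_shells(series)
coeffs, rnorm = fit_nnls_voxel(avg.data[0, 0, 0], build_design_matrix(avg.bvals))
print(coeffs)
```

prints `[0.32 2.6  0.13]` — the estimator recovers the generating
contributions to machine precision because the four-shell design matrix
has full column rank.

A full synthetic cohort, end to end:

```python
import rsibreast as rb

config = rb.PipelineConfig()            # 12 patients, 64×64×16 grid, σ = 0.02
cohort = rb.generate_cohort(12, config.phantom_config(), seed=0)
table, reports = rb.analyze_cohort(cohort, config)
stats = rb.run_statistics(table, config)
for r in stats["pairwise_wilcoxon"]["C1"]:
    print(r["comparison"], round(r["p_adjusted"], 4))
```

prints (seed 0):

```
C1: malignant vs benign 0.0015
C1: malignant vs healthy 0.0366
C1: benign vs healthy 0.2314
```

i.e. the restricted-diffusion compartment separates malignant tissue from
both benign lesions and healthy tissue, while benign and healthy do not
differ — the qualitative pattern the model is designed to expose. Fitted
medians are in units of the b = 0 98th-percentile normalization, so they
equal the ground-truth contributions divided by a common per-patient
scale factor; all cohort statistics are rank-based and unaffected by it.

The same pipeline is scriptable from the shell:

```
rsibreast run-all --seed 0 --outdir out/
rsibreast roi out/patients --outdir out/
```

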