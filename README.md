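# t2biexp

Biexponential T2 relaxometry of multi-echo MRI, built around the
temporomandibular-joint (TMJ) use case: does disk displacement leave a
quantitative trace in the relaxation behaviour of the surrounding
stomatognathic structures (disk, retrodiscal tissue, condylar bone
marrow, masticatory muscles, molar pulp)?

The package provides, as a library plus a thin CLI:

- **Signal model** — two-pool transverse relaxation
  `S(TE) = A_s·exp(−TE/T2_s) + A_l·exp(−TE/T2_l)` and its
  monoexponential special case, with component fractions
  `f_s = A_s/(A_s+A_l)`, `f_l = 1 − f_s`.
- **Synthetic phantoms & cohorts** — seeded multi-echo volumes (NIfTI)
  whose voxels draw from published reference tissue distributions
  (7 structures × 2 clinical groups, 18 vs 32 joints), with Gaussian or
  Rician acquisition noise.
- **Reconstruction** — voxelwise weighted least-squares fitting of both
  models with a from-scratch Powell conjugate-direction minimiser
  (multistart, NNLS-seeded amplitudes), inverse-variance echo weights,
  degeneracy classification (zero component, |ΔT2| < 1 ms, zero
  amplitude, or mono MSE below biexponential MSE ⇒ voxel demoted), and
  assembly of short/long T2, amplitude, fraction and validity maps.
- **ROI statistics** — subject-level pooled Student t-tests per
  structure × component with Bonferroni correction (0.05/4 = 0.0125),
  trend flagging at 0.05, Shapiro–Wilk normality, Pearson correlation,
  Cohen's κ and intersection-over-union reliability measures.

See `docs/methods.md` for the model, the numerical choices and the
measured limits of estimation at low SNR.

## Worked example

```python
import numpy as np
from t2biexp import (EchoTimes, PhantomSpec, ROIPlacement, make_phantom,
                     reconstruct_volume, reference_tissue, roi_summary)

tissue = reference_tissue("retrodiscal_tissue", "no_displacement").zero_sd()
roi = ROIPlacement(label=1, x=(2, 6), y=(2, 6))
spec = PhantomSpec(rois=((tissue, roi),), shape=(8, 8, 1),
                   echo_times=EchoTimes.default(), seed=3)
vol, truth = make_phantom(spec)                 # noise-free 8-echo phantom
stack = reconstruct_volume(vol, EchoTimes.default(), perfect_mse=1e-18)
for comp in ("t2_short", "t2_long", "frac_short"):
    s = roi_summary(getattr(stack, comp), truth.labels, stack.validity, 1)
    print(f"{comp}: {s.mean:.4f} over {s.n_valid_voxels} voxels")
```

prints

```
t2_short: 17.6000 over 16 voxels
t2_long: 105.3000 over 16 voxels
frac_short: 0.6660 over 16 voxels
```

i.e. every ROI voxel of a noise-free phantom configured with the
no-displacement retrodiscal reference values (T2_s = 17.6 ms,
T2_l = 105.3 ms, f_s = 0.666) is classified biexponential and
reconstructed back to the configured parameters.

The same pipeline from the shell:

```sh
t2biexp simulate --structure retrodiscal_tissue --zero-sd --shape 8,8,1 \
        --seed 3 --out sim/
t2biexp reconstruct --input sim/phantom.nii.gz --out maps/
t2biexp simulate --mode cohort --seed 3 --out coh/
t2biexp analyze --cohort coh/cohort.csv --out results.csv
t2biexp report  --cohort coh/cohort.csv --out report/
```

`analyze` emits the 7 × 4 table of group comparisons (means, SDs, t,
df, p, significance/trend flags, normality p-values); `report` adds a
figure contrasting the mono- and biexponential fits of an example
decay curve, whose monoexponential MSE is visibly higher.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline-level reference quantities from scratch:
noise-free phantom recovery of configured tissue parameters
(short/long T2 and short fraction for retrodiscal tissue, disk and
bone marrow), the Bonferroni threshold and the pooled t-test p-value
for the strongest group contrast, noisy-phantom ROI-mean recovery at
SNR 100 over 500 voxels, and Cohen's κ for perfect rater agreement on
the 18/32 group split.  Every value is computed at run time by
generating the stated inputs and running the reconstruction and
statistics; results are written as JSON keyed by target id.
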