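# demist

Detection-task-specific denoising for low-count myocardial perfusion
(MPI) SPECT, with the complete task-based evaluation machinery needed to
ask the question that matters clinically: *does denoising improve an
observer's ability to detect perfusion defects, or does it only make the
pictures prettier?*

## Who this is for

Researchers in nuclear-medicine image processing and task-based image
quality assessment who want (a) a denoiser whose training loss explicitly
preserves the image features a human-like observer uses for defect
detection, and (b) a self-contained, fully synthetic test bench — phantom,
projector, Poisson counts, dose reduction, defect insertion, OSEM,
channelized Hotelling observer, ROC/DeLong statistics, SNR eigenanalysis —
so every stage is testable without clinical data.

## The method in brief

A low-dose reconstruction `f̂_LD` is mapped to a predicted normal-dose
image `f̂_ND^pred = D_Θ(f̂_LD)` by a small residual encoder–decoder.  The
network is trained with a hybrid loss

    L(Θ) = L_fid(Θ) + λ · L_task(Θ)

where `L_fid` is per-voxel MSE to the true normal-dose image and `L_task`
is the MSE between *anthropomorphic channel vectors* `v = (S_j U)ᵀ f̂_2D`
of the predicted and true normal-dose slices around the defect: `U` holds
rotationally symmetric, octave-spaced frequency channels (first channel
starts at 0.1838 cycles/cm with equal bandwidth; each successive channel
doubles both) and `S_j` shifts them to case j's defect centroid.  λ = 0 is
the task-agnostic baseline (TADL).  Evaluation uses a channelized
Hotelling observer (template `w = K_v⁻¹Δv̄`, leave-one-out), empirical
ROC AUC with DeLong variance/tests and Bonferroni correction, and the
spectral decomposition `SNR² = Σ_m α_m²/γ_m` that separates a denoiser's
effect on noise (γ_m) from its effect on task-relevant signal (α_m).

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from demist import (LVPhantomSpec, SystemModel, generate_lv_phantom,
                    forward_project, sample_poisson, binomial_thin,
                    osem_reconstruct, butterworth_filter_3d)

spec = LVPhantomSpec(jitter_radius_mm=0.5, jitter_center_mm=1.0,
                     jitter_uptake_frac=0.05, seed=3)
activity, lv_mask, centroid = generate_lv_phantom(spec)
sys = SystemModel()
counts = sample_poisson(forward_project(activity, sys), seed=7, system=sys)
low = binomial_thin(counts, 0.125, seed=8)          # 12.5% dose
recon = butterworth_filter_3d(osem_reconstruct(low, sys))
print(counts.counts.sum(), round(recon.values[lv_mask].mean(), 1))
```

prints

```
261773 6.7
```

— about 260k detected counts at normal dose and a mean reconstructed
wall intensity of 6.7 (before count-rate normalisation by 1/p) at 12.5%
dose.  The full comparison — simulate a cohort, train the denoiser at
λ ∈ {0, 1}, score every method with the observer — is one call:

```python
from demist.pipeline import headline_experiment
res = headline_experiment(seed=1)
print({m: round(a, 3) for m, a in res["auc"].items()})
```

which trains the denoiser at λ = 0 (task-agnostic) and λ = 1
(task-specific) on 64 synthetic cases and reports leave-one-out CHO AUC
on 40+40 test cases — with seed 1 it prints

```
{'lowdose': 0.666, 'normaldose': 0.882, 'tadl': 0.571, 'demist': 0.586}
```

i.e. at 12.5% dose the observer loses about 0.2 AUC relative to normal
dose, and at this desk scale (64 training cases, AUC standard error
~0.06) the two denoisers sit within noise of the low-dose protocol —
see `docs/methods.md` for what the scaled-down surrogate can and cannot
show.  Takes about five minutes on one CPU core; `demist run` writes the
same tables as CSV.

A command-line surface wraps the same library:

```bash
demist phantom --out work/ --seed 3
demist lowdose --in work/sinogram_nd.h5 --p 0.125 --seed 1 --out work/ld.h5
demist insert-defect --in work/phantom.h5 --location anterior --extent 60 \
       --severity 0.25 --out work/defect.h5
demist run --seed 1 --out work/exp/
```

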