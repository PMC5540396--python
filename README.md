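# ktpca

k-t PCA reconstruction for accelerated dynamic MRI, with artificial-sparsity
variants, a synthetic first-pass perfusion phantom, and quantitative
evaluation tools.

## The problem

Dynamic MRI (cardiac perfusion, cine, fMRI) trades spatial against temporal
resolution: acquiring every phase-encode line of every frame is too slow.
Lattice ("sheared-grid") undersampling acquires only every R-th line per
frame, shifting the sampled comb each frame. In x-f space — spatial position
against temporal frequency, reached by an inverse FFT along k and a forward
FFT along t — this folds the object onto itself at exactly R known offsets.
Unfolding those superpositions is the reconstruction problem this package
solves, for people who study such reconstructions: it provides the standard
method, two self-calibrated improvements, and the simulation and evaluation
machinery to compare them.

## The methods

**k-t PCA.** A small fully sampled band at the k-space center ("training
profiles", default 11) is kept at full temporal resolution. Its x-f data is
factored by PCA as P_train = W_train·B, where the rows of B are orthonormal
temporal-frequency principal components. Assuming the true x-f data also
factors as P = W·B, the aliased signal at each location collects into
P_alias,x = E·W_x with an encoding matrix E built from frequency-shifted
copies of B, and the weights are recovered by the Tikhonov-regularized
least-squares solution

    W_x = M² Eᴴ (E M² Eᴴ + λI)⁺ P_alias,x ,     M² = diag(w_train,x w_train,xᴴ).

By default λ is noise-matched (λ = R·σ̂², the aliased-data noise variance,
with σ̂ estimated from the outer k-space corners). Each coil channel is
reconstructed independently and combined with sensitivity maps S_j as
I = Σ_j I_j·S_j*.

**Residual k-t PCA** subtracts the temporal-average (DC) k-space — estimated
from the acquired samples themselves — from every frame, reconstructs only
the residual dynamics, and adds the DC image back.

**Sparse k-t PCA** runs the standard reconstruction once, re-samples its k-t
space with the acquisition pattern, complex-subtracts it from the measured
samples, reconstructs that sparse difference (with a basis fitted to the
difference training data), and adds the correction to the first pass. Both
variants shrink the effective image content so fewer strong pixels alias
onto each other.

**Evaluation.** Per-frame NRMSE = ‖I_ref − I_rec‖_F / ‖I_ref‖_F, its frame
average (m-NRMSE), absolute error maps, ROI signal-intensity time courses,
and pseudo-multiple-replica g-factor / SNR maps (repeat the reconstruction
on noise-perturbed copies; SNR = |mean|/std per pixel;
g = SNR_full / (SNR_R·√R)).

**Phantom.** A deterministic multi-coil perfusion phantom: nested-ellipse
anatomy, gamma-variate bolus enhancement with transit-delay gradients across
the blood pools (controllable temporal rank), smooth complex coil maps, and
complex white Gaussian noise at a target image-domain SNR.

## Worked example

```python
from ktpca import RunConfig, run_pipeline

cfg = RunConfig(n_readout=64, n_pe=64, n_frames=32, n_coils=4, R=4, seeds=[0, 1, 2])
result = run_pipeline(cfg)
for method, score in result["mean_m_nrmse"].items():
    print(f"{method:12s} m-NRMSE = {100 * score:.2f}%")
```

prints

```
traditional  m-NRMSE = 5.49%
residual     m-NRMSE = 5.16%
sparse       m-NRMSE = 5.22%
```

i.e. on a 64×64, 32-frame, 4-coil phantom at 20 dB SNR and four-fold
acceleration, both artificial-sparsity variants reduce the mean
reconstruction error of standard k-t PCA (here by ~5–6% relative), the
behaviour the method was designed for. Each stage is also scriptable:

```bash
ktpca phantom --nx 64 --ny 64 --frames 32 --coils 4 --out phantom.h5
ktpca sample --r 4 --train-profiles 11 --in phantom.h5 --out und.h5 --train-out train.h5
ktpca recon --method sparse --npc 6 --in und.h5 --train train.h5 --out rec.h5
ktpca evaluate --rec rec.h5 --ref full.h5 --out report.json
```

## Layout

| module | contents |
| --- | --- |
| `ktpca.phantom` | perfusion phantom, coil projection, noise model |
| `ktpca.sampling` | sheared-grid patterns, PSF offsets, training extraction |
| `ktpca.core` | x-f transforms, PCA basis, encoding matrix, regularized solve |
| `ktpca.variants` | residual / sparse k-t PCA, sensitivities, coil combination |
| `ktpca.evaluation` | NRMSE, error maps, ROI curves, pseudo-replica g/SNR maps |
| `ktpca.io`, `ktpca.cli`, `ktpca.pipeline` | HDF5/NIfTI containers, CLI verbs, end-to-end runs |

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
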