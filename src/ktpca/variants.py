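"""Artificial-sparsity variants of k-t PCA and coil combination.

Two self-calibrated schemes reduce the effective image content before
(or after) unfolding so that fewer strong pixels alias onto each other:

* **residual k-t PCA** — subtract the temporal-average (DC) k-space
  from every frame, reconstruct the residual dynamics only, and add the
  DC image back.
* **sparse k-t PCA** — run the standard reconstruction once, re-sample
  its k-t space with the acquisition pattern, complex-subtract it from
  the measured samples, reconstruct that sparse difference with a basis
  fitted to the difference training data, and add the correction to the
  first-pass image.

Coil images are combined as a matched filter, ``I = sum_j I_j * conj(S_j)``,
with sensitivity maps normalized to unit root-sum-of-squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ReconResult, infer_pattern, reconstruct_traditional
from .datatypes import KTData
from .sampling import SamplingPattern
from .transforms import fft2c, ifft2c

__all__ = [
    "SensitivityMaps",
    "dc_from_samples",
    "reconstruct_residual",
    "resample_recon",
    "reconstruct_sparse",
    "estimate_sensitivities",
    "combine_coils",
]


@dataclass
class SensitivityMaps:
    """Complex coil sensitivities with their support mask."""

    S: np.ndarray  # (n_coils, n_readout, n_pe)
    mask: np.ndarray  # boolean (n_readout, n_pe)


def dc_from_samples(kt_undersampled: KTData) -> tuple[np.ndarray, np.ndarray]:
    """Temporal-average k-space and its image from the acquired samples only.

    Each phase-encode line is averaged over the frames in which it was
    acquired (on a sheared grid every line is hit n_frames / R times),
    giving an unaliased estimate of the static (DC) content.
    Returns ``(dc_kspace, dc_image)``, both shaped (n_coils, n_readout, n_pe).
    """
    counts = kt_undersampled.mask.sum(axis=1)  # per pe line
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ValueError(
            f"phase-encode lines never acquired: {missing.tolist()}; "
            "the lattice union must cover k-space"
        )
    dc_k = (kt_undersampled.data * kt_undersampled.mask[None, None, :, :]).sum(axis=3)
    dc_k /= counts[None, None, :]
    dc_img = ifft2c(dc_k, axes=(1, 2))
    return dc_k, dc_img


def reconstruct_residual(
    kt_undersampled: KTData,
    kt_training: KTData,
    n_pc: int,
    lam: float | None = None,
    lam_scale: float = 1.0,
) -> ReconResult:
    """Residual k-t PCA: unfold the DC-subtracted dynamics, add DC back.

    The training data's own temporal average is subtracted from the
    training set so basis and data describe the same residual signal.
    """
    dc_k, dc_img = dc_from_samples(kt_undersampled)
    resid = kt_undersampled.copy()
    resid.data = resid.data - dc_k[:, :, :, None] * kt_undersampled.mask[None, None, :, :]

    train = kt_training.copy()
    train_dc = kt_training.data.mean(axis=3)
    train.data = train.data - train_dc[:, :, :, None] * kt_training.mask[None, None, :, :]

    rec = reconstruct_traditional(resid, train, n_pc, lam, lam_scale)
    images = rec.images + dc_img[:, :, :, None]
    return ReconResult(images=images, method_tag="residual", params=rec.params)


def resample_recon(recon: ReconResult, pattern: SamplingPattern) -> KTData:
    """Project a reconstruction back onto the acquisition pattern.

    Forward spatial FFT per coil and frame, then zero every non-acquired
    location, reusing the pattern's mask.
    """
    nx_pe = recon.images.shape[2:]
    if (pattern.n_pe, pattern.n_frames) != (recon.images.shape[2], recon.images.shape[3]):
        raise ValueError(
            f"pattern grid {(pattern.n_pe, pattern.n_frames)} does not match "
            f"reconstruction grid {nx_pe}"
        )
    kspace = fft2c(recon.images, axes=(1, 2))
    kspace *= pattern.acquired[None, None, :, :]
    return KTData(kspace, pattern.acquired.copy())


def reconstruct_sparse(
    kt_undersampled: KTData,
    kt_training: KTData,
    n_pc: int,
    lam: float | None = None,
    lam_scale: float = 1.0,
    refit_basis: bool = True,
    iterations: int = 1,
) -> ReconResult:
    """Sparse k-t PCA: correct the first pass with a reconstruction of its
    own sampled-domain error.

    Per correction pass: (1) re-sample the current reconstruction with
    the acquisition pattern; (2) complex-subtract it from the measured
    k-t samples to form the sparse difference data; (3) form difference
    training data the same way at the training locations; (4) reconstruct
    the difference (with a freshly fitted basis unless ``refit_basis`` is
    False); (5) add the difference image to the current reconstruction.
    """
    pattern = infer_pattern(kt_undersampled)
    first = reconstruct_traditional(kt_undersampled, kt_training, n_pc, lam, lam_scale)
    images = first.images
    train_pat = SamplingPattern(
        R=1,
        n_pe=pattern.n_pe,
        n_frames=pattern.n_frames,
        acquired=kt_training.mask,
        shift_per_frame=1,
    )
    for _ in range(iterations):
        current = ReconResult(images=images, method_tag="sparse", params=first.params)
        diff = kt_undersampled.copy()
        diff.data = kt_undersampled.data - resample_recon(current, pattern).data

        diff_train = kt_training.copy()
        diff_train.data = kt_training.data - resample_recon(current, train_pat).data

        bases = None
        if not refit_basis:
            from .core import fit_basis, kt_to_xf

            xf_train = kt_to_xf(kt_training)
            bases = [fit_basis(xf, n_pc) for xf in xf_train]
        correction = reconstruct_traditional(
            diff, diff_train, n_pc, lam, lam_scale, pattern=pattern, bases=bases
        )
        images = images + correction.images
    params = dict(first.params)
    params["iterations"] = iterations
    return ReconResult(images=images, method_tag="sparse", params=params)


def estimate_sensitivities(
    kt_undersampled: KTData,
    smooth_sigma: float = 1.0,
    support_threshold: float = 0.05,
) -> SensitivityMaps:
    """Self-calibrated coil maps from the temporal-average (DC) images.

    ``S_j = dc_j / RSS(dc)`` (unit root-sum-of-squares by construction),
    lightly smoothed; the support mask keeps pixels whose RSS exceeds
    ``support_threshold`` times its maximum.
    """
    if not np.any(kt_undersampled.data):
        raise ValueError("cannot estimate sensitivities from all-zero data")
    _, dc_img = dc_from_samples(kt_undersampled)
    rss = np.sqrt(np.sum(np.abs(dc_img) ** 2, axis=0))
    support = rss > support_threshold * rss.max()
    S = dc_img / np.where(rss > 0, rss, 1.0)[None, :, :]
    if smooth_sigma > 0:
        S = gaussian_filter(S.real, sigma=(0, smooth_sigma, smooth_sigma)) + 1j * gaussian_filter(
            S.imag, sigma=(0, smooth_sigma, smooth_sigma)
        )
    return SensitivityMaps(S=S, mask=support)


def combine_coils(recon: ReconResult | np.ndarray, maps: SensitivityMaps) -> np.ndarray:
    """Matched-filter coil combination: ``I = sum_j I_j * conj(S_j)``."""
    images = recon.images if isinstance(recon, ReconResult) else np.asarray(recon)
    if images.shape[0] != maps.S.shape[0] or images.shape[1:3] != maps.S.shape[1:]:
        raise ValueError(
            f"coil image shape {images.shape} incompatible with maps {maps.S.shape}"
        )
    return np.sum(images * np.conj(maps.S)[:, :, :, None], axis=0)
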