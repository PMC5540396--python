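"""Reconstruction quality metrics and Monte-Carlo noise propagation.

Implements the per-frame normalized root-mean-square error

    NRMSE_t = || I_ref(t) - I_rec(t) ||_F / || I_ref(t) ||_F

its average over frames (m-NRMSE), absolute error maps, ROI
signal-intensity time courses, and pseudo-multiple-replica g-factor /
SNR maps: the reconstruction is repeated on many noise-perturbed copies
of the acquired data, per-pixel SNR is |mean| / std over replicas, and

    g = SNR_full / (SNR_R * sqrt(R))

compares the accelerated reconstruction with a fully sampled one after
removing the sqrt(R) scan-time penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import KTData
from .variants import SensitivityMaps, combine_coils, estimate_sensitivities

__all__ = [
    "EvalReport",
    "nrmse",
    "nrmse_per_frame",
    "m_nrmse",
    "error_map",
    "roi_timecourse",
    "pseudo_replica",
]


@dataclass
class EvalReport:
    """Quantitative summary of one reconstruction."""

    nrmse_frames: np.ndarray
    m_nrmse: float
    error_maps: np.ndarray
    roi_curves: np.ndarray | None = None
    g_map: np.ndarray | None = None
    snr_map: np.ndarray | None = None
    method_tag: str = ""
    params: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {
            "method": self.method_tag,
            "m_nrmse": float(self.m_nrmse),
            "nrmse_per_frame": [float(v) for v in self.nrmse_frames],
        }
        if self.g_map is not None:
            out["median_g"] = float(np.nanmedian(self.g_map))
        if self.snr_map is not None:
            out["median_snr"] = float(np.nanmedian(self.snr_map))
        out.update({k: v for k, v in self.params.items() if np.isscalar(v)})
        return out


def nrmse(rec: np.ndarray, ref: np.ndarray, magnitude: bool = False) -> float:
    """Frobenius-norm error of ``rec`` relative to ``ref``.

    Computed on the complex images by default; ``magnitude=True``
    compares magnitude images instead (conventional for in vivo data).
    """
    rec = np.asarray(rec)
    ref = np.asarray(ref)
    if rec.shape != ref.shape:
        raise ValueError(f"shape mismatch: rec {rec.shape} vs ref {ref.shape}")
    if magnitude:
        rec, ref = np.abs(rec), np.abs(ref)
    denom = np.linalg.norm(ref)
    if denom == 0:
        raise ValueError("reference image has zero norm")
    return float(np.linalg.norm(ref - rec) / denom)


def nrmse_per_frame(
    rec_series: np.ndarray, ref_series: np.ndarray, magnitude: bool = False
) -> np.ndarray:
    """NRMSE of every frame (frames on the last axis)."""
    if rec_series.shape != ref_series.shape:
        raise ValueError(
            f"shape mismatch: rec {rec_series.shape} vs ref {ref_series.shape}"
        )
    return np.array(
        [
            nrmse(rec_series[..., t], ref_series[..., t], magnitude=magnitude)
            for t in range(rec_series.shape[-1])
        ]
    )


def m_nrmse(rec_series: np.ndarray, ref_series: np.ndarray, magnitude: bool = False) -> float:
    """Arithmetic mean over frames of the per-frame NRMSE."""
    return float(nrmse_per_frame(rec_series, ref_series, magnitude=magnitude).mean())


def error_map(
    rec: np.ndarray, ref: np.ndarray, brighten: float = 1.0, magnitude: bool = False
) -> np.ndarray:
    """Per-pixel absolute error |ref - rec|, with an optional display gain.

    ``magnitude=True`` compares magnitudes (invariant to a global phase
    of either input); the ``brighten`` factor is a pure display scaling
    applied to the returned map.
    """
    if rec.shape != ref.shape:
        raise ValueError(f"shape mismatch: rec {rec.shape} vs ref {ref.shape}")
    if magnitude:
        diff = np.abs(np.abs(ref) - np.abs(rec))
    else:
        diff = np.abs(ref - rec)
    return brighten * diff


def roi_timecourse(series: np.ndarray, roi_labels: np.ndarray) -> np.ndarray:
    """Mean magnitude per frame inside each labelled region.

    Returns an array (n_rois, n_frames) for labels 1..max(roi_labels).
    """
    labels = np.asarray(roi_labels)
    n_rois = int(labels.max())
    if n_rois < 1:
        raise ValueError("roi_labels contains no labelled region")
    mag = np.abs(series)
    curves = np.empty((n_rois, series.shape[-1]))
    for r in range(1, n_rois + 1):
        sel = labels == r
        if not sel.any():
            raise ValueError(f"ROI label {r} is empty")
        curves[r - 1] = mag[sel, :].mean(axis=0)
    return curves


def _replica_snr(
    recon_fn,
    kt: KTData,
    kt_training: KTData,
    noise_sigma: float,
    n_replicas: int,
    rng: np.random.Generator,
    maps: SensitivityMaps,
) -> np.ndarray:
    """Per-pixel, per-frame complex SNR = |mean| / std over noise replicas."""
    acc = None
    acc2 = None
    for _ in range(n_replicas):
        shape = kt.data.shape
        noise = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * (
            noise_sigma / np.sqrt(2.0)
        )
        kt_r = KTData(kt.data + noise * kt.mask[None, None, :, :], kt.mask)
        img = combine_coils(recon_fn(kt_r, kt_training), maps)
        if acc is None:
            acc = np.zeros_like(img)
            acc2 = np.zeros(img.shape)
        acc += img
        acc2 += np.abs(img) ** 2
    mean = acc / n_replicas
    var = acc2 / n_replicas - np.abs(mean) ** 2
    std = np.sqrt(np.clip(var, 0, None) * n_replicas / max(n_replicas - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.abs(mean) / std
    snr[std == 0] = np.nan
    return snr


def pseudo_replica(
    recon_fn,
    kt_undersampled: KTData,
    kt_training: KTData,
    noise_sigma: float,
    n_replicas: int,
    seed: int,
    kt_full: KTData | None = None,
    maps: SensitivityMaps | None = None,
    snr_full: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-multiple-replica g-factor and SNR maps.

    ``recon_fn(kt, kt_training) -> ReconResult`` is re-run on
    ``n_replicas`` copies of the data with fresh complex Gaussian noise
    (standard deviation ``noise_sigma``) added to the acquired samples.
    The accelerated SNR map is |mean|/std over replicas of the combined
    image; the same procedure on the fully sampled data (``kt_full``,
    R = 1 mask) gives the reference map, and

        g = SNR_full / (SNR_R * sqrt(R)).

    A precomputed ``snr_full`` may be passed to share the reference
    branch between methods.  Frames are averaged into a single 2-D map.
    Pixels with zero replica variance are returned as NaN.
    """
    if n_replicas < 2:
        raise ValueError("n_replicas must be >= 2")
    R = int(round(kt_undersampled.mask.size / max(kt_undersampled.mask.sum(), 1)))
    if kt_full is None and snr_full is None and R != 1:
        raise ValueError("kt_full is required to form the R=1 reference branch")
    ss = np.random.SeedSequence(seed)
    rng_acc, rng_full = (np.random.default_rng(s) for s in ss.spawn(2))
    if maps is None:
        maps = estimate_sensitivities(kt_undersampled)
    snr_acc = _replica_snr(
        recon_fn, kt_undersampled, kt_training, noise_sigma, n_replicas, rng_acc, maps
    ).mean(axis=-1)
    if snr_full is None:
        if kt_full is None:
            if R != 1:
                raise ValueError("kt_full is required to form the R=1 reference branch")
            kt_full = kt_undersampled
        snr_full = _replica_snr(
            recon_fn, kt_full, kt_training, noise_sigma, n_replicas, rng_full, maps
        ).mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = snr_full / (snr_acc * np.sqrt(R))
    return g, snr_acc
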