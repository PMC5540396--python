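"""Synthetic first-pass cardiac-perfusion phantom.

Generates a multi-coil dynamic series with the statistical structure of
a contrast-enhanced perfusion scan: static anatomy built from nested
ellipses (body, myocardial ring, two ventricular cavities), gamma-variate
bolus enhancement curves with region-specific delay and peak, smooth
complex surface-coil sensitivities, and complex white Gaussian noise at
a target image-domain SNR.  The noiseless pixel-by-frame matrix has
numerical rank at most ``temporal_rank + 1`` (static level plus the
independent enhancement curves), which is the low-rank structure the
reconstruction methods rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import DynamicSeries, KTData
from .transforms import fft2c, ifft2c

__all__ = ["PhantomConfig", "make_phantom", "apply_coils", "add_noise", "gamma_variate"]

log = logging.getLogger(__name__)


@dataclass
class PhantomConfig:
    """Phantom geometry, dynamics and noise settings.

    Defaults follow a typical simulated perfusion acquisition: a
    224 x 192 matrix, 32 frames, 4 receiver coils and 20 dB SNR.
    """

    n_readout: int = 224
    n_pe: int = 192
    n_frames: int = 32
    n_coils: int = 4
    snr_db: float = 20.0
    temporal_rank: int = 12
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_readout", "n_pe", "n_frames", "n_coils"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"PhantomConfig.{name} must be a positive integer, got {v!r}")
        if not (1 <= self.temporal_rank <= self.n_frames):
            raise ValueError(
                f"PhantomConfig.temporal_rank must be in [1, n_frames={self.n_frames}], "
                f"got {self.temporal_rank}"
            )
        if not np.isfinite(self.snr_db) and self.snr_db != np.inf:
            raise ValueError(f"PhantomConfig.snr_db must be finite (or +inf to disable noise)")


def gamma_variate(t: np.ndarray, t0: float, t_peak: float, alpha: float) -> np.ndarray:
    """Normalized gamma-variate bolus curve peaking at ``t_peak`` with value 1.

    ``y(t) = ((t - t0)/(t_peak - t0))**alpha * exp(alpha * (1 - (t - t0)/(t_peak - t0)))``
    for t > t0, zero before arrival.  ``alpha`` controls the washout tail.
    """
    tau = (t - t0) / (t_peak - t0)
    y = np.where(tau > 0, np.power(np.clip(tau, 0, None), alpha) * np.exp(alpha * (1 - tau)), 0.0)
    return y


def _ellipse(nx: int, ny: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0


def make_phantom(config: PhantomConfig) -> DynamicSeries:
    """Build the noiseless dynamic series, coil maps, masks and ROI labels.

    Anatomy: a body ellipse (static), a myocardial ring, and two
    ventricle-like cavities labelled 1 (right-ventricle analogue, early
    bolus arrival) and 2 (left-ventricle analogue, later arrival).  Each
    dynamic region follows one of ``temporal_rank`` gamma-variate curves
    (regions share curves when the rank is lower than the number of
    dynamic regions); rank beyond 3 models bolus transit by splitting
    the regions into bands with progressively delayed curves.  A smooth
    static phase is applied so the object is genuinely complex.
    """
    config.validate()
    nx, ny, nt = config.n_readout, config.n_pe, config.n_frames

    body = _ellipse(nx, ny, 0.50 * nx, 0.50 * ny, 0.44 * nx, 0.40 * ny)
    r0 = 0.5 * (nx + ny) / 2
    # heart offset toward one side, as in a short-axis slice
    hx, hy = 0.46 * nx, 0.58 * ny
    lv_outer = _ellipse(nx, ny, hx, hy, 0.20 * r0, 0.20 * r0)
    lv_cavity = _ellipse(nx, ny, hx, hy, 0.115 * r0, 0.115 * r0)
    myocardium = lv_outer & ~lv_cavity
    rv_cavity = _ellipse(nx, ny, hx - 0.02 * nx, hy - 0.30 * ny, 0.14 * r0, 0.10 * r0) & ~lv_outer

    static = np.zeros((nx, ny))
    static[body] = 0.50
    static[myocardium] = 0.55
    static[lv_cavity] = 0.30
    static[rv_cavity] = 0.30

    # dynamic regions in bolus order: RV first, then LV, then myocardium
    t = np.arange(nt, dtype=float)
    ts = nt / 32.0  # timing laid out for 32 frames, scaled to the grid
    region_curves = [
        gamma_variate(t, t0=2.0 * ts, t_peak=9.0 * ts, alpha=3.0),   # RV cavity
        gamma_variate(t, t0=6.0 * ts, t_peak=15.0 * ts, alpha=3.5),  # LV cavity
        gamma_variate(t, t0=10.0 * ts, t_peak=21.0 * ts, alpha=2.5),  # myocardium
    ]
    region_maps = [rv_cavity.astype(float) * 0.9, lv_cavity.astype(float) * 1.0,
                   myocardium.astype(float) * 0.25]

    region_params = [
        dict(t0=2.0 * ts, t_peak=9.0 * ts, alpha=3.0),
        dict(t0=6.0 * ts, t_peak=15.0 * ts, alpha=3.5),
        dict(t0=10.0 * ts, t_peak=21.0 * ts, alpha=2.5),
    ]

    rank = config.temporal_rank
    n_anat = min(rank, len(region_curves))
    curves = [region_curves[i] for i in range(n_anat)]
    maps = [np.zeros((nx, ny)) for _ in range(n_anat)]
    for i, m in enumerate(region_maps):
        maps[i % n_anat] += m
    # Components beyond the three anatomical base curves model bolus
    # transit: arrival time varies across each blood pool as contrast
    # flows through, so the temporal profiles form a family of delayed
    # curves rather than a single one.  Each region is split into
    # contiguous bands along the phase-encode direction; band b of
    # region i follows the region's gamma-variate delayed by
    # 0.7*b frames (32-frame scale).  The bands are disjoint, so the
    # noiseless series has exact rank <= temporal_rank + 1.
    extras = [0, 0, 0]
    for j in range(n_anat, rank):
        extras[j % 3] += 1
    for i in range(3):
        if extras[i] == 0:
            continue
        region = [rv_cavity, lv_cavity, myocardium][i]
        amp = [0.9, 1.0, 0.25][i]
        ys = np.flatnonzero(region.any(axis=0))
        bands = np.array_split(ys, extras[i] + 1)
        for b, band_ys in enumerate(bands[1:], start=1):
            band = np.zeros((nx, ny), dtype=bool)
            band[:, band_ys] = True
            band &= region
            if not band.any():
                continue
            p = region_params[i]
            delayed = gamma_variate(
                t, t0=p["t0"] + 0.7 * b * ts, t_peak=p["t_peak"] + 0.7 * b * ts,
                alpha=p["alpha"],
            )
            maps[i % n_anat] = maps[i % n_anat] * ~band
            maps.append(band.astype(float) * amp)
            curves.append(delayed)

    dynamic = np.zeros((nx, ny, nt))
    for m, c in zip(maps, curves):
        dynamic += m[:, :, None] * c[None, None, :]

    X, Y = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), indexing="ij")
    phase = np.exp(1j * (0.3 * X + 0.2 * Y + 0.4 * X * Y))
    truth = (static[:, :, None] + dynamic) * phase[:, :, None]
    truth *= body[:, :, None]

    sens = _coil_maps(nx, ny, config.n_coils)

    roi = np.zeros((nx, ny), dtype=int)
    roi[rv_cavity] = 1
    roi[lv_cavity] = 2
    roi_curves = np.stack([region_curves[0], region_curves[1]])

    return DynamicSeries(
        truth=truth,
        sensitivities=sens,
        object_mask=body,
        roi_labels=roi,
        roi_curves=roi_curves,
    )


def _coil_maps(nx: int, ny: int, n_coils: int) -> np.ndarray:
    """Smooth complex surface-coil profiles, unit root-sum-of-squares.

    One broad Gaussian lobe per coil, centered outside the field of view
    at evenly spaced angles, with a gentle coil-specific linear phase.
    """
    X, Y = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), indexing="ij")
    maps = np.empty((n_coils, nx, ny), dtype=complex)
    for j in range(n_coils):
        theta = 2 * np.pi * j / n_coils
        cx, cy = 1.5 * np.cos(theta), 1.5 * np.sin(theta)
        mag = np.exp(-(((X - cx) ** 2 + (Y - cy) ** 2)) / (2 * 1.2**2))
        ph = np.exp(1j * (0.5 * np.cos(theta) * X + 0.5 * np.sin(theta) * Y + 0.3 * j))
        maps[j] = mag * ph
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / rss[None, :, :]


def apply_coils(series: DynamicSeries) -> KTData:
    """Project the truth through the coil maps and transform to k-space.

    Per coil and frame the image is ``truth * sensitivity``; the forward
    unitary DC-centered FFT along both spatial axes gives fully sampled
    k-t data with an all-true mask.
    """
    coil_images = series.sensitivities[:, :, :, None] * series.truth[None, :, :, :]
    kspace = fft2c(coil_images, axes=(1, 2))
    mask = np.ones((series.truth.shape[1], series.truth.shape[2]), dtype=bool)
    return KTData(kspace, mask)


def noise_sigma_for_snr(
    kt: KTData, snr_db: float, object_mask: np.ndarray | None = None
) -> float:
    """Per-pixel complex noise standard deviation hitting the target SNR.

    SNR is defined in amplitude decibels as (mean coil-image magnitude
    over the object support and all frames) / (complex noise standard
    deviation per image pixel): ``snr_db = 20 log10(mean/sigma)``.
    """
    images = ifft2c(kt.data, axes=(1, 2))
    mag = np.abs(images)
    if object_mask is None:
        log.warning("no object mask supplied; SNR reference is the whole-image mean")
        mean_mag = mag.mean()
    else:
        mean_mag = mag[:, object_mask, :].mean()
    return float(mean_mag / 10.0 ** (snr_db / 20.0))


def add_noise(
    kt: KTData,
    snr_db: float,
    seed: int,
    object_mask: np.ndarray | None = None,
) -> KTData:
    """Add i.i.d. complex white Gaussian noise to every acquired sample.

    The noise level is set from the image-domain SNR definition of
    :func:`noise_sigma_for_snr`; because the spatial transform is
    unitary, noise of the same variance added in k-space produces that
    per-pixel image noise.  ``snr_db = inf`` disables noise.
    """
    if np.isinf(snr_db) and snr_db > 0:
        return kt.copy()
    if not np.isfinite(snr_db):
        raise ValueError(f"snr_db must be finite or +inf, got {snr_db}")
    sigma = noise_sigma_for_snr(kt, snr_db, object_mask)
    rng = np.random.default_rng(seed)
    shape = kt.data.shape
    noise = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * (
        sigma / np.sqrt(2.0)
    )
    data = kt.data + noise * kt.mask[None, None, :, :]
    return KTData(data, kt.mask.copy())
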