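"""Traditional k-t PCA reconstruction.

The method unfolds lattice-undersampled dynamic data in x-f space.  A
temporal-frequency basis B is learned by PCA (truncated SVD, no mean
subtraction) from low-resolution, fully time-resolved training data:
``P_train = W_train B``.  Assuming the true x-f data also factors as
``P = W B`` with spatially varying weights W, the aliased signal at a
reduced-FOV location is a unit-weight sum over the R lattice aliases,
``P_alias,x = E W_x`` with an encoding matrix E built from
frequency-shifted copies of B.  The weights are recovered with the
Tikhonov-regularized least-squares solution

    W_x = M^2 E^H (E M^2 E^H + lam I)^+ P_alias,x

where M^2 = diag(w_train,x w_train,x^H) is the training signal
covariance and ^+ the Moore-Penrose pseudo-inverse.  Each coil channel
is reconstructed independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import KTData
from .sampling import SamplingPattern, psf_offsets, psf_weights
from .transforms import freq_to_time, ifft2c, time_to_freq

__all__ = [
    "XFData",
    "PCABasis",
    "UnfoldingProblem",
    "ReconResult",
    "kt_to_xf",
    "xf_to_kt",
    "fit_basis",
    "build_unfolding",
    "solve_weights",
    "reconstruct_traditional",
]

# Encoding-matrix column order: alias-major, principal-component-minor,
# i.e. column (i, p) sits at index i * n_pc + p.


@dataclass
class XFData:
    """Single-coil x-f data: readout position x, phase-encode position y,
    DC-centered temporal-frequency bin f."""

    values: np.ndarray  # complex, (n_readout, n_pe, n_frequency)

    @property
    def n_frequency(self) -> int:
        return self.values.shape[-1]


@dataclass
class PCABasis:
    """Temporal-frequency principal components and training weights.

    ``B`` has orthonormal rows (one per principal component over
    frequency bins); ``W_train`` holds the per-voxel weights of the
    training data on those components, reshaped to the (x, y) grid for
    lookup during unfolding.
    """

    B: np.ndarray  # (n_pc, n_frequency)
    W_train: np.ndarray  # (n_readout, n_pe, n_pc)
    n_pc: int


@dataclass
class UnfoldingProblem:
    """One per-location unfolding system (Tikhonov least squares)."""

    E: np.ndarray  # (n_frequency, R * n_pc)
    M2: np.ndarray  # nonnegative real, (R * n_pc,)
    lam: float
    p_alias: np.ndarray  # (n_frequency,)


@dataclass
class ReconResult:
    """Per-coil reconstructed image series plus the parameters that made it."""

    images: np.ndarray  # complex, (n_coils, n_readout, n_pe, n_frames)
    method_tag: str
    params: dict = field(default_factory=dict)


def kt_to_xf(kt: KTData, scale: float = 1.0) -> list[XFData]:
    """Transform zero-filled k-t data to x-f space, one XFData per coil.

    For lattice-undersampled input the zero filling attenuates the
    aliased signal by 1/R; passing ``scale=R`` restores the unit-weight
    aliasing sum assumed by the encoding model.
    """
    xf = time_to_freq(ifft2c(kt.data, axes=(1, 2)), axis=-1)
    if scale != 1.0:
        xf = xf * scale
    return [XFData(xf[c]) for c in range(kt.n_coils)]


def xf_to_kt(xf_values: np.ndarray) -> np.ndarray:
    """Inverse of the per-coil x-f transform: returns k-t space samples."""
    from .transforms import fft2c

    img = freq_to_time(xf_values, axis=-1)
    return fft2c(img, axes=(-3, -2))


def fit_basis(training_xf: XFData, n_pc: int) -> PCABasis:
    """PCA of the training x-f data: B = top right singular vectors.

    The training voxels (all x, y of the low-resolution image) are
    stacked as a matrix with one row per voxel and one column per
    temporal-frequency bin; no mean is subtracted, so the DC component
    stays in the data and the basis.
    """
    nx, ny, nf = training_xf.values.shape
    if not 1 <= n_pc <= nf:
        raise ValueError(f"n_pc must be in [1, {nf}], got {n_pc}")
    mat = training_xf.values.reshape(nx * ny, nf)
    _, _, vh = np.linalg.svd(mat, full_matrices=False)
    B = vh[:n_pc]
    W = mat @ B.conj().T
    return PCABasis(B=B, W_train=W.reshape(nx, ny, n_pc), n_pc=n_pc)


def _encoding_matrix(basis: PCABasis, offsets, weights) -> np.ndarray:
    """E[m, (i, p)] = w_i * B[p, (m - df_i) mod nf] (alias-major columns)."""
    n_pc, nf = basis.B.shape
    R = len(offsets)
    E = np.empty((nf, R * n_pc), dtype=complex)
    m = np.arange(nf)
    for i, (_, df) in enumerate(offsets):
        # cyclic frequency shift of the basis rows by df
        E[:, i * n_pc : (i + 1) * n_pc] = weights[i] * basis.B[:, (m - df) % nf].T
    return E


def _alias_locations(offsets, y_reduced: int, n_pe: int) -> list[int]:
    """True-object phase-encode rows folded onto reduced-FOV row y_reduced."""
    return [(y_reduced - dy) % n_pe for dy, _ in offsets]


def build_unfolding(
    basis: PCABasis,
    offsets: list[tuple[int, int]],
    pattern: SamplingPattern,
    x: int,
    y_reduced: int,
    p_alias: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
) -> UnfoldingProblem:
    """Assemble the encoding matrix and signal covariance for one location.

    The unknown blocks are the basis weights at the R aliased rows
    ``y_i = (y_reduced - dy_i) mod n_pe``; block i of E holds the basis
    rows cyclically shifted in frequency by ``df_i`` and scaled by the
    lattice PSF amplitude.  M2 is the entrywise squared magnitude of the
    training weights at the aliased locations.
    """
    if weights is None:
        weights = psf_weights(pattern)
    E = _encoding_matrix(basis, offsets, weights)
    ys = _alias_locations(offsets, y_reduced, pattern.n_pe)
    M2 = np.concatenate([np.abs(basis.W_train[x, y, :]) ** 2 for y in ys])
    return UnfoldingProblem(E=E, M2=M2, lam=float(lam), p_alias=np.asarray(p_alias))


def solve_weights(problem: UnfoldingProblem) -> np.ndarray:
    """Tikhonov-regularized solve: W_x = M2 E^H (E M2 E^H + lam I)^+ p_alias."""
    E, M2, lam, p = problem.E, problem.M2, problem.lam, problem.p_alias
    if not (np.isfinite(E).all() and np.isfinite(M2).all() and np.isfinite(p).all()):
        raise ValueError("non-finite values in unfolding problem")
    nf = E.shape[0]
    A = (E * M2[None, :]) @ E.conj().T + lam * np.eye(nf)
    rcond = nf * np.finfo(float).eps
    Ainv = np.linalg.pinv(A, rcond=rcond, hermitian=True)
    return M2 * (E.conj().T @ (Ainv @ p))


def _solve_batch(E: np.ndarray, M2: np.ndarray, lam: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Vectorized :func:`solve_weights` over readout positions.

    E: (nf, K); M2: (nx, K); lam: (nx,); P: (nx, nf)  ->  W: (nx, K)
    """
    nf = E.shape[0]
    A = np.einsum("mc,xc,nc->xmn", E, M2, E.conj(), optimize=True)
    A += lam[:, None, None] * np.eye(nf)[None]
    Ainv = np.linalg.pinv(A, rcond=nf * np.finfo(float).eps, hermitian=True)
    v = np.einsum("xmn,xn->xm", Ainv, P, optimize=True)
    return M2 * (v @ np.conj(E))


def estimate_noise_sigma(kt: KTData) -> float:
    """Robust per-sample complex noise std from the outer k-space corners.

    Uses acquired samples with both spatial frequencies beyond 35% of
    the Nyquist band, where object energy is negligible for smooth
    anatomy; the Rayleigh-median estimator ``sigma = median(|s|) /
    sqrt(ln 2)`` is insensitive to residual signal outliers.
    """
    nx, n_pe = kt.n_readout, kt.n_pe
    cx, cy = nx // 2, n_pe // 2
    kx_far = np.abs(np.arange(nx) - cx) > 0.35 * nx
    ky_far = np.abs(np.arange(n_pe) - cy) > 0.35 * n_pe
    corner = kt.data[:, kx_far, :, :][:, :, ky_far, :]
    vals = np.abs(corner)[:, :, kt.mask[ky_far, :]]
    if vals.size == 0:
        return 0.0
    return float(np.median(vals) / np.sqrt(np.log(2.0)))


def resolve_lam(kt: KTData, R: int, lam: float | None, lam_scale: float) -> float:
    """Default Tikhonov weight: the aliased x-f noise variance R * sigma^2.

    The diagonal loading in the regularized unfolding plays the role of
    the noise covariance of the aliased data vector; with unit-modulus
    lattice weights and the R-scale compensation that variance is
    R * sigma^2 per frequency bin.  ``lam_scale`` rescales it;
    an explicit ``lam`` overrides it entirely.
    """
    if lam is not None:
        return float(lam)
    return lam_scale * R * estimate_noise_sigma(kt) ** 2


def reconstruct_coil_xf(
    xf_alias: np.ndarray,
    basis: PCABasis,
    pattern: SamplingPattern,
    lam: float,
) -> np.ndarray:
    """Unfold one coil's aliased x-f data; returns the full-FOV x-f estimate.

    ``xf_alias`` must already carry the R scale compensation (see
    :func:`kt_to_xf`).  Loops over reduced-FOV rows, solving all readout
    positions of a row in one batched call.
    """
    nx, n_pe, nf = xf_alias.shape
    offsets = psf_offsets(pattern)
    weights = psf_weights(pattern)
    E = _encoding_matrix(basis, offsets, weights)
    n_pc = basis.n_pc
    W = np.zeros((nx, n_pe, n_pc), dtype=complex)
    n_red = n_pe // pattern.R
    for y_r in range(n_red):
        ys = _alias_locations(offsets, y_r, n_pe)
        M2 = np.concatenate(
            [np.abs(basis.W_train[:, y, :]) ** 2 for y in ys], axis=1
        )  # (nx, R*n_pc)
        lam_x = np.full(nx, float(lam))
        P = xf_alias[:, y_r, :]
        Wx = _solve_batch(E, M2, lam_x, P)  # (nx, R*n_pc)
        for i, y in enumerate(ys):
            W[:, y, :] = Wx[:, i * n_pc : (i + 1) * n_pc]
    return W @ basis.B  # (nx, n_pe, nf)


def reconstruct_traditional(
    kt_undersampled: KTData,
    kt_training: KTData,
    n_pc: int,
    lam: float | None = None,
    lam_scale: float = 1.0,
    pattern: SamplingPattern | None = None,
    bases: list[PCABasis] | None = None,
) -> ReconResult:
    """Standard k-t PCA, reconstructed channel by channel.

    Per coil: fit the temporal basis to that coil's training data,
    unfold every (x, reduced-y) location, synthesize x-f data as W·B and
    inverse-transform to the image series.

    Parameters
    ----------
    lam
        Absolute Tikhonov weight; ``None`` (default) uses the
        noise-matched choice ``lam_scale * R * sigma_hat^2`` with the
        noise level estimated from the outer k-space corners (see
        :func:`resolve_lam`).
    pattern
        Lattice description; inferred from the data mask when omitted.
    bases
        Pre-fitted per-coil bases (skips the training fit; used for
        linearity checks and basis reuse).
    """
    if pattern is None:
        pattern = infer_pattern(kt_undersampled)
    lam_value = resolve_lam(kt_undersampled, pattern.R, lam, lam_scale)
    xf_alias = kt_to_xf(kt_undersampled, scale=pattern.R)
    xf_train = kt_to_xf(kt_training)
    images = np.empty_like(kt_undersampled.data)
    used_bases = []
    for c in range(kt_undersampled.n_coils):
        basis = bases[c] if bases is not None else fit_basis(xf_train[c], n_pc)
        used_bases.append(basis)
        xf_rec = reconstruct_coil_xf(xf_alias[c].values, basis, pattern, lam_value)
        images[c] = freq_to_time(xf_rec, axis=-1)
    return ReconResult(
        images=images,
        method_tag="traditional",
        params={
            "n_pc": n_pc,
            "lam": lam_value,
            "lam_scale": lam_scale,
            "R": pattern.R,
            "training_profiles": list(pattern.training_profiles),
        },
    )


def infer_pattern(kt: KTData) -> SamplingPattern:
    """Recover (R, shift) of a sheared-grid mask from the data's mask."""
    mask = kt.mask
    n_pe, n_frames = mask.shape
    lines0 = np.flatnonzero(mask[:, 0])
    if lines0.size == 0:
        raise ValueError("frame 0 acquires no lines; not a sheared grid")
    if lines0.size == n_pe:
        R = 1
        shift = 0
    else:
        diffs = np.diff(lines0)
        R = int(diffs[0])
        if not (diffs == R).all():
            raise ValueError("mask is not a uniform lattice in frame 0")
        shift = 0
        if n_frames > 1:
            lines1 = np.flatnonzero(mask[:, 1])
            shift = int((lines1[0] - lines0[0]) % R)
    pat = SamplingPattern(
        R=R,
        n_pe=n_pe,
        n_frames=n_frames,
        acquired=mask.copy(),
        shift_per_frame=shift if R > 1 else 1,
    )
    # raises if the full mask deviates from the lattice
    if R > 1:
        psf_offsets(pat)
    return pat
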