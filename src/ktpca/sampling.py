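"""Sheared-grid lattice undersampling and training-profile extraction.

Accelerated dynamic acquisitions sample only every R-th phase-encode
line per frame, advancing the sampled comb by a fixed increment from
frame to frame.  On such a lattice the point spread function in (y, f)
space consists of exactly R discrete peaks, so each aliased x-f sample
is a sum of R true object samples — the structure the unfolding
reconstruction exploits.  A small fully sampled band around the k-space
center ("training profiles") is kept at full temporal resolution to
learn the temporal basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import KTData
from .transforms import dc_index, ifft2c, time_to_freq

__all__ = [
    "SamplingPattern",
    "make_sheared_grid",
    "psf_offsets",
    "psf_weights",
    "extract_training",
    "undersample",
]


@dataclass
class SamplingPattern:
    """Lattice sampling description for one dynamic acquisition.

    ``acquired[k, t]`` is True when phase-encode line ``k`` is sampled in
    frame ``t``.  Phase-encode index 0 is the most negative ky of the
    centered grid; the DC line sits at ``n_pe // 2``.
    """

    R: int
    n_pe: int
    n_frames: int
    acquired: np.ndarray
    shift_per_frame: int = 1
    training_profiles: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.acquired = np.asarray(self.acquired, dtype=bool)
        if self.acquired.shape != (self.n_pe, self.n_frames):
            raise ValueError("acquired mask shape must be (n_pe, n_frames)")


def make_sheared_grid(
    n_pe: int, n_frames: int, R: int, shift: int = 1
) -> SamplingPattern:
    """Build the interleaved lattice: frame t samples lines k ≡ t·shift (mod R).

    Every frame acquires ``ceil(n_pe / R)`` lines and, when R divides
    n_pe, any R consecutive frames jointly cover all lines.
    """
    if R < 1:
        raise ValueError(f"reduction factor R must be >= 1, got {R}")
    if R > n_pe:
        raise ValueError(f"R={R} exceeds n_pe={n_pe}")
    k = np.arange(n_pe)[:, None]
    t = np.arange(n_frames)[None, :]
    acquired = (k % R) == ((t * shift) % R)
    return SamplingPattern(
        R=R, n_pe=n_pe, n_frames=n_frames, acquired=acquired, shift_per_frame=shift
    )


def _require_lattice(pattern: SamplingPattern) -> None:
    if pattern.n_pe % pattern.R or pattern.n_frames % pattern.R:
        raise ValueError(
            "psf offsets are defined only for lattice patterns with R dividing "
            f"both n_pe and n_frames; got R={pattern.R}, n_pe={pattern.n_pe}, "
            f"n_frames={pattern.n_frames}. Use a generic-PSF reconstruction "
            "for non-lattice masks (not provided here)."
        )
    k = np.arange(pattern.n_pe)[:, None]
    t = np.arange(pattern.n_frames)[None, :]
    expected = (k % pattern.R) == ((t * pattern.shift_per_frame) % pattern.R)
    if not np.array_equal(pattern.acquired, expected):
        raise ValueError(
            "mask is not the sheared-grid lattice described by (R, shift); "
            "use a generic-PSF reconstruction for arbitrary masks (not provided here)."
        )


def psf_offsets(pattern: SamplingPattern) -> list[tuple[int, int]]:
    """The R aliasing offsets (Δy, Δf) of the lattice point spread function.

    For the sheared grid the PSF is nonzero at exactly R points:
    ``Δy_i = i * n_pe / R`` paired with ``Δf_i = (i * shift * n_frames / R)
    mod n_frames``, i = 0..R-1, with (0, 0) first.  The offsets form a
    group under addition modulo (n_pe, n_frames).
    """
    _require_lattice(pattern)
    R, n_pe, n_t = pattern.R, pattern.n_pe, pattern.n_frames
    dy = n_pe // R
    df = (pattern.shift_per_frame * (n_t // R)) % n_t
    return [(i * dy % n_pe, i * df % n_t) for i in range(R)]


def psf_weights(pattern: SamplingPattern) -> np.ndarray:
    """Complex PSF amplitude at each aliasing offset, normalized so full
    sampling gives weight 1.

    The weights are obtained by pushing the mask through the exact
    transform chain used for the data (inverse spatial FFT along the
    phase-encode axis, forward temporal FFT), so any phase introduced by
    the centered-grid conventions is captured exactly.  For a lattice
    all weights have unit modulus; the aliased data times R is then the
    unit-row-vector sum of the R true x-f samples with these phases.
    """
    offsets = psf_offsets(pattern)
    m = pattern.acquired.astype(complex)[None, None, :, :]
    psf = time_to_freq(ifft2c(m, axes=(1, 2)), axis=-1)[0, 0]
    cy, cf = dc_index(pattern.n_pe), dc_index(pattern.n_frames)
    norm = np.sqrt(pattern.n_pe * pattern.n_frames) / pattern.R
    w = np.empty(len(offsets), dtype=complex)
    for i, (dy, df) in enumerate(offsets):
        w[i] = psf[(cy + dy) % pattern.n_pe, (cf + df) % pattern.n_frames] / norm
    return w


def training_indices(n_pe: int, n_profiles: int) -> np.ndarray:
    """Indices of the central ``n_profiles`` phase-encode lines (DC included)."""
    if n_profiles > n_pe:
        raise ValueError(f"n_profiles={n_profiles} exceeds n_pe={n_pe}")
    c = dc_index(n_pe)
    lo = c - n_profiles // 2
    return np.arange(lo, lo + n_profiles)


def extract_training(kt: KTData, n_profiles: int) -> KTData:
    """Cut the central fully sampled band: low spatial, full temporal resolution.

    Returns k-t data that is zero outside the central ``n_profiles``
    phase-encode lines, carrying its own all-frames mask on those lines.
    """
    idx = training_indices(kt.n_pe, n_profiles)
    if not kt.mask[idx, :].all():
        missing = [int(i) for i in idx if not kt.mask[i, :].all()]
        raise ValueError(
            f"training profiles {missing} are not fully sampled across all frames"
        )
    mask = np.zeros((kt.n_pe, kt.n_frames), dtype=bool)
    mask[idx, :] = True
    data = np.zeros_like(kt.data)
    data[:, :, idx, :] = kt.data[:, :, idx, :]
    return KTData(data, mask)


def undersample(kt: KTData, pattern: SamplingPattern) -> KTData:
    """Zero every non-acquired sample and attach the pattern mask (idempotent)."""
    if (pattern.n_pe, pattern.n_frames) != (kt.n_pe, kt.n_frames):
        raise ValueError(
            f"pattern grid {(pattern.n_pe, pattern.n_frames)} does not match "
            f"data grid {(kt.n_pe, kt.n_frames)}"
        )
    data = kt.data * pattern.acquired[None, None, :, :]
    return KTData(data, pattern.acquired.copy())
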