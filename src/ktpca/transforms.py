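"""Fixed Fourier conventions shared by every stage.

All spatial transforms are unitary (``norm="ortho"``) and DC-centered:
index ``n // 2`` of an axis of length ``n`` holds the zero-frequency
sample.  The temporal transform maps the frame axis to a DC-centered
temporal-frequency axis with the same unitary scaling.  These
conventions are fixed here once; no other module calls numpy's FFT
directly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fft2c",
    "ifft2c",
    "time_to_freq",
    "freq_to_time",
    "dc_index",
]


def dc_index(n: int) -> int:
    """Index of the zero-frequency (DC) sample on a centered axis."""
    return n // 2


def fft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Unitary, DC-centered 2-D forward FFT (image -> k-space)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Unitary, DC-centered 2-D inverse FFT (k-space -> image)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def time_to_freq(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unitary forward FFT along the frame axis; output DC-centered.

    The time origin is frame 0 (no input shift): a static series maps to
    a single nonzero bin at ``dc_index(n_frames)``.
    """
    return np.fft.fftshift(np.fft.fft(x, axis=axis, norm="ortho"), axes=axis)


def freq_to_time(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Inverse of :func:`time_to_freq`."""
    return np.fft.ifft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho")
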