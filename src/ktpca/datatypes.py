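"""Core containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KTData", "DynamicSeries"]


@dataclass
class KTData:
    """Multi-coil dynamic k-space data with its sampling mask.

    Attributes
    ----------
    data
        Complex k-space samples, shape ``(n_coils, n_readout, n_pe,
        n_frames)``.  Non-acquired samples are stored as zero.
    mask
        Boolean acquisition mask over phase-encode lines and frames,
        shape ``(n_pe, n_frames)``.  The readout axis is always fully
        sampled, so the mask does not carry a readout dimension.
    """

    data: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(
                f"KTData.data must be 4-D (coil, readout, pe, frame); got shape {self.data.shape}"
            )
        if self.mask.shape != (self.data.shape[2], self.data.shape[3]):
            raise ValueError(
                f"mask shape {self.mask.shape} does not match (n_pe, n_frames)="
                f"{(self.data.shape[2], self.data.shape[3])}"
            )

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_readout(self) -> int:
        return self.data.shape[1]

    @property
    def n_pe(self) -> int:
        return self.data.shape[2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def copy(self) -> "KTData":
        return KTData(self.data.copy(), self.mask.copy())


@dataclass
class DynamicSeries:
    """Ground-truth dynamic object with coil sensitivities and ROI labels.

    Attributes
    ----------
    truth
        Complex noiseless image series, shape ``(n_readout, n_pe, n_frames)``.
    sensitivities
        Complex coil maps, shape ``(n_coils, n_readout, n_pe)``, smooth and
        normalized to unit root-sum-of-squares.
    object_mask
        Boolean support of the object, shape ``(n_readout, n_pe)``.
    roi_labels
        Integer label image; 1 and 2 mark the two ventricle-like regions.
    roi_curves
        Enhancement curve per labelled region, shape ``(n_rois, n_frames)``
        (the temporal ground truth for the ROI time-course checks).
    """

    truth: np.ndarray
    sensitivities: np.ndarray
    object_mask: np.ndarray
    roi_labels: np.ndarray
    roi_curves: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_frames(self) -> int:
        return self.truth.shape[-1]
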