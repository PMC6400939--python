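"""Frame calibration and biopsy assembly.

A core-needle biopsy is imaged with a fiber-bundle microendoscope one frame
per millimetre of tissue.  The camera runs with automatic gain and exposure,
and absolute sensitivity drifts between imaging sessions, so raw intensities
are not comparable across frames.  This module puts every frame on a common
intensity scale (division by a fluorescence-slide reference and by the
gain/exposure ratio relative to that reference) and then assembles the
calibrated frames of a biopsy into one stitched image whose masked pixels are
pooled into a single vector for distribution-based analysis.

Stitching here is side-by-side concatenation in site order.  All downstream
statistics operate on the pooled pixel distribution, which is invariant to
where frames are placed, so no registration or overlap blending is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FluorescenceFrame:
    """One masked fluorescence frame for a single 1-mm biopsy site.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (arbitrary units).
    mask
        Boolean array of the same shape; True inside the field of view.
    gain
        Camera gain (unitless, > 0).
    exposure
        Exposure time in milliseconds (> 0).
    session_id
        Identifier of the imaging session the frame was acquired in.
    """

    pixels: np.ndarray
    mask: np.ndarray
    gain: float = 1.0
    exposure: float = 1.0
    session_id: str = "default"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"pixels shape {self.pixels.shape} != mask shape {self.mask.shape}"
            )
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be non-negative")
        if self.gain <= 0 or self.exposure <= 0:
            raise ValueError("gain and exposure must be positive")

    @property
    def masked_pixels(self) -> np.ndarray:
        """Masked intensities as a flat vector (row-major order)."""
        return self.pixels[self.mask]


@dataclass(frozen=True)
class CalibrationReference:
    """Per-session fluorescence-slide reference used to normalise frames."""

    session_id: str
    slide_mean: float
    reference_gain: float = 1.0
    reference_exposure: float = 1.0

    def __post_init__(self) -> None:
        if self.slide_mean <= 0:
            raise ValueError("slide_mean must be positive")
        if self.reference_gain <= 0 or self.reference_exposure <= 0:
            raise ValueError("reference gain/exposure must be positive")


@dataclass
class StitchedImage:
    """Calibrated frames of one biopsy placed side by side.

    ``pooled_pixels`` holds every masked pixel, frame by frame in site order;
    it is the sample all distribution features are computed from.
    """

    biopsy_id: str
    frame_layout: np.ndarray
    pooled_pixels: np.ndarray
    n_frames: int = field(default=0)


def calibrate_frame(
    frame: FluorescenceFrame, ref: CalibrationReference
) -> FluorescenceFrame:
    """Normalise a frame to its session's fluorescence-slide reference.

    Output pixels are ``pixels / (slide_mean * (gain/reference_gain) *
    (exposure/reference_exposure))``.  The correction is linear, so frames
    from different sessions (or different automatic gain/exposure settings)
    become directly comparable.  The mask is unchanged and the output frame
    carries the reference gain/exposure.
    """
    if frame.session_id != ref.session_id:
        raise ValueError(
            f"frame session {frame.session_id!r} does not match "
            f"reference session {ref.session_id!r}"
        )
    factor = (
        ref.slide_mean
        * (frame.gain / ref.reference_gain)
        * (frame.exposure / ref.reference_exposure)
    )
    return FluorescenceFrame(
        pixels=frame.pixels / factor,
        mask=frame.mask.copy(),
        gain=ref.reference_gain,
        exposure=ref.reference_exposure,
        session_id=frame.session_id,
    )


def stitch_biopsy(
    frames: list[FluorescenceFrame], biopsy_id: str = ""
) -> StitchedImage:
    """Concatenate calibrated frames side by side and pool masked pixels.

    Frames must share dimensions.  Frame *k*'s masked pixels precede frame
    *k+1*'s in ``pooled_pixels``, so pooling conserves the pixel multiset.
    """
    if not frames:
        raise ValueError("cannot stitch an empty frame list")
    shape = frames[0].pixels.shape
    for i, f in enumerate(frames):
        if f.pixels.shape != shape:
            raise ValueError(
                f"frame {i} shape {f.pixels.shape} differs from frame 0 shape {shape}"
            )
    layout = np.hstack([f.pixels for f in frames])
    pooled = np.concatenate([f.masked_pixels for f in frames])
    return StitchedImage(
        biopsy_id=biopsy_id,
        frame_layout=layout,
        pooled_pixels=pooled,
        n_frames=len(frames),
    )
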