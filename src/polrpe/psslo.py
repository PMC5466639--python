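"""PS-SLO depolarized light image.

A polarization-sensitive scanning laser ophthalmoscope illuminates the retina
with linearly polarized light at a series of input polarization angles and
records the crossed-detector return per angle.  Polarization-preserving
structures leak into the crossed detector through an angle-dependent
(sinusoidal, period pi) crosstalk term, whereas depolarizing structures return
an angle-independent floor; the per-pixel minimum over all input angles
therefore isolates the depolarized contribution.  The raw minimum image is
rescaled min-to-max to an 8-bit 0-255 grayscale for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PssloStack:
    """Crossed-detector frames, shape (n_angles, x, b); angles in radians.

    The uncrossed-detector frames are carried for completeness but are not
    used by the depolarized-light computation.
    """

    frames: np.ndarray
    angles: np.ndarray
    uncrossed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (angles, x, b)")
        if len(self.angles) != self.frames.shape[0]:
            raise ValueError("angle count does not match frame count")

    @property
    def n_angles(self) -> int:
        return self.frames.shape[0]


@dataclass
class DepolarizedImage:
    """Per-pixel minimum crossed-detector value over the input angles."""

    raw: np.ndarray
    display: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.display = rescale_grayscale(self.raw)


def depolarized_light_image(stack: PssloStack) -> DepolarizedImage:
    """Minimum value per pixel over all input polarization angles."""
    if stack.n_angles < 2:
        raise ValueError("need at least 2 input polarization angles to minimize")
    return DepolarizedImage(raw=stack.frames.min(axis=0))


def rescale_grayscale(raw: np.ndarray) -> np.ndarray:
    """Min-to-max brightness adjustment to a 0-255 grayscale.

    G = round(255 * (D - min D) / (max D - min D)), rounding half away from
    zero; a constant image (degenerate range) maps to all zeros.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros(raw.shape, dtype=np.uint8)
    scaled = 255.0 * (raw - lo) / (hi - lo)
    return np.floor(scaled + 0.5).astype(np.uint8)  # half away from zero (values >= 0)
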