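"""Centered unitary 2D Fourier transforms.

Single k-space convention for the whole package: DC at index ``floor(n/2)``
on each axis, orthonormal (unitary) normalization, applied over the last two
axes so multi-coil stacks pass through unchanged.
"""
from __future__ import annotations

import numpy as np

_AXES = (-2, -1)


def fft2c(x: np.ndarray) -> np.ndarray:
    """Image -> centered k-space, unitary."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def ifft2c(y: np.ndarray) -> np.ndarray:
    """Centered k-space -> image, unitary."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(y, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )
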