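"""Orthonormal multilevel Haar transform used as the sparsifying transform.

Periodization boundary handling keeps the transform square and orthonormal,
so Parseval holds exactly and the l1-proximal step of the reconstruction is
a plain soft-threshold in coefficient space.
"""
from __future__ import annotations

import numpy as np
import pywt


class WaveletOperator:
    """Orthonormal 2D multilevel Haar analysis/synthesis.

    ``forward`` returns a coefficient array of the same shape as the image
    (periodization mode); ``inverse`` is its exact inverse for any image
    whose sides are divisible by ``2**levels``.
    """

    family = "haar"

    def __init__(self, levels: int = 3, boundary: str = "periodization"):
        if levels < 1:
            raise ValueError("levels must be >= 1")
        self.levels = levels
        self.boundary = boundary
        self._slices_cache: dict[tuple[int, int], list] = {}

    def _check_shape(self, shape: tuple[int, int]) -> None:
        div = 2**self.levels
        if shape[0] % div or shape[1] % div:
            raise ValueError(
                f"image sides {shape} must be divisible by 2**levels = {div}"
            )

    def forward(self, image: np.ndarray) -> np.ndarray:
        self._check_shape(image.shape)
        coeffs = pywt.wavedec2(image, self.family, mode=self.boundary, level=self.levels)
        arr, slices = pywt.coeffs_to_array(coeffs)
        self._slices_cache[image.shape] = slices
        return arr

    def inverse(self, coeff_array: np.ndarray) -> np.ndarray:
        self._check_shape(coeff_array.shape)
        slices = self._slices_cache.get(coeff_array.shape)
        if slices is None:
            # reconstruct the slice layout by transforming a dummy image
            self.forward(np.zeros(coeff_array.shape))
            slices = self._slices_cache[coeff_array.shape]
        coeffs = pywt.array_to_coeffs(coeff_array, slices, output_format="wavedec2")
        return pywt.waverec2(coeffs, self.family, mode=self.boundary)


class IdentityTransform:
    """Fallback transform (levels = 0): coefficients are the image itself."""

    family = "identity"
    levels = 0

    def forward(self, image: np.ndarray) -> np.ndarray:
        return image

    def inverse(self, coeff_array: np.ndarray) -> np.ndarray:
        return coeff_array


def max_feasible_levels(shape: tuple[int, int], requested: int) -> int:
    """Largest decomposition depth <= requested dividing both sides."""
    lv = 0
    while lv < requested and shape[0] % 2 ** (lv + 1) == 0 and shape[1] % 2 ** (lv + 1) == 0:
        lv += 1
    return lv
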