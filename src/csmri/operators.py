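"""Multi-coil Cartesian encoding (SENSE-type) system operator.

The forward operator maps an image to masked multi-coil k-space:
coil-sensitivity multiplication, unitary 2D Fourier transform, phase-encode
masking.  With RSS-normalized coil maps and a unitary FFT the masking is an
orthogonal projection, so the operator norm is at most 1 — which fixes the
safe gradient step of the iterative reconstruction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import SamplingMask
from .fourier import fft2c, ifft2c
from .phantom import CoilSet


@dataclass
class SystemOperator:
    """A = mask ∘ F ∘ coil-multiplication, with its adjoint."""

    coils: CoilSet
    mask: SamplingMask
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.coils.shape != self.image_shape:
            raise ValueError("coil maps do not match image shape")
        if self.mask.n_pe != self.image_shape[0]:
            raise ValueError("mask does not match phase-encode size")
        self._line_mask = self.mask.bool_mask()

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Image -> masked multi-coil k-space (unsampled slots zero)."""
        if image.shape != self.image_shape:
            raise ValueError("image shape mismatch")
        k = fft2c(self.coils.sensitivities * image[None])
        k[:, ~self._line_mask, :] = 0.0
        return k

    def adjoint(self, kspace: np.ndarray) -> np.ndarray:
        """Masked multi-coil k-space -> coil-combined image:
        sum_c conj(S_c) * IFFT(mask * k_c)."""
        if kspace.shape != (self.coils.n_coils, *self.image_shape):
            raise ValueError("k-space shape mismatch")
        k = kspace.copy()
        k[:, ~self._line_mask, :] = 0.0
        return np.sum(np.conj(self.coils.sensitivities) * ifft2c(k), axis=0)

    def normal(self, image: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(image))

    def max_eigenvalue(self, n_iter: int = 30, seed: int = 0) -> float:
        """Largest eigenvalue of AᴴA (squared operator norm) by power
        iteration; the Lipschitz constant of the data-fidelity gradient."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(self.image_shape) + 1j * rng.standard_normal(self.image_shape)
        x /= np.linalg.norm(x)
        lam = 0.0
        for _ in range(n_iter):
            y = self.normal(x)
            norm = np.linalg.norm(y)
            if norm == 0 or not np.isfinite(norm):
                raise RuntimeError("power iteration failed (zero or non-finite iterate)")
            lam = norm
            x = y / norm
        return float(lam)
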