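"""Quantitative image-quality surrogates.

Reader studies score artifact level, organ-margin sharpness and
small-structure visibility on an ordinal scale; those judgements are not
computable, so the simulator scores reconstructions with standard full-
reference metrics against the known ground-truth image instead: NRMSE,
PSNR, SSIM and a label-boundary edge-sharpness measure.

All metrics operate on magnitude images.  Reconstructions can differ from
the reference by a global scale, so report-level comparisons first rescale
the test image to the reference's l2 norm; the raw ``nrmse`` primitive is
deliberately left unscaled (it is reference-normalized and therefore not
symmetric in its arguments).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import BACKGROUND


def normalize_to_reference(test: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rescale ``test`` to the l2 norm of ``reference`` (global scale only)."""
    tn = np.linalg.norm(test)
    if tn == 0:
        return test
    return test * (np.linalg.norm(reference) / tn)


def nrmse(test: np.ndarray, reference: np.ndarray) -> float:
    """||test - reference||_2 / ||reference||_2."""
    if test.shape != reference.shape:
        raise ValueError("shape mismatch")
    rn = np.linalg.norm(reference)
    if rn == 0:
        raise ValueError("reference image is identically zero")
    return float(np.linalg.norm(test - reference) / rn)


def psnr_db(test: np.ndarray, reference: np.ndarray) -> float:
    """Peak signal-to-noise ratio (dB), peak = reference maximum."""
    if test.shape != reference.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean(np.abs(test - reference) ** 2))
    if mse == 0:
        return float("inf")
    return float(20 * np.log10(reference.max()) - 10 * np.log10(mse))


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    half = (size - 1) / 2
    g = np.exp(-((np.arange(size) - half) ** 2) / (2 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim(
    test: np.ndarray,
    reference: np.ndarray,
    window: int = 11,
    constants: tuple[float, float] = (0.01, 0.03),
    sigma: float = 1.5,
    data_range: float | None = None,
) -> float:
    """Mean structural similarity with a Gaussian window.

    Local weighted means/variances/covariance are computed at every pixel
    where the full window fits (no border padding), and the SSIM map is
    averaged over that valid region.  ``data_range`` defaults to the
    reference maximum.
    """
    if test.shape != reference.shape:
        raise ValueError("shape mismatch")
    if window > min(test.shape):
        raise ValueError("window larger than image")
    k1, k2 = constants
    if data_range is None:
        data_range = float(reference.max())
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    w = _gaussian_window(window, sigma)
    from numpy.lib.stride_tricks import sliding_window_view

    tw = sliding_window_view(np.asarray(test, dtype=float), (window, window))
    rw = sliding_window_view(np.asarray(reference, dtype=float), (window, window))
    mu_t = np.einsum("ijkl,kl->ij", tw, w)
    mu_r = np.einsum("ijkl,kl->ij", rw, w)
    var_t = np.einsum("ijkl,kl->ij", (tw - mu_t[..., None, None]) ** 2, w)
    var_r = np.einsum("ijkl,kl->ij", (rw - mu_r[..., None, None]) ** 2, w)
    cov = np.einsum(
        "ijkl,kl->ij",
        (tw - mu_t[..., None, None]) * (rw - mu_r[..., None, None]),
        w,
    )
    num = (2 * mu_t * mu_r + c1) * (2 * cov + c2)
    den = (mu_t**2 + mu_r**2 + c1) * (var_t + var_r + c2)
    return float(np.mean(num / den))


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Pixels of non-background labels bordering a different label
    (4-neighbourhood)."""
    diff = np.zeros(labels.shape, dtype=bool)
    diff[:-1, :] |= labels[:-1, :] != labels[1:, :]
    diff[1:, :] |= labels[1:, :] != labels[:-1, :]
    diff[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    diff[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    return diff & (labels != BACKGROUND)


def edge_sharpness(image: np.ndarray, labels: np.ndarray) -> float:
    """Mean finite-difference gradient magnitude over tissue-boundary
    pixels — a proxy for perceived organ-margin sharpness (blur lowers it)."""
    if image.shape != labels.shape:
        raise ValueError("labels must align with the image")
    boundary = _boundary_mask(labels)
    if not np.any(boundary):
        raise ValueError("label map has no boundary pixels")
    gy, gx = np.gradient(np.asarray(image, dtype=float))
    grad = np.sqrt(gy**2 + gx**2)
    return float(grad[boundary].mean())


@dataclass
class MetricsReport:
    """All quality metrics of one reconstruction against the ground truth."""

    nrmse: float
    psnr_db: float
    ssim: float
    edge_sharpness: float | None = None
    per_label_nrmse: dict[int, float] = field(default_factory=dict)

    @classmethod
    def from_images(
        cls,
        test: np.ndarray,
        reference: np.ndarray,
        labels: np.ndarray | None = None,
    ) -> "MetricsReport":
        """Score magnitude images after matching the test image's global
        scale to the reference."""
        test = np.abs(np.asarray(test))
        reference = np.abs(np.asarray(reference))
        test = normalize_to_reference(test, reference)
        per_label: dict[int, float] = {}
        sharp = None
        if labels is not None:
            sharp = edge_sharpness(test, labels)
            for lab in np.unique(labels):
                if lab == BACKGROUND:
                    continue
                m = labels == lab
                ref_n = np.linalg.norm(reference[m])
                if ref_n > 0:
                    per_label[int(lab)] = float(
                        np.linalg.norm(test[m] - reference[m]) / ref_n
                    )
        return cls(
            nrmse=nrmse(test, reference),
            psnr_db=psnr_db(test, reference),
            ssim=ssim(test, reference),
            edge_sharpness=sharp,
            per_label_nrmse=per_label,
        )
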