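"""Procedural abdominal phantom and receive-coil simulation.

The phantom emulates a T2-weighted upper-abdominal slice at the level needed
for reconstruction experiments: a piecewise-smooth object with known tissue
masks, per-tissue proton-density and T2 values, a slowly varying phase map,
and optional focal lesions.  Two lesion classes are modelled:

* ``fluid`` — cyst-like, very long T2 (>= 500 ms), bright on T2 weighting;
* ``solid`` — mid-range T2 (60-120 ms), moderate signal.

Geometry is an ellipse/blob composition, not an anatomical atlas; what the
experiments need is piecewise-smooth structure with exactly known masks, so
that reconstruction error can be attributed per tissue.

Coil sensitivities are smooth complex maps, root-sum-of-squares normalized,
emulating a flexible anterior array combined with spine coil elements.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

# tissue label codes
BACKGROUND = 0
BODY = 1
LIVER = 2
SPLEEN = 3
FLUID_LESION = 10
SOLID_LESION = 20

LABEL_NAMES = {
    BACKGROUND: "background",
    BODY: "body",
    LIVER: "liver",
    SPLEEN: "spleen",
    FLUID_LESION: "fluid_lesion",
    SOLID_LESION: "solid_lesion",
}

# per-tissue (proton density a.u., T2 range ms)
_TISSUE_PD = {BODY: 0.70, LIVER: 0.85, SPLEEN: 0.80, FLUID_LESION: 1.0, SOLID_LESION: 0.75}


@dataclass
class Lesion:
    """Record of one inserted focal lesion."""

    center: tuple[int, int]
    radius: float  # px
    tissue_class: str  # "fluid" | "solid"
    label: int


@dataclass
class Phantom:
    """Ground-truth 2D object the forward model images.

    All maps share one shape.  ``proton_density`` is non-negative,
    ``t2_map`` strictly positive on the object support, ``phase_map`` is a
    low-order polynomial (slowly varying by construction).
    """

    proton_density: np.ndarray
    t2_map: np.ndarray
    phase_map: np.ndarray
    labels: np.ndarray
    pixel_size: float  # mm, isotropic
    lesion_list: list[Lesion] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.proton_density.shape

    def ground_truth_image(self, te_ms: float) -> np.ndarray:
        """Complex T2-weighted reference image at echo time ``te_ms``:
        ``pd * exp(-TE/T2) * exp(i*phase)``."""
        return (
            self.proton_density
            * np.exp(-te_ms / self.t2_map)
            * np.exp(1j * self.phase_map)
        )

    def lesion_mask(self) -> np.ndarray:
        return self.labels >= FLUID_LESION

    def without_decay(self) -> "Phantom":
        """Copy with effectively infinite T2 (decay-free forward model)."""
        return replace(self, t2_map=np.full_like(self.t2_map, 1e12))


@dataclass
class CoilSet:
    """Complex receive-coil sensitivity maps, RSS-normalized on support."""

    sensitivities: np.ndarray  # (coil, rows, cols) complex
    support_mask: np.ndarray  # (rows, cols) bool

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.sensitivities.shape[1:]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.sensitivities) ** 2, axis=0))


def _ellipse_mask(shape, center, semi_axes, angle_rad=0.0) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def make_phantom(
    shape: tuple[int, int],
    n_lesions: int = 0,
    lesion_classes: Sequence[str] = ("fluid", "solid"),
    seed: int = 0,
    *,
    t2_parenchyma: tuple[float, float] = (40.0, 60.0),
    t2_solid: tuple[float, float] = (60.0, 120.0),
    t2_fluid: tuple[float, float] = (600.0, 1200.0),
    t2_body: tuple[float, float] = (60.0, 90.0),
    phase_amplitude: float = 0.5,
    pixel_size: float = 1.5,
    max_placement_tries: int = 200,
) -> Phantom:
    """Generate a piecewise-smooth abdominal-like phantom.

    Parameters
    ----------
    shape : (rows, cols), each >= 32.
    n_lesions : number of focal lesions to insert (cycled through
        ``lesion_classes``); lesions are placed inside the liver without
        overlapping each other.
    phase_amplitude : radians; amplitude scale of the low-order polynomial
        phase map.  Homodyne reconstruction assumes a slowly varying phase,
        and this knob lets experiments probe that assumption.
    seed : all randomness is drawn from ``numpy.random.default_rng(seed)``;
        identical arguments give bit-identical phantoms.

    Raises
    ------
    ValueError on invalid sizes or classes; RuntimeError if a lesion cannot
    be placed without overlap within ``max_placement_tries`` attempts.
    """
    rows, cols = shape
    if rows < 32 or cols < 32:
        raise ValueError("phantom shape must be at least 32x32")
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    for cls in lesion_classes:
        if cls not in ("fluid", "solid"):
            raise ValueError(f"unknown lesion class {cls!r}")
    if n_lesions > 0 and not lesion_classes:
        raise ValueError("lesion_classes empty but n_lesions > 0")

    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)

    c0 = (rows * 0.5, cols * 0.5)
    body = _ellipse_mask(shape, c0, (rows * 0.38, cols * 0.45))
    labels[body] = BODY

    liver = _ellipse_mask(
        shape, (rows * 0.48, cols * 0.36), (rows * 0.26, cols * 0.24), angle_rad=0.25
    )
    liver &= body
    labels[liver] = LIVER

    spleen = _ellipse_mask(
        shape, (rows * 0.42, cols * 0.74), (rows * 0.10, cols * 0.07), angle_rad=-0.4
    )
    spleen &= body
    labels[spleen] = SPLEEN

    # lesion placement: inside liver, pairwise non-overlapping, bounded retries
    lesions: list[Lesion] = []
    occupied = np.zeros(shape, dtype=bool)
    liver_idx = np.argwhere(labels == LIVER)
    for i in range(n_lesions):
        cls = lesion_classes[i % len(lesion_classes)]
        label = FLUID_LESION if cls == "fluid" else SOLID_LESION
        placed = False
        for _ in range(max_placement_tries):
            center = liver_idx[rng.integers(len(liver_idx))]
            radius = float(rng.uniform(max(2.0, min(shape) / 32), min(shape) / 16))
            mask = _ellipse_mask(shape, center, (radius, radius))
            # must sit fully in liver tissue and not touch earlier lesions
            if not np.all(labels[mask] == LIVER):
                continue
            if np.any(occupied & mask):
                continue
            labels[mask] = label
            occupied |= mask
            lesions.append(Lesion(tuple(int(v) for v in center), radius, cls, label))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {i} without overlap after "
                f"{max_placement_tries} tries"
            )

    # T2: one draw per tissue region from its configured range, then a mild
    # smooth multiplicative field so the object is not piecewise constant
    t2 = np.ones(shape)  # background kept positive (unused: pd = 0 there)
    ranges = {
        BODY: t2_body,
        LIVER: t2_parenchyma,
        SPLEEN: t2_parenchyma,
        FLUID_LESION: t2_fluid,
        SOLID_LESION: t2_solid,
    }
    region_t2 = {lab: float(rng.uniform(*rg)) for lab, rg in ranges.items()}
    for lab, val in region_t2.items():
        t2[labels == lab] = val
    smooth_mod = gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 12)
    smooth_mod = 1.0 + 0.06 * smooth_mod / max(np.abs(smooth_mod).max(), 1e-12)
    t2 = t2 * smooth_mod
    # the modulation must not push any region outside its configured range
    for lab, rg in ranges.items():
        sel = labels == lab
        t2[sel] = np.clip(t2[sel], rg[0], rg[1])
    t2 = np.clip(t2, 1e-3, None)

    pd = np.zeros(shape)
    for lab, val in _TISSUE_PD.items():
        pd[labels == lab] = val
    pd_mod = gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 10)
    pd_mod = 1.0 + 0.05 * pd_mod / max(np.abs(pd_mod).max(), 1e-12)
    pd = np.clip(pd * pd_mod, 0.0, None)

    # low-order polynomial phase in normalized coordinates [-1, 1]
    y = np.linspace(-1, 1, rows)[:, None]
    x = np.linspace(-1, 1, cols)[None, :]
    coef = rng.uniform(-1, 1, size=6)
    poly = (
        coef[0]
        + coef[1] * x
        + coef[2] * y
        + coef[3] * x * y
        + coef[4] * x**2
        + coef[5] * y**2
    )
    phase = phase_amplitude * poly / max(np.abs(poly).max(), 1e-12)

    return Phantom(
        proton_density=pd,
        t2_map=t2,
        phase_map=phase,
        labels=labels,
        pixel_size=pixel_size,
        lesion_list=lesions,
    )


def simulate_coils(
    shape: tuple[int, int],
    n_coils: int,
    smoothness: float = 12.0,
    seed: int = 0,
    support_mask: np.ndarray | None = None,
) -> CoilSet:
    """Smooth complex coil-sensitivity maps, RSS-normalized on support.

    Each coil is a Gaussian envelope centred on the object periphery (coils
    ring the body) times a smooth complex perturbation band-limited by
    ``smoothness`` (spatial scale in pixels).  ``n_coils == 1`` returns the
    identity sensitivity.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    rows, cols = shape
    if support_mask is None:
        support_mask = np.ones(shape, dtype=bool)

    if n_coils == 1:
        sens = np.ones((1, rows, cols), dtype=complex)
        sens[0, ~support_mask] = 0.0
        return CoilSet(sens, support_mask)

    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:rows, 0:cols]
    center = np.array([rows / 2, cols / 2])
    ring_r = 0.55 * min(rows, cols)
    sigma_env = 0.60 * min(rows, cols)

    sens = np.empty((n_coils, rows, cols), dtype=complex)
    for c in range(n_coils):
        theta = 2 * np.pi * c / n_coils + rng.uniform(-0.15, 0.15)
        cy = center[0] + ring_r * np.sin(theta)
        cx = center[1] + ring_r * np.cos(theta)
        env = np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sigma_env**2))
        pert = gaussian_filter(rng.standard_normal(shape), smoothness) + 1j * gaussian_filter(
            rng.standard_normal(shape), smoothness
        )
        scale = np.abs(pert).max()
        pert = 0.25 * pert / max(scale, 1e-12)
        # smooth linear phase per coil
        lin_phase = (rng.uniform(-1, 1) * (rr - cy) + rng.uniform(-1, 1) * (cc - cx)) / max(
            rows, cols
        )
        sens[c] = env * (1.0 + pert) * np.exp(1j * lin_phase)

    rss = np.sqrt(np.sum(np.abs(sens) ** 2, axis=0))
    sens = np.where(support_mask[None], sens / np.maximum(rss[None], 1e-30), 0.0)
    return CoilSet(sens, support_mask)
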