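"""Single-shot fast-spin-echo (SSFSE) acquisition simulation.

Covers the acquisition side of the experiment: protocol records and their
echo-train arithmetic, phase-encode sampling patterns (variable-density,
uniform parallel-imaging geometry, partial Fourier, full), the echo-train
forward model with per-line T2 decay and complex Gaussian noise, the
fully-sampled-center reference scan used for coil calibration, and the
interleaved slice-ordering rule.

Conventions: phase encode is axis 0 (rows) of the image, readout axis 1;
k-space is DC-centered at index ``floor(n/2)`` with a unitary FFT; line
indices are 0-based.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fourier import fft2c
from .phantom import CoilSet, Phantom

MASK_KINDS = ("variable_density", "uniform", "partial_fourier", "full", "acs")
SEQUENCE_KINDS = ("ssfse_conv", "mtse", "ssfse_cs")


@dataclass
class ProtocolParams:
    """Acquisition protocol record.

    ``acceleration`` is the total phase-encode acceleration factor R (a
    parallel-imaging factor for conventional SSFSE, the CS factor for the
    accelerated variant).  ``partial_fourier`` is the retained fraction of
    phase-encode lines (6/8 = 0.75 for conventional SSFSE; 1.0 = none).
    ``n_acs`` is the number of autocalibration lines of the reference scan.
    """

    matrix_read: int
    matrix_pe: int
    acceleration: float
    partial_fourier: float = 1.0
    n_acs: int = 24
    tr_ms: float = 500.0
    te_ms: float = 99.0
    echo_spacing_ms: float = 1.5
    n_slices: int = 32
    slice_increment: int = 2
    flip_deg: float = 120.0
    bandwidth_hz: float | None = None  # stored for completeness, unused
    sequence_kind: str = "ssfse_cs"

    def __post_init__(self) -> None:
        if self.matrix_pe < 32:
            raise ValueError("matrix_pe must be >= 32")
        if self.acceleration < 1:
            raise ValueError("acceleration must be >= 1")
        if not (0.5 < self.partial_fourier <= 1.0):
            raise ValueError("partial_fourier must be in (0.5, 1]")
        if self.n_acs < 0 or self.n_acs % 2 != 0:
            raise ValueError("n_acs must be a non-negative even count")
        if self.slice_increment < 1:
            raise ValueError("slice_increment must be >= 1")
        if self.sequence_kind not in SEQUENCE_KINDS:
            raise ValueError(f"unknown sequence_kind {self.sequence_kind!r}")


#: Published reference protocols (3 T liver T2WI, two scanner platforms).
PROTOCOLS: dict[str, ProtocolParams] = {
    "skyra_ssfse_conv": ProtocolParams(
        matrix_read=256, matrix_pe=256, acceleration=2, partial_fourier=0.75,
        tr_ms=732, te_ms=100, n_slices=42, slice_increment=2, flip_deg=106,
        bandwidth_hz=977, sequence_kind="ssfse_conv",
    ),
    "vida_ssfse_conv": ProtocolParams(
        matrix_read=384, matrix_pe=250, acceleration=2, partial_fourier=0.75,
        tr_ms=1000, te_ms=99, n_slices=42, slice_increment=2, flip_deg=154,
        bandwidth_hz=372, sequence_kind="ssfse_conv",
    ),
    "skyra_ssfse_cs": ProtocolParams(
        matrix_read=384, matrix_pe=253, acceleration=3.0, n_acs=24,
        tr_ms=500, te_ms=99, n_slices=32, slice_increment=4, flip_deg=118,
        bandwidth_hz=372, sequence_kind="ssfse_cs",
    ),
    "vida_ssfse_cs": ProtocolParams(
        matrix_read=384, matrix_pe=253, acceleration=3.0, n_acs=24,
        tr_ms=561, te_ms=96, n_slices=32, slice_increment=4, flip_deg=135,
        bandwidth_hz=685, sequence_kind="ssfse_cs",
    ),
    "skyra_mtse": ProtocolParams(
        matrix_read=384, matrix_pe=307, acceleration=2,
        tr_ms=2040, te_ms=101, n_slices=42, flip_deg=134,
        bandwidth_hz=1085, sequence_kind="mtse",
    ),
    "vida_mtse": ProtocolParams(
        matrix_read=384, matrix_pe=307, acceleration=2,
        tr_ms=1700, te_ms=99, n_slices=42, flip_deg=140,
        bandwidth_hz=303, sequence_kind="mtse",
    ),
}


def echo_train_length(params: ProtocolParams) -> int:
    """Sampled-imaging-line budget per shot: ``floor(matrix_pe / R)``.

    Defined for single-shot sequences only; a multishot TSE distributes
    lines over several excitations and needs a shots-based calculation.
    """
    if params.sequence_kind == "mtse":
        raise ValueError(
            "echo_train_length is defined for single-shot sequences; "
            "multishot TSE requires a shots-based calculator (not provided)"
        )
    return int(math.floor(params.matrix_pe / params.acceleration))


@dataclass
class SamplingMask:
    """Phase-encode sampling pattern.

    ``sampled_lines`` is an ordered index list (acquisition order); indices
    are unique and in ``[0, n_pe)``.
    """

    n_pe: int
    sampled_lines: np.ndarray
    kind: str
    acs_lines: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sampled_lines = np.asarray(self.sampled_lines, dtype=int)
        self.acs_lines = np.asarray(self.acs_lines, dtype=int)
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}")
        if len(np.unique(self.sampled_lines)) != len(self.sampled_lines):
            raise ValueError("sampled lines must be unique")
        if len(self.sampled_lines) and (
            self.sampled_lines.min() < 0 or self.sampled_lines.max() >= self.n_pe
        ):
            raise ValueError("sampled line indices out of range")

    @property
    def n_sampled(self) -> int:
        return len(self.sampled_lines)

    @property
    def effective_acceleration(self) -> float:
        return self.n_pe / self.n_sampled

    def bool_mask(self) -> np.ndarray:
        m = np.zeros(self.n_pe, dtype=bool)
        m[self.sampled_lines] = True
        return m

    def reordered(self, order: str) -> "SamplingMask":
        """Copy with sampled_lines permuted to ``linear`` (ascending) or
        ``center_out`` (by distance from the center line) order."""
        lines = np.sort(self.sampled_lines)
        if order == "center_out":
            c = self.n_pe // 2
            lines = lines[np.lexsort((lines, np.abs(lines - c)))]
        elif order != "linear":
            raise ValueError(f"unknown ordering {order!r}")
        return SamplingMask(self.n_pe, lines, self.kind, self.acs_lines, self.seed)


def full_mask(n_pe: int) -> SamplingMask:
    return SamplingMask(n_pe, np.arange(n_pe), "full")


def build_vd_mask(
    n_pe: int,
    budget: int,
    center_fraction: float = 24 / 84,
    accel_increment: float = 1.0,
    seed: int = 0,
) -> SamplingMask:
    """Variable-density phase-encode mask: fully sampled contiguous center
    block of ``round(center_fraction * budget)`` lines plus peripheral lines
    drawn without replacement from a density decreasing linearly from the
    k-space center, with slope set by ``accel_increment`` (0 = uniform).
    """
    if budget > n_pe:
        raise ValueError("budget exceeds number of phase-encode lines")
    n_center = int(round(center_fraction * budget))
    if n_center < 1:
        raise ValueError("center_fraction * budget must be >= 1")
    if n_center > budget:
        raise ValueError("center block exceeds the line budget")
    if accel_increment < 0:
        raise ValueError("accel_increment must be >= 0")

    c = n_pe // 2
    lo = c - n_center // 2
    center_block = np.arange(lo, lo + n_center)
    if center_block[0] < 0 or center_block[-1] >= n_pe:
        raise ValueError("center block does not fit in k-space")

    rest = np.setdiff1d(np.arange(n_pe), center_block)
    n_extra = budget - n_center
    if n_extra > 0:
        d_max = max(np.abs(rest - c).max(), 1)
        w = np.maximum(1.0 - accel_increment * np.abs(rest - c) / d_max, 0.02)
        rng = np.random.default_rng(seed)
        extra = rng.choice(rest, size=n_extra, replace=False, p=w / w.sum())
    else:
        extra = np.array([], dtype=int)

    lines = np.sort(np.concatenate([center_block, extra]))
    return SamplingMask(n_pe, lines, "variable_density", acs_lines=center_block, seed=seed)


def build_uniform_mask(n_pe: int, r: int, offset: int = 0) -> SamplingMask:
    """Uniform (parallel-imaging geometry) mask: lines ``offset, offset+r, ...``."""
    if r < 1:
        raise ValueError("undersampling factor r must be >= 1")
    if not (0 <= offset < r):
        raise ValueError("offset must satisfy 0 <= offset < r")
    lines = np.arange(offset, n_pe, r)
    return SamplingMask(n_pe, lines, "uniform")


def build_pf_mask(n_pe: int, fraction: float) -> SamplingMask:
    """Partial-Fourier mask: one contiguous asymmetric block of
    ``ceil(fraction * n_pe)`` lines covering the upper half of k-space plus
    the symmetric margin below the center line; the center is always kept.
    """
    if not (0.5 < fraction <= 1.0):
        raise ValueError("partial-Fourier fraction must exceed 1/2 (homodyne needs > half coverage)")
    k = int(math.ceil(fraction * n_pe))
    lo = n_pe - k
    lines = np.arange(lo, n_pe)
    return SamplingMask(n_pe, lines, "partial_fourier")


@dataclass
class KSpaceData:
    """Multi-coil Cartesian k-space of one slice.

    ``data`` has shape (coil, pe-line, readout); unsampled line slots are
    zero.  ``echo_times_ms[i]`` is the effective echo time at which line
    ``mask.sampled_lines[i]`` was acquired.
    """

    data: np.ndarray
    mask: SamplingMask
    echo_times_ms: np.ndarray
    noise_sigma: float = 0.0
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.echo_times_ms) != self.mask.n_sampled:
            raise ValueError("one echo time per sampled line required")
        if self.data.shape[1] != self.mask.n_pe:
            raise ValueError("data/mask phase-encode size mismatch")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


def _echo_schedule(mask: SamplingMask, params: ProtocolParams, ordering: str):
    """Acquisition order and per-line effective echo times.

    The center-most sampled line is pinned to the nominal TE; the other
    lines sit at multiples of the echo spacing before/after it according to
    their position in the echo train.
    """
    ordered = mask.reordered(ordering)
    lines = ordered.sampled_lines
    c = mask.n_pe // 2
    e_center = int(np.argmin(np.abs(lines - c)))
    te = params.te_ms + (np.arange(len(lines)) - e_center) * params.echo_spacing_ms
    return ordered, te


def acquire(
    phantom: Phantom,
    coils: CoilSet,
    mask: SamplingMask,
    params: ProtocolParams,
    ordering: str = "linear",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> KSpaceData:
    """Simulate one SSFSE echo train.

    Each sampled line ``j``, acquired at echo index ``e(j)``, is the
    corresponding row of the unitary 2D FFT of
    ``coil * pd * exp(-te_eff(j)/T2) * exp(i*phase)``, where the effective
    echo time of the center-most line equals the protocol TE and neighbours
    are offset by the echo spacing — the per-line decay that causes the T2
    blurring long echo trains are known for.  Independent complex Gaussian
    noise (standard deviation ``noise_sigma`` per real/imaginary component)
    is added to every acquired sample.
    """
    if mask.n_pe != params.matrix_pe:
        raise ValueError("mask.n_pe must equal params.matrix_pe")
    if phantom.shape != (params.matrix_pe, params.matrix_read):
        raise ValueError("phantom shape must equal (matrix_pe, matrix_read)")
    if coils.shape != phantom.shape:
        raise ValueError("coil maps must match the phantom shape")

    ordered, te_eff = _echo_schedule(mask, params, ordering)
    rows, cols = phantom.shape
    data = np.zeros((coils.n_coils, rows, cols), dtype=complex)

    base = phantom.proton_density * np.exp(1j * phantom.phase_map)
    for i, line in enumerate(ordered.sampled_lines):
        weighted = base * np.exp(-te_eff[i] / phantom.t2_map)
        k = fft2c(coils.sensitivities * weighted[None])
        data[:, line, :] = k[:, line, :]

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        idx = ordered.sampled_lines
        shape = (coils.n_coils, len(idx), cols)
        noise = noise_sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
        data[:, idx, :] += noise

    return KSpaceData(data, ordered, te_eff, noise_sigma=noise_sigma)


def acquire_reference(
    phantom: Phantom,
    coils: CoilSet,
    params: ProtocolParams,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> KSpaceData:
    """Reference (calibration) scan: a second echo train acquiring a fully
    sampled contiguous block of ``params.n_acs`` center lines, same forward
    model as :func:`acquire`."""
    if params.n_acs == 0:
        raise ValueError("reference scan requires n_acs > 0 calibration lines")
    if params.n_acs > params.matrix_pe:
        raise ValueError("n_acs exceeds matrix_pe")
    c = params.matrix_pe // 2
    lo = c - params.n_acs // 2
    lines = np.arange(lo, lo + params.n_acs)
    kind = "full" if params.n_acs == params.matrix_pe else "acs"
    mask = SamplingMask(params.matrix_pe, lines, kind, acs_lines=lines)
    ks = acquire(phantom, coils, mask, params, ordering="linear",
                 noise_sigma=noise_sigma, seed=seed)
    ks.is_reference = True
    return ks


def slice_order(n_slices: int, increment: int) -> np.ndarray:
    """Interleaved slice acquisition order with stride ``increment``:
    ``0, inc, 2*inc, ..., 1, 1+inc, ...`` — a permutation of all slices that
    separates temporally adjacent acquisitions by ``increment`` positions
    (except at pass boundaries), reducing slice crosstalk at short TR."""
    if not (1 <= increment <= n_slices):
        raise ValueError("increment must satisfy 1 <= increment <= n_slices")
    order = [s for start in range(increment) for s in range(start, n_slices, increment)]
    return np.array(order, dtype=int)
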