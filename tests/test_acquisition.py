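"""Acquisition simulation: protocol arithmetic, sampling masks, the
echo-train forward model, reference scan and slice ordering."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csmri import (
    PROTOCOLS,
    KSpaceData,
    ProtocolParams,
    acquire,
    acquire_reference,
    build_pf_mask,
    build_uniform_mask,
    build_vd_mask,
    echo_train_length,
    full_mask,
    make_phantom,
    simulate_coils,
    slice_order,
)
from csmri.fourier import fft2c, ifft2c
from csmri.phantom import CoilSet, Phantom


# --- echo-train arithmetic -------------------------------------------------

@pytest.mark.parametrize(
    "protocol,expected",
    [("skyra_ssfse_cs", 84), ("vida_ssfse_conv", 125), ("skyra_ssfse_conv", 128)],
)
def test_echo_train_length_matches_published_protocols(protocol, expected):
    assert echo_train_length(PROTOCOLS[protocol]) == expected


def test_echo_train_length_identity_without_acceleration():
    p = ProtocolParams(matrix_read=64, matrix_pe=200, acceleration=1.0)
    assert echo_train_length(p) == 200


def test_echo_train_length_rejects_multishot():
    with pytest.raises(ValueError):
        echo_train_length(PROTOCOLS["skyra_mtse"])


# --- masks -----------------------------------------------------------------

def test_vd_mask_hits_budget_and_effective_acceleration():
    m = build_vd_mask(253, 84, seed=0)
    assert m.n_sampled == 84
    assert round(m.effective_acceleration, 1) == 3.0
    assert m.kind == "variable_density"


def test_vd_mask_full_budget_is_full_mask():
    m = build_vd_mask(64, 64, seed=1)
    assert np.array_equal(np.sort(m.sampled_lines), np.arange(64))


def test_vd_mask_center_density_exceeds_periphery():
    """Windowed density counting over many seeds: the central 21-line
    window must contain more sampled lines than outer 21-line windows."""
    n_pe, budget, width = 253, 84, 21
    c = n_pe // 2
    central, outer = [], []
    for seed in range(200):
        sel = build_vd_mask(n_pe, budget, seed=seed).bool_mask()
        central.append(sel[c - width // 2 : c + width // 2 + 1].sum())
        outer.append(sel[:width].sum())
        outer.append(sel[-width:].sum())
    assert np.mean(central) > np.mean(outer)


def test_vd_mask_determinism_and_errors():
    a = build_vd_mask(128, 43, seed=5)
    b = build_vd_mask(128, 43, seed=5)
    assert np.array_equal(a.sampled_lines, b.sampled_lines)
    with pytest.raises(ValueError):
        build_vd_mask(64, 65)
    with pytest.raises(ValueError):
        build_vd_mask(64, 10, center_fraction=0.01)


@pytest.mark.parametrize(
    "n_pe,r,offset,expected_count",
    [(250, 2, 0, 125), (16, 1, 0, 16), (16, 3, 1, 5)],
)
def test_uniform_mask_counts(n_pe, r, offset, expected_count):
    m = build_uniform_mask(n_pe, r, offset)
    assert m.n_sampled == expected_count
    assert np.array_equal(m.sampled_lines, np.arange(offset, n_pe, r))


def test_uniform_mask_enumeration_and_error():
    assert list(build_uniform_mask(16, 3, 1).sampled_lines) == [1, 4, 7, 10, 13]
    with pytest.raises(ValueError):
        build_uniform_mask(16, 0)


@pytest.mark.parametrize("n_pe,fraction,expected", [(256, 6 / 8, 192), (253, 6 / 8, 190)])
def test_pf_mask_retained_counts(n_pe, fraction, expected):
    m = build_pf_mask(n_pe, fraction)
    assert m.n_sampled == expected
    assert n_pe // 2 in m.sampled_lines
    assert np.all(np.diff(np.sort(m.sampled_lines)) == 1)  # contiguous


def test_pf_mask_full_fraction_and_error():
    assert build_pf_mask(64, 1.0).n_sampled == 64
    with pytest.raises(ValueError):
        build_pf_mask(64, 0.5)


@settings(derandomize=True, max_examples=25)
@given(
    n_pe=st.integers(40, 300),
    accel=st.floats(1.0, 4.0),
    seed=st.integers(0, 100),
)
def test_vd_mask_line_count_property(n_pe, accel, seed):
    budget = int(n_pe / accel)
    m = build_vd_mask(n_pe, budget, seed=seed)
    assert m.n_sampled == budget
    assert len(np.unique(m.sampled_lines)) == budget


# --- forward model ---------------------------------------------------------

def _square_params(n, **kw):
    return ProtocolParams(matrix_read=n, matrix_pe=n, acceleration=1.0, **kw)


def test_acquire_decay_free_limit_is_exact_fft(uniform_coil):
    ph = make_phantom((64, 64), n_lesions=1, seed=2).without_decay()
    params = _square_params(64)
    ks = acquire(ph, uniform_coil((64, 64)), full_mask(64), params)
    expected = fft2c(ph.ground_truth_image(params.te_ms))
    assert np.abs(ks.data[0] - expected).max() < 1e-10


def test_acquire_inverts_exactly_in_ideal_conditions(uniform_coil):
    """Full sampling, no decay, no noise, uniform coil: unitary inverse FFT
    recovers the object (Parseval-level accuracy)."""
    ph = make_phantom((64, 64), n_lesions=0, seed=6).without_decay()
    ks = acquire(ph, uniform_coil((64, 64)), full_mask(64), _square_params(64))
    img = ifft2c(ks.data[0])
    gt = ph.ground_truth_image(99.0)
    assert np.abs(img - gt).max() < 1e-10
    assert abs(np.linalg.norm(ks.data) - np.linalg.norm(gt)) < 1e-10


def test_t2_decay_broadens_the_point_spread_function(uniform_coil):
    """A point impulse imaged with a finite-T2 echo train has a PE-direction
    PSF wider than one pixel (T2 blurring), measured numerically."""
    n = 64
    pd = np.zeros((n, n))
    pd[n // 2, n // 2] = 1.0
    ph = Phantom(
        proton_density=pd,
        t2_map=np.full((n, n), 80.0),
        phase_map=np.zeros((n, n)),
        labels=(pd > 0).astype(np.int32),
        pixel_size=1.5,
    )
    params = _square_params(n, te_ms=99.0, echo_spacing_ms=1.5)
    ks = acquire(ph, uniform_coil((n, n)), full_mask(n), params)
    psf = np.abs(ifft2c(ks.data[0]))[:, n // 2]
    half = psf.max() / 2
    # interpolate half-maximum crossing points around the peak
    peak = int(np.argmax(psf))
    left = peak
    while left > 0 and psf[left - 1] >= half:
        left -= 1
    right = peak
    while right < n - 1 and psf[right + 1] >= half:
        right += 1
    lo = left - 1 + (half - psf[left - 1]) / (psf[left] - psf[left - 1]) if left > 0 else left
    hi = right + (half - psf[right]) / (psf[right + 1] - psf[right]) if right < n - 1 else right
    fwhm = hi - lo
    assert fwhm > 1.0


def test_acquire_noise_statistics(uniform_coil):
    """Monte-Carlo check: with a zero object, the acquired samples are pure
    complex Gaussian noise of the configured per-component std."""
    n = 128
    ph = Phantom(
        proton_density=np.zeros((n, n)),
        t2_map=np.ones((n, n)),
        phase_map=np.zeros((n, n)),
        labels=np.zeros((n, n), dtype=np.int32),
        pixel_size=1.5,
    )
    sigma = 0.37
    ks = acquire(ph, uniform_coil((n, n)), full_mask(n), _square_params(n),
                 noise_sigma=sigma, seed=12)
    samples = ks.data[0].ravel()
    assert len(samples) >= 10**4
    assert abs(np.std(samples.real) - sigma) / sigma < 0.05
    assert abs(np.std(samples.imag) - sigma) / sigma < 0.05


def test_acquire_seed_determinism_and_shape_checks(phantom64, coils64, params64):
    m = build_vd_mask(64, 21, seed=0)
    a = acquire(phantom64, coils64, m, params64, noise_sigma=0.01, seed=3)
    b = acquire(phantom64, coils64, m, params64, noise_sigma=0.01, seed=3)
    assert np.array_equal(a.data, b.data)
    with pytest.raises(ValueError):
        acquire(phantom64, coils64, build_vd_mask(128, 43), params64)


def test_data_nonzero_only_at_sampled_slots(phantom64, coils64, params64):
    m = build_vd_mask(64, 21, seed=1)
    ks = acquire(phantom64, coils64, m, params64, noise_sigma=0.01, seed=4)
    unsampled = ~m.bool_mask()
    assert np.all(ks.data[:, unsampled, :] == 0)
    assert len(ks.echo_times_ms) == m.n_sampled


# --- reference scan --------------------------------------------------------

def test_reference_scan_carries_contiguous_center_acs(phantom64, coils64, params64):
    ref = acquire_reference(phantom64, coils64, params64)
    lines = np.sort(ref.mask.sampled_lines)
    assert ref.is_reference
    assert len(lines) == 24
    assert np.all(np.diff(lines) == 1)
    assert 32 in lines


def test_reference_rows_match_full_acquisition(uniform_coil):
    ph = make_phantom((64, 64), n_lesions=1, seed=8)
    coil = uniform_coil((64, 64))
    params = ProtocolParams(matrix_read=64, matrix_pe=64, acceleration=1.0, n_acs=24)
    ref = acquire_reference(ph, coil, params)
    full = acquire(ph, coil, full_mask(64), params)
    rows = np.sort(ref.mask.sampled_lines)
    assert np.abs(ref.data[0, rows] - full.data[0, rows]).max() == 0.0


def test_full_acs_reference_equals_full_acquisition(uniform_coil):
    ph = make_phantom((64, 64), n_lesions=0, seed=9)
    coil = uniform_coil((64, 64))
    params = ProtocolParams(matrix_read=64, matrix_pe=64, acceleration=1.0, n_acs=64)
    ref = acquire_reference(ph, coil, params)
    full = acquire(ph, coil, full_mask(64), params)
    assert np.abs(ref.data - full.data).max() == 0.0


def test_reference_requires_acs_lines(phantom64, coils64):
    params = ProtocolParams(matrix_read=64, matrix_pe=64, acceleration=1.0, n_acs=0)
    with pytest.raises(ValueError):
        acquire_reference(phantom64, coils64, params)


# --- slice ordering --------------------------------------------------------

def test_slice_order_stride_rule():
    assert list(slice_order(8, 4)) == [0, 4, 1, 5, 2, 6, 3, 7]


def test_slice_order_identity_and_errors():
    assert list(slice_order(5, 1)) == [0, 1, 2, 3, 4]
    with pytest.raises(ValueError):
        slice_order(4, 5)


@settings(derandomize=True, max_examples=50)
@given(n=st.integers(1, 60), data=st.data())
def test_slice_order_is_a_permutation(n, data):
    inc = data.draw(st.integers(1, n))
    order = slice_order(n, inc)
    assert sorted(order) == list(range(n))
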