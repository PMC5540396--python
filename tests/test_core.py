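"""Core k-t PCA machinery: transforms, basis fit, encoding, regularized solve."""

import numpy as np
import pytest

from ktpca import (
    KTData,
    PCABasis,
    UnfoldingProblem,
    XFData,
    build_unfolding,
    fit_basis,
    kt_to_xf,
    make_sheared_grid,
    psf_offsets,
    psf_weights,
    solve_weights,
    undersample,
)
from ktpca.core import reconstruct_coil_xf, xf_to_kt, infer_pattern, reconstruct_traditional
from ktpca.transforms import dc_index
from ktpca.variants import combine_coils
from ktpca.evaluation import m_nrmse


def random_kt(rng, n_coils=1, nx=4, n_pe=8, nt=8):
    data = rng.standard_normal((n_coils, nx, n_pe, nt)) + 1j * rng.standard_normal(
        (n_coils, nx, n_pe, nt)
    )
    return KTData(data, np.ones((n_pe, nt), bool))


def test_xf_round_trip_is_identity():
    rng = np.random.default_rng(0)
    kt = random_kt(rng, n_coils=2)
    xf = kt_to_xf(kt)
    back = xf_to_kt(np.stack([x.values for x in xf]))
    assert np.abs(back - kt.data).max() < 1e-10


def test_static_series_concentrates_in_dc_bin(small_kt):
    static = KTData(
        np.repeat(small_kt.data[:, :, :, :1], small_kt.n_frames, axis=3),
        small_kt.mask,
    )
    xf = kt_to_xf(static)[0].values
    dc = dc_index(small_kt.n_frames)
    off_dc = np.delete(xf, dc, axis=-1)
    assert np.abs(off_dc).max() < 1e-10 * np.abs(xf).max()


def test_lattice_impulse_aliases_at_psf_offsets():
    """An impulse object under an R=4 lattice folds into exactly 4 x-f copies."""
    n_pe = nt = 8
    kt_full = np.zeros((1, 4, n_pe, nt), complex)
    img = np.zeros((4, n_pe, nt), complex)
    img[2, 3, :] = np.exp(2j * np.pi * 2 * np.arange(nt) / nt)  # moving impulse
    from ktpca.transforms import fft2c

    kt_full = KTData(fft2c(img, axes=(0, 1))[None], np.ones((n_pe, nt), bool))
    pat = make_sheared_grid(n_pe, nt, 4, 1)
    xf_alias = kt_to_xf(undersample(kt_full, pat), scale=4)[0].values
    xf_true = kt_to_xf(kt_full)[0].values
    # true signal occupies one (y, f) point; the aliased data occupies 4
    y0, f0 = np.argwhere(np.abs(xf_true[2]) > 1e-9)[0]
    hot = set(map(tuple, np.argwhere(np.abs(xf_alias[2]) > 1e-9)))
    expected = {
        ((y0 + dy) % n_pe, (f0 + df) % nt) for dy, df in psf_offsets(pat)
    }
    assert hot == expected


def make_training_xf(rng, nx=4, ny=8, nf=8, rank=None):
    mat = rng.standard_normal((nx * ny, nf)) + 1j * rng.standard_normal((nx * ny, nf))
    if rank is not None:
        u, s, vh = np.linalg.svd(mat, full_matrices=False)
        s[rank:] = 0
        mat = (u * s) @ vh
    return XFData(mat.reshape(nx, ny, nf))


def test_basis_rows_orthonormal_and_complete_basis_exact():
    rng = np.random.default_rng(1)
    xf = make_training_xf(rng)
    basis = fit_basis(xf, 8)
    assert np.abs(basis.B @ basis.B.conj().T - np.eye(8)).max() < 1e-10
    recon = basis.W_train.reshape(-1, 8) @ basis.B
    rel = np.linalg.norm(recon - xf.values.reshape(-1, 8)) / np.linalg.norm(xf.values)
    assert rel < 1e-10


def test_rank_one_training_reconstructed_by_single_component():
    rng = np.random.default_rng(2)
    xf = make_training_xf(rng, rank=1)
    basis = fit_basis(xf, 1)
    recon = basis.W_train.reshape(-1, 1) @ basis.B
    rel = np.linalg.norm(recon - xf.values.reshape(-1, 8)) / np.linalg.norm(xf.values)
    assert rel < 1e-10


def test_truncation_residual_matches_discarded_singular_values():
    rng = np.random.default_rng(3)
    xf = make_training_xf(rng, nx=8, ny=8, nf=8)
    s = np.linalg.svd(xf.values.reshape(64, 8), compute_uv=False)
    for n_pc in (2, 5):
        basis = fit_basis(xf, n_pc)
        resid = np.linalg.norm(
            xf.values.reshape(64, 8) - basis.W_train.reshape(64, n_pc) @ basis.B
        )
        assert abs(resid - np.sqrt(np.sum(s[n_pc:] ** 2))) < 1e-10 * s[0]


def test_fit_basis_rejects_out_of_range_component_count():
    rng = np.random.default_rng(4)
    xf = make_training_xf(rng)
    with pytest.raises(ValueError, match="n_pc"):
        fit_basis(xf, 0)
    with pytest.raises(ValueError, match="n_pc"):
        fit_basis(xf, 9)


def _basis_on_grid(rng, n_pe, nf, n_pc, unit_weights=False):
    b = fit_basis(make_training_xf(rng, nx=2, ny=n_pe, nf=nf), n_pc)
    if unit_weights:
        b.W_train = np.exp(1j * rng.uniform(0, 2 * np.pi, b.W_train.shape))
    return b


def test_unfolding_r1_reduces_to_transposed_basis():
    rng = np.random.default_rng(5)
    basis = _basis_on_grid(rng, 8, 8, 3)
    pat = make_sheared_grid(8, 8, 1, 1)
    prob = build_unfolding(
        basis, psf_offsets(pat), pat, x=0, y_reduced=2,
        p_alias=np.zeros(8), lam=0.0,
    )
    assert prob.E.shape == (8, 3)
    assert np.abs(prob.E - basis.B.T).max() < 1e-12


def test_unfolding_columns_are_frequency_shifts_of_alias_zero():
    rng = np.random.default_rng(6)
    basis = _basis_on_grid(rng, 8, 8, 2)
    pat = make_sheared_grid(8, 8, 4, 1)
    offsets = psf_offsets(pat)
    weights = psf_weights(pat)
    prob = build_unfolding(
        basis, offsets, pat, x=0, y_reduced=0, p_alias=np.zeros(8), lam=0.0
    )
    n_pc = basis.n_pc
    for i, (_, df) in enumerate(offsets):
        blk = prob.E[:, i * n_pc : (i + 1) * n_pc]
        ref = np.roll(prob.E[:, :n_pc] / weights[0], df, axis=0) * weights[i]
        assert np.abs(blk - ref).max() < 1e-12


def test_unit_modulus_training_weights_give_identity_covariance():
    rng = np.random.default_rng(7)
    basis = _basis_on_grid(rng, 8, 8, 2, unit_weights=True)
    pat = make_sheared_grid(8, 8, 4, 1)
    prob = build_unfolding(
        basis, psf_offsets(pat), pat, x=1, y_reduced=1, p_alias=np.zeros(8), lam=0.0
    )
    assert np.allclose(prob.M2, 1.0, atol=1e-12)


def test_solve_zero_data_gives_zero_weights():
    rng = np.random.default_rng(8)
    E = rng.standard_normal((8, 6)) + 1j * rng.standard_normal((8, 6))
    prob = UnfoldingProblem(E=E, M2=np.ones(6), lam=0.5, p_alias=np.zeros(8))
    assert np.all(solve_weights(prob) == 0)


def test_solve_square_invertible_unregularized_is_exact_inverse():
    rng = np.random.default_rng(9)
    E = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
    p = rng.standard_normal(6) + 1j * rng.standard_normal(6)
    prob = UnfoldingProblem(E=E, M2=np.ones(6), lam=0.0, p_alias=p)
    w = solve_weights(prob)
    assert np.abs(w - np.linalg.solve(E, p)).max() < 1e-8 * np.abs(p).max()


def test_solve_rejects_non_finite_input():
    prob = UnfoldingProblem(
        E=np.full((4, 2), np.nan, complex), M2=np.ones(2), lam=0.0, p_alias=np.zeros(4)
    )
    with pytest.raises(ValueError, match="finite"):
        solve_weights(prob)


def brute_force_tikhonov(E, M2, lam, p):
    """Independent oracle: normal equations of min ||Ew-p||^2 + lam ||M^-1 w||^2."""
    Minv2 = np.diag(1.0 / M2)
    lhs = E.conj().T @ E + lam * Minv2
    return np.linalg.solve(lhs, E.conj().T @ p)


@pytest.mark.parametrize("trial", range(25))
def test_solver_matches_brute_force_tikhonov_minimizer(trial):
    rng = np.random.default_rng(100 + trial)
    nf = int(rng.integers(4, 17))
    k = int(rng.integers(2, min(13, nf + 4)))
    E = rng.standard_normal((nf, k)) + 1j * rng.standard_normal((nf, k))
    M2 = rng.uniform(0.1, 3.0, k)
    lam = float(rng.uniform(1e-4, 1.0))
    p = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    w = solve_weights(UnfoldingProblem(E=E, M2=M2, lam=lam, p_alias=p))
    ref = brute_force_tikhonov(E, M2, lam, p)
    assert np.linalg.norm(w - ref) < 1e-8 * np.linalg.norm(ref)


@pytest.mark.parametrize("R", [2, 4])
def test_noiseless_in_span_phantom_recovered_exactly(small_series, small_kt, true_maps, R):
    """With the basis spanning the true temporal subspace and no
    regularization, lattice unfolding recovers the object to numerical
    precision."""
    pat = make_sheared_grid(32, 16, R, 1)
    from ktpca import extract_training

    kt_u = undersample(small_kt, pat)
    kt_tr = extract_training(small_kt, 11)
    rec = reconstruct_traditional(kt_u, kt_tr, n_pc=6, lam=0.0)
    img = combine_coils(rec, true_maps)
    assert m_nrmse(img, small_series.truth) < 1e-8


def test_full_sampling_complete_basis_equals_zero_filled_reference(small_kt):
    from ktpca import extract_training
    from ktpca.transforms import ifft2c

    pat = make_sheared_grid(32, 16, 1, 1)
    kt_u = undersample(small_kt, pat)
    kt_tr = extract_training(small_kt, small_kt.n_pe)
    rec = reconstruct_traditional(kt_u, kt_tr, n_pc=small_kt.n_frames, lam=0.0)
    ref = ifft2c(small_kt.data, axes=(1, 2))
    assert np.abs(rec.images - ref).max() < 1e-8 * np.abs(ref).max()


def test_reconstruction_linear_in_data_for_fixed_basis(small_kt, small_acq):
    from ktpca.core import fit_basis, kt_to_xf

    kt_u, kt_tr = small_acq["undersampled"], small_acq["training"]
    bases = [fit_basis(xf, 6) for xf in kt_to_xf(kt_tr)]
    a = 1.7 - 0.4j
    rec1 = reconstruct_traditional(kt_u, kt_tr, 6, lam=1e-3, bases=bases)
    scaled = KTData(a * kt_u.data, kt_u.mask)
    rec2 = reconstruct_traditional(scaled, kt_tr, 6, lam=1e-3, bases=bases)
    assert np.abs(rec2.images - a * rec1.images).max() < 1e-8 * np.abs(rec1.images).max()


def test_pattern_inferred_from_mask_matches_generator(small_kt):
    for R, shift in [(2, 1), (4, 1), (4, 3)]:
        pat = make_sheared_grid(32, 16, R, shift)
        kt_u = undersample(small_kt, pat)
        inferred = infer_pattern(kt_u)
        assert inferred.R == R
        assert np.array_equal(inferred.acquired, pat.acquired)
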