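import math

import numpy as np
import pytest

from conftest_helpers import svd_2x2_closed_form  # noqa: F401  (see file docstring)
from membrox.io import AxisKind, SpectralMatrix
from membrox.svd import (
    ScoreMode,
    choose_dimensionality,
    decompose,
    omega_scores,
    reconstruct,
    sigma_cutoff_dimensionality,
)


def wrap(M, wavelengths=None, axis=AxisKind.wavelength):
    M = np.asarray(M, dtype=float)
    wl = np.arange(M.shape[0], dtype=float) if wavelengths is None else wavelengths
    return SpectralMatrix(wl, M, [{"col": float(j)} for j in range(M.shape[1])], axis)


def test_identical_columns_are_rank_one():
    col = np.array([1.0, 2.0, 0.5, 0.1])
    res = decompose(wrap(np.column_stack([col] * 3)))
    assert res.singular_values[1] == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(
        reconstruct(res, 1).intensities, np.column_stack([col] * 3), atol=1e-12
    )


def test_orthonormal_columns_give_unit_singular_values():
    res = decompose(wrap([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]))
    np.testing.assert_allclose(res.singular_values, [1.0, 1.0])


def test_full_rank_reconstruction_matches_input():
    rng = np.random.default_rng(42)
    M = rng.normal(size=(6, 4))
    res = decompose(wrap(M))
    err = np.linalg.norm(reconstruct(res, 4).intensities - M) / np.linalg.norm(M)
    assert err < 1e-10


def test_basis_and_coefficients_are_orthonormal():
    rng = np.random.default_rng(3)
    res = decompose(wrap(rng.normal(size=(8, 5))))
    np.testing.assert_allclose(res.basis.T @ res.basis, np.eye(5), atol=1e-10)
    np.testing.assert_allclose(
        res.coefficients.T @ res.coefficients, np.eye(5), atol=1e-10
    )


def test_m_less_than_n_is_a_hard_error():
    with pytest.raises(ValueError, match="m >= n"):
        decompose(wrap(np.ones((2, 3))))
    with pytest.raises(ValueError, match="zero"):
        decompose(wrap(np.zeros((3, 2))))


def test_dimensionality_choice_rules():
    col = np.array([1.0, 2.0, 0.5])
    rank1 = decompose(wrap(np.column_stack([col, 2 * col])))
    assert choose_dimensionality(rank1, 0.9) == 1
    assert choose_dimensionality(rank1, 1.0) == rank1.rank == 1

    rng = np.random.default_rng(0)
    res = decompose(wrap(rng.normal(size=(6, 4))))
    assert choose_dimensionality(res, 1.0) == 4
    # sigma-ratio criterion: a component 1000x below sigma_1 is dropped
    M = np.diag([1.0, 1e-4, 1e-4])[:, :3]
    res2 = decompose(wrap(M))
    assert sigma_cutoff_dimensionality(res2, ratio=300) == 1
    assert sigma_cutoff_dimensionality(res2, ratio=1e6) == 3


def test_variance_criterion_separates_coupled_from_independent_455():
    """A 455 nm by-product tightly coupled to the 530 nm peak adds no second
    component; an independent 455 nm amplitude does."""
    wl = np.arange(400.0, 701.0)
    s530 = np.exp(-0.5 * ((wl - 530) / 22) ** 2)
    s455 = np.exp(-0.5 * ((wl - 455) / 20) ** 2)
    amps = np.linspace(0.2, 1.0, 5)
    coupled = wrap(np.column_stack([a * (s530 + 0.35 * s455) for a in amps]), wl)
    assert choose_dimensionality(decompose(coupled), 0.85) == 1

    a = np.array([1.0, 0.8, 0.6, 0.4, 0.2])
    b = np.array([0.1, 0.45, 0.8, 1.15, 1.5])
    independent = wrap(np.column_stack([ai * s530 + bi * s455 for ai, bi in zip(a, b)]), wl)
    assert choose_dimensionality(decompose(independent), 0.85) == 2


def test_epr_score_proportional_to_column_scale():
    base = np.array([0.5, 1.0, -1.0, -0.5])
    factors = np.array([1.0, 0.5, 0.25])
    res = decompose(wrap(np.column_stack([f * base for f in factors]), axis=AxisKind.field_offset))
    omega = omega_scores(res, ScoreMode.epr).omega
    np.testing.assert_allclose(omega / omega[0], factors, atol=1e-12)
    assert omega[0] > 0  # oriented as a positive amount


def test_optical_score_matches_closed_form_2x2():
    M = np.array([[3.0, 1.0], [1.0, 3.0]])
    mat = wrap(M, wavelengths=np.array([455.0, 530.0]))
    res = decompose(mat)
    s_ref, _ = svd_2x2_closed_form(M)
    np.testing.assert_allclose(res.singular_values, s_ref, rtol=1e-12)
    # orientation: psi1 non-positive at its peak, psi2 non-negative at 530 nm
    u = 1 / math.sqrt(2)
    np.testing.assert_allclose(res.basis[:, 0], [-u, -u], atol=1e-12)
    np.testing.assert_allclose(res.basis[:, 1], [-u, u], atol=1e-12)
    np.testing.assert_allclose(res.coefficients[:, 0], [-u, -u], atol=1e-12)
    np.testing.assert_allclose(res.coefficients[:, 1], [-u, u], atol=1e-12)
    omega = omega_scores(res, ScoreMode.optical).omega
    # by hand: omega_j = (-psi1 + psi2)^T x_j = sqrt(2) * [x_530 - 0 * ...]
    expected = (-res.basis[:, 0] + res.basis[:, 1]) @ M
    np.testing.assert_allclose(omega, expected, atol=1e-12)
    np.testing.assert_allclose(omega, [math.sqrt(2) * 1.0, math.sqrt(2) * 3.0], atol=1e-12)


def test_flipping_input_sign_flips_all_scores():
    rng = np.random.default_rng(7)
    M = np.abs(rng.normal(size=(6, 3))) + 0.1
    for mode in (ScoreMode.optical, ScoreMode.epr):
        w_pos = omega_scores(decompose(wrap(M)), mode).omega
        w_neg = omega_scores(decompose(wrap(-M)), mode).omega
        np.testing.assert_allclose(w_neg, -w_pos, atol=1e-10)


def test_score_mode_dimensionality_requirements():
    col = np.array([1.0, 2.0, 0.5])
    res = decompose(wrap(col[:, None]))
    assert omega_scores(res, ScoreMode.epr).omega.shape == (1,)
    with pytest.raises(ValueError, match="d >= 2"):
        omega_scores(res, ScoreMode.optical)


def test_truncated_residual_is_monotone_and_eckart_young():
    rng = np.random.default_rng(11)
    for m, n in [(5, 5), (6, 4), (4, 3)]:
        M = rng.normal(size=(m, n))
        res = decompose(wrap(M))
        prev = np.inf
        for d in range(1, n + 1):
            resid = np.linalg.norm(reconstruct(res, d).intensities - M)
            dropped = math.sqrt(float(np.sum(res.singular_values[d:] ** 2)))
            assert resid == pytest.approx(dropped, abs=1e-9)
            assert resid <= prev + 1e-12
            prev = resid
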