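import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from dtishape import (
    DiffusionTensorModel,
    GradientScheme,
    build_design_matrix,
    default_protocol,
    eigendecompose,
    fit_tensor,
    fractional_anisotropy,
    shape_to_eigenvalues,
    shape_triangle_coords,
    triangle_to_shape,
    westin_metrics,
)
from dtishape.phantom import AcquisitionProtocol, simulate_signal
from dtishape.tensor import (
    IllPosedSchemeError,
    InconsistentShapeError,
    NonFiniteTensorError,
    tensor_from_eigensystem,
)
from conftest import random_spd_tensors

# eigenvalue triples (descending, non-negative) for property tests
evals_triples = st.tuples(
    st.floats(0.0, 3e-3), st.floats(0.0, 3e-3), st.floats(0.0, 3e-3)
).map(lambda t: tuple(sorted(t, reverse=True)))


# ---------------------------------------------------------------------------
# design matrix


def test_design_row_b0_is_intercept_only():
    sch = GradientScheme(np.r_[0.0, np.full(20, 1000.0)],
                         np.vstack([np.zeros(3), default_protocol().bvecs[1:]]))
    X = build_design_matrix(sch)
    assert np.allclose(X[0], [1, 0, 0, 0, 0, 0, 0])


def test_design_row_axis_aligned_direction():
    bvecs = np.vstack([np.zeros(3), [[1.0, 0, 0]], default_protocol().bvecs[1:]])
    bvals = np.r_[0.0, 1000.0, np.full(20, 1000.0)]
    X = build_design_matrix(GradientScheme(bvals, bvecs))
    assert np.allclose(X[1], [1, -1000, 0, 0, 0, 0, 0])


def test_design_row_diagonal_direction_cross_term():
    v = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    bvecs = np.vstack([np.zeros(3), v, default_protocol().bvecs[1:]])
    bvals = np.r_[0.0, 1000.0, np.full(20, 1000.0)]
    X = build_design_matrix(GradientScheme(bvals, bvecs))
    # dxy coefficient = −2·b·gx·gy = −1000
    assert np.isclose(X[1, 4], -1000.0)
    assert np.isclose(X[1, 1], -500.0) and np.isclose(X[1, 2], -500.0)


def test_rank_deficient_scheme_names_columns():
    # 20 copies of one direction + b0: cannot resolve off-axis terms
    bvecs = np.vstack([np.zeros(3), np.tile([1.0, 0, 0], (20, 1))])
    bvals = np.r_[0.0, np.full(20, 1000.0)]
    with pytest.raises(IllPosedSchemeError, match="dyy"):
        build_design_matrix(GradientScheme(bvals, bvecs))


# ---------------------------------------------------------------------------
# tensor fitting


def test_noiseless_fit_recovers_tensor(scheme):
    evals = np.array([1.7e-3, 0.3e-3, 0.3e-3])
    D = np.diag(evals)
    sig = 1000.0 * np.exp(-scheme.bvals * np.einsum(
        "ni,ij,nj->n", scheme.bvecs, D, scheme.bvecs))
    res = fit_tensor(sig, scheme)
    assert np.allclose(res.tensor, D, rtol=1e-10, atol=1e-16)
    assert np.isclose(res.s0, 1000.0, rtol=1e-10)


def test_identical_dwi_signals_give_isotropic_tensor(scheme):
    d = 0.7e-3
    sig = np.where(scheme.b0_mask, 1000.0, 1000.0 * np.exp(-1000.0 * d))
    res = fit_tensor(sig, scheme)
    assert np.allclose(res.tensor, np.eye(3) * d, atol=1e-12)


def test_b0_only_scheme_is_underdetermined():
    sch = GradientScheme(np.zeros(21), np.zeros((21, 3)))
    sig = np.full(21, 1000.0)
    with pytest.raises(IllPosedSchemeError):
        fit_tensor(sig, sch)


def test_oracle_equivalence_with_pseudoinverse(scheme, rng):
    """OLS fit agrees with a brute-force normal-equations solve, 1e-10."""
    D = random_spd_tensors(rng, 100)
    q = np.einsum("ni,mij,nj->mn", scheme.bvecs, D, scheme.bvecs)
    sig = 850.0 * np.exp(-scheme.bvals * q)
    res = fit_tensor(sig, scheme)
    X = build_design_matrix(scheme)
    beta_oracle = np.linalg.solve(X.T @ X, X.T @ np.log(sig).T).T
    assert np.allclose(res.params, beta_oracle, rtol=1e-10, atol=1e-14)
    # and the recovered tensors equal the ground truth
    assert np.allclose(res.tensor, D, rtol=1e-8, atol=1e-14)


def test_nonpositive_signals_clamped_and_counted(scheme, rng):
    D = random_spd_tensors(rng, 1)[0]
    sig = 1000.0 * np.exp(-scheme.bvals * np.einsum(
        "ni,ij,nj->n", scheme.bvecs, D, scheme.bvecs))
    sig[3] = -5.0
    res = fit_tensor(sig, scheme)
    assert int(res.n_clamped_signals) == 1
    assert np.isfinite(res.tensor).all()


def test_all_nonpositive_voxel_yields_masked_sentinel(scheme):
    sig = np.zeros(21)
    res = fit_tensor(sig, scheme)
    assert not res.usable
    assert np.isnan(res.params).all()


def test_wls_matches_ols_on_noiseless_signals(scheme, rng):
    D = random_spd_tensors(rng, 5)
    q = np.einsum("ni,mij,nj->mn", scheme.bvecs, D, scheme.bvecs)
    sig = 1000.0 * np.exp(-scheme.bvals * q)
    ols = DiffusionTensorModel(sig, scheme).fit(method="ols")
    wls = DiffusionTensorModel(sig, scheme).fit(method="wls")
    assert np.allclose(ols.tensor, wls.tensor, rtol=1e-8, atol=1e-14)


# ---------------------------------------------------------------------------
# eigendecomposition


def test_diagonal_tensor_eigenvalues_sorted():
    eig = eigendecompose(np.diag([3.0, 2.0, 1.0]))
    assert np.allclose(eig.evals, [3.0, 2.0, 1.0])


def test_isotropic_tensor_any_orthonormal_frame():
    eig = eigendecompose(np.eye(3) * 0.7)
    assert np.allclose(eig.evals, 0.7)
    assert np.allclose(eig.evecs @ eig.evecs.T, np.eye(3), atol=1e-12)


def test_rotation_invariance_of_eigenvalues():
    D0 = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
    R = Rotation.from_euler("z", 45, degrees=True).as_matrix()
    eig = eigendecompose(R @ D0 @ R.T)
    assert np.allclose(eig.evals, np.diag(D0), atol=1e-18)


def test_eigendecompose_reconstruction_and_orthonormality(rng):
    D = random_spd_tensors(rng, 50)
    eig = eigendecompose(D)
    # descending order
    assert np.all(np.diff(eig.evals, axis=-1) <= 1e-20)
    # orthonormal within 1e-8
    gram = np.einsum("nij,nik->njk", eig.evecs, eig.evecs)
    assert np.allclose(gram, np.eye(3), atol=1e-8)
    # reconstruction within 1e-10 relative
    back = tensor_from_eigensystem(eig.evals_raw, eig.evecs)
    assert np.allclose(back, D, rtol=1e-10, atol=1e-18)


def test_negative_eigenvalues_clamped_with_flag():
    D = np.diag([1.0e-3, 0.5e-3, -1e-5])
    eig = eigendecompose(D)
    assert eig.clamped
    assert eig.evals[-1] == 0.0
    assert eig.evals_raw[-1] < 0


def test_nonfinite_tensor_identifies_voxel():
    D = np.zeros((4, 3, 3))
    D[2, 0, 0] = np.inf
    with pytest.raises(NonFiniteTensorError, match="2"):
        eigendecompose(D)


def test_eigenvector_sign_convention_deterministic(rng):
    D = random_spd_tensors(rng, 20)
    e1 = eigendecompose(D).evecs
    e2 = eigendecompose(D.copy()).evecs
    assert np.array_equal(e1, e2)
    # largest-magnitude component of each eigenvector is positive
    mags = np.take_along_axis(
        e1, np.argmax(np.abs(e1), axis=-2, keepdims=True), axis=-2)
    assert np.all(mags > 0)


# ---------------------------------------------------------------------------
# shape metrics


@pytest.mark.parametrize(
    "evals, expected",
    [
        ((1.0, 1.0, 1.0), 0.0),           # isotropic
        ((1.0, 0.0, 0.0), 1.0),           # stick limit
        ((0.63167, 0.22167, 0.14667), 0.660),  # inverse-map image triple
    ],
)
def test_fa_reference_values(evals, expected):
    assert fractional_anisotropy(np.array(evals)) == pytest.approx(
        expected, abs=5e-4)


def test_fa_of_all_zero_triple_is_zero():
    assert fractional_anisotropy(np.zeros(3)) == 0.0


@pytest.mark.parametrize(
    "evals, triple",
    [
        ((1.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
        ((1.0, 1.0, 1.0), (0.0, 0.0, 1.0)),
        ((0.5, 0.3, 0.2), (0.2, 0.2, 0.6)),
    ],
)
def test_westin_reference_values(evals, triple):
    m = westin_metrics(np.array(evals))
    assert (float(m.cl), float(m.cp), float(m.cs)) == pytest.approx(triple,
                                                                    abs=1e-12)


def test_westin_nonpositive_trace_yields_sentinel():
    m = westin_metrics(np.zeros(3))
    assert np.isnan([m.cl, m.cp, m.cs, m.fa]).all()


@pytest.mark.parametrize(
    "triple, trace, expected",
    [
        ((0.0, 0.0, 1.0), 3.0, (1.0, 1.0, 1.0)),
        ((1.0, 0.0, 0.0), 1.0, (1.0, 0.0, 0.0)),
        ((0.41, 0.15, 0.44), 1.0, (0.63167, 0.22167, 0.14667)),
    ],
)
def test_shape_to_eigenvalues_reference_values(triple, trace, expected):
    lam = shape_to_eigenvalues(*triple, trace)
    assert lam == pytest.approx(expected, abs=5e-6)
    assert lam.sum() == pytest.approx(trace, abs=1e-12)


def test_shape_to_eigenvalues_rejects_inconsistent_triples():
    with pytest.raises(InconsistentShapeError):
        shape_to_eigenvalues(0.5, 0.5, 0.5, 1.0)
    with pytest.raises(InconsistentShapeError):
        shape_to_eigenvalues(-0.1, 0.4, 0.7, 1.0)


def test_triangle_corners_and_centroid():
    assert shape_triangle_coords(1.0, 0.0, 0.0) == (0.0, 0.0)
    assert shape_triangle_coords(0.0, 1.0, 0.0) == (1.0, 0.0)
    x, y = shape_triangle_coords(0.0, 0.0, 1.0)
    assert (x, y) == pytest.approx((0.5, np.sqrt(3) / 2))
    x, y = shape_triangle_coords(1 / 3, 1 / 3, 1 / 3)
    assert (x, y) == pytest.approx((0.5, np.sqrt(3) / 6))


# ---------------------------------------------------------------------------
# invariants (property-based)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(evals_triples)
def test_shape_metrics_sum_to_one(triple):
    lam = np.array(triple)
    m = westin_metrics(lam)
    if lam.sum() > 0:
        assert float(m.cl + m.cp + m.cs) == pytest.approx(1.0, abs=1e-12)
        assert -1e-12 <= min(m.cl, m.cp, m.cs)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(evals_triples, st.floats(1e-4, 1.0))
def test_westin_round_trip_identity(triple, trace):
    lam = np.array(triple)
    if lam.sum() <= 1e-6 * 3e-3:
        return
    m = westin_metrics(lam)
    back = shape_to_eigenvalues(float(m.cl), float(m.cp), float(m.cs),
                                float(lam.sum()))
    assert np.allclose(back, lam, rtol=1e-9, atol=1e-15)
    # forward direction with an arbitrary trace
    lam2 = shape_to_eigenvalues(float(m.cl), float(m.cp), float(m.cs), trace)
    m2 = westin_metrics(lam2)
    assert np.allclose([m2.cl, m2.cp, m2.cs], [m.cl, m.cp, m.cs], atol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_rotation_invariance_of_shape_metrics(seed):
    rng = np.random.default_rng(seed)
    lam = np.sort(rng.uniform(1e-4, 3e-3, 3))[::-1]
    R = Rotation.random(random_state=int(seed % (2**31))).as_matrix()
    D = R @ np.diag(lam) @ R.T
    m0 = westin_metrics(lam)
    m1 = westin_metrics(eigendecompose(D))
    assert np.allclose([m1.fa, m1.cl, m1.cp, m1.cs],
                       [m0.fa, m0.cl, m0.cp, m0.cs], atol=1e-10)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(evals_triples, st.floats(1e-3, 1e3))
def test_scale_invariance_of_shape_metrics(triple, c):
    lam = np.array(triple)
    if lam.sum() == 0:
        return
    m0 = westin_metrics(lam)
    m1 = westin_metrics(lam * c)
    assert np.allclose([m1.fa, m1.cl, m1.cp, m1.cs],
                       [m0.fa, m0.cl, m0.cp, m0.cs], atol=1e-10)


def test_fa_limits_and_monotonicity_in_lambda1():
    assert fractional_anisotropy(np.array([2e-3, 0, 0])) == 1.0
    assert fractional_anisotropy(np.array([2e-3] * 3)) == 0.0
    l23 = 0.4e-3
    l1s = np.linspace(l23, 5e-3, 50)
    fas = [float(fractional_anisotropy(np.array([l1, l23, l23])))
           for l1 in l1s]
    assert np.all(np.diff(fas) > 0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1))
def test_triangle_map_invertible_on_simplex(a, b):
    # map the unit square onto the simplex
    cl, cp = a * (1 - b), b * (1 - a)
    cs = 1.0 - cl - cp
    if cs < 0:
        return
    x, y = shape_triangle_coords(cl, cp, cs)
    cl2, cp2, cs2 = triangle_to_shape(x, y)
    assert np.allclose([cl2, cp2, cs2], [cl, cp, cs], atol=1e-12)
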