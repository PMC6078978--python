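"""Core enhancement pipeline: KNN transition, doubly stochastic operator, diffusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import entrywise_diffusion_oracle, knn_transition_oracle, localized_dsm_oracle
from netenhance import (
    DiffusionConfig,
    ValidationError,
    WeightedNetwork,
    build_knn_transition,
    build_localized_dsm,
    default_knn,
    diffuse_closed_form,
    diffuse_iterative,
    enhance,
    map_eigenvalue,
    rescale_to_input_degrees,
)
from netenhance.enhance import LocalizedDSM
from netenhance.synthetic import BlockNetworkSpec, generate_block_network


def dsm_deviation(M):
    return max(np.abs(M.sum(0) - 1).max(), np.abs(M.sum(1) - 1).max())


# ---------------------------------------------------------------------------
# KNN transition matrix


@pytest.mark.parametrize(
    "W, k, expected",
    [
        ([[1, 1], [1, 1]], 2, [[0.5, 0.5], [0.5, 0.5]]),
        ([[0, 1], [1, 0]], 2, [[0, 1], [1, 0]]),  # zero self-weight contributes nothing
        ([[0, 0], [0, 0]], 2, [[1, 0], [0, 1]]),  # degenerate rows become self-absorbing
    ],
)
def test_knn_transition_hand_examples(W, k, expected):
    P = build_knn_transition(WeightedNetwork(np.array(W, float)), k)
    np.testing.assert_allclose(P.probs, expected, atol=1e-15)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_knn_transition_matches_bruteforce_topk(random_network_factory, seed):
    """Rows are stochastic, have at most k nonzeros, and equal a literal top-k oracle."""
    net = random_network_factory(8, seed)
    P = build_knn_transition(net, 4)
    np.testing.assert_allclose(P.probs.sum(axis=1), 1.0, atol=1e-10)
    assert (np.count_nonzero(P.probs, axis=1) <= 4).all()
    np.testing.assert_allclose(P.probs, knn_transition_oracle(net.weights, 4), atol=1e-12)


def test_knn_ties_broken_by_ascending_index():
    W = np.array(
        [[0, 1, 1, 1],
         [1, 0, 0, 0],
         [1, 0, 0, 0],
         [1, 0, 0, 0]], float)
    P = build_knn_transition(WeightedNetwork(W), 2)
    # node 0 has three equal neighbors; index 1 wins the single non-self slot
    assert P.probs[0, 1] == 1.0 and P.probs[0, 2] == 0.0 and P.probs[0, 3] == 0.0


def test_knn_k_out_of_range():
    net = WeightedNetwork(np.ones((3, 3)))
    with pytest.raises(ValidationError):
        build_knn_transition(net, 0)
    with pytest.raises(ValidationError):
        build_knn_transition(net, 4)


def test_negative_weights_rejected_naming_entries():
    with pytest.raises(ValidationError, match=r"\[0, 1\]"):
        WeightedNetwork(np.array([[0, -1], [-1, 0]], float))


# ---------------------------------------------------------------------------
# localized doubly stochastic operator


@pytest.mark.parametrize(
    "P, expected",
    [
        ([[0.5, 0.5], [0.5, 0.5]], [[0.5, 0.5], [0.5, 0.5]]),
        ([[0, 1], [1, 0]], [[1, 0], [0, 1]]),
        ([[1, 0], [0, 1]], [[1, 0], [0, 1]]),
    ],
)
def test_localized_dsm_hand_examples(P, expected):
    from netenhance.enhance import TransitionMatrix

    T = build_localized_dsm(TransitionMatrix(np.array(P, float), k=2))
    np.testing.assert_allclose(T.operator, expected, atol=1e-15)


@pytest.mark.parametrize("seed", [0, 5])
def test_localized_dsm_matches_direct_summation(random_network_factory, seed):
    net = random_network_factory(10, seed)
    P = build_knn_transition(net, 5)
    T = build_localized_dsm(P)
    np.testing.assert_allclose(T.operator, localized_dsm_oracle(P.probs), atol=1e-12)
    assert dsm_deviation(T.operator) < 1e-10


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(2, 40), st.integers(0, 10**6))
def test_operator_is_symmetric_dsm_with_unit_spectrum(n, seed):
    """For any input, the operator is a symmetric PSD doubly stochastic matrix."""
    rng = np.random.default_rng(seed)
    W = rng.random((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    k = rng.integers(1, n + 1)
    T = build_localized_dsm(build_knn_transition(WeightedNetwork(W), int(k))).operator
    assert np.abs(T - T.T).max() < 1e-10
    assert T.min() >= 0
    assert dsm_deviation(T) < 1e-8
    lam = np.linalg.eigvalsh(T)
    assert lam.min() > -1e-9 and lam.max() < 1 + 1e-9
    # eigenvalue 1 carried by the all-ones direction
    ones = np.ones(n) / np.sqrt(n)
    np.testing.assert_allclose(T @ ones, ones, atol=1e-10)


# ---------------------------------------------------------------------------
# diffusion


def test_flat_operator_is_a_fixed_point():
    """The 2-node flat operator is idempotent, hence its own diffusion limit."""
    T = LocalizedDSM(np.full((2, 2), 0.5))
    res_it = diffuse_iterative(T, DiffusionConfig(alpha=0.9, mode="iterative", tol=1e-12))
    res_cf = diffuse_closed_form(T, 0.9)
    np.testing.assert_allclose(res_it.denoised, T.operator, atol=1e-12)
    np.testing.assert_allclose(res_cf.denoised, T.operator, atol=1e-12)


def test_identity_operator_is_preserved():
    T = LocalizedDSM(np.eye(4))
    for res in (diffuse_iterative(T), diffuse_closed_form(T, 0.5)):
        np.testing.assert_allclose(res.denoised, np.eye(4), atol=1e-12)


def test_iterative_limit_independent_of_w0(random_network_factory):
    net = random_network_factory(30, 7)
    T = build_localized_dsm(build_knn_transition(net, 6))
    cfg = DiffusionConfig(alpha=0.8, mode="iterative", tol=1e-12, max_iter=2000)
    from_T = diffuse_iterative(T, cfg).denoised
    from_W = diffuse_iterative(T, cfg, W0=net.weights).denoised
    assert np.linalg.norm(from_T - from_W) < 1e-6


def test_matrix_update_matches_entrywise_double_sum(random_network_factory):
    """Each sweep of the matrix update equals the literal entrywise double sum."""
    net = random_network_factory(5, 3)
    T = build_localized_dsm(build_knn_transition(net, 3)).operator
    alpha = 0.85
    W = T.copy()
    for _ in range(4):
        W_matrix = alpha * (T @ W @ T) + (1 - alpha) * T
        W_oracle = entrywise_diffusion_oracle(T, W, alpha)
        np.testing.assert_allclose(W_matrix, W_oracle, atol=1e-12)
        W = W_matrix


def test_closed_form_agrees_with_iterative(random_network_factory):
    net = random_network_factory(50, 11)
    T = build_localized_dsm(build_knn_transition(net, 8))
    cf = diffuse_closed_form(T, 0.9).denoised
    it = diffuse_iterative(
        T, DiffusionConfig(alpha=0.9, mode="iterative", tol=1e-10, max_iter=5000)
    ).denoised
    assert np.linalg.norm(cf - it) / np.linalg.norm(it) < 1e-6


def test_every_iterate_stays_doubly_stochastic(random_network_factory):
    net = random_network_factory(20, 2)
    T = build_localized_dsm(build_knn_transition(net, 5)).operator
    W = T.copy()
    for _ in range(30):
        W = 0.9 * (T @ W @ T) + 0.1 * T
        assert dsm_deviation(W) < 1e-8
        assert np.abs(W - W.T).max() < 1e-8


def test_nonconvergence_flagged_not_fatal():
    W = np.random.default_rng(0).random((15, 15))
    T = build_localized_dsm(build_knn_transition(WeightedNetwork((W + W.T) / 2), 5))
    with pytest.warns(UserWarning, match="did not reach"):
        res = diffuse_iterative(T, DiffusionConfig(alpha=0.9, mode="iterative", tol=1e-15, max_iter=3))
    assert not res.converged
    assert res.iterations == 3


# ---------------------------------------------------------------------------
# eigenvalue map


def test_map_eigenvalue_values_and_domain():
    assert map_eigenvalue(0.0, 0.5) == 0.0
    assert map_eigenvalue(1.0, 0.37) == pytest.approx(1.0)
    assert map_eigenvalue(0.5, 0.9) == pytest.approx(0.05 / 0.775)
    with pytest.raises(ValidationError):
        map_eigenvalue(1.1, 0.9)
    with pytest.raises(ValidationError):
        map_eigenvalue(0.5, 1.0)


def test_map_eigenvalue_shrinkage_and_order():
    """f(lam) <= lam, strictly increasing, and smaller eigenvalues shrink faster."""
    lam = np.linspace(0.0, 1.0, 1000)
    f = map_eigenvalue(lam, 0.9)
    assert (f <= lam + 1e-15).all()
    assert (np.diff(f) > 0).all()
    # ratio test: f(lam')/f(lam) <= lam'/lam for 0 < lam' < lam
    lo, hi = lam[1:-1], lam[2:]
    assert (map_eigenvalue(lo, 0.9) / map_eigenvalue(hi, 0.9) <= lo / hi + 1e-12).all()
    # top eigengap never shrinks: f(1) - f(lam2) >= 1 - lam2
    assert (1.0 - f >= 1.0 - lam - 1e-12).all()


# ---------------------------------------------------------------------------
# rescaling


def test_rescale_unit_degrees_is_noop(random_network_factory):
    """A doubly stochastic input has unit degrees, so rescaling changes nothing."""
    net = random_network_factory(6, 4)
    T = build_localized_dsm(build_knn_transition(net, 3))
    res = diffuse_closed_form(T, 0.9)
    ds_input = WeightedNetwork(T.operator)  # degrees all exactly 1
    out = rescale_to_input_degrees(res, ds_input)
    np.testing.assert_allclose(out.weights, res.denoised, atol=1e-10)


def test_rescale_hand_example_and_row_variant():
    res = diffuse_closed_form(LocalizedDSM(np.eye(2)), 0.9)  # W* = I
    net = WeightedNetwork(np.array([[3.0, 1.0], [1.0, 8.0]]))  # degrees (4, 9)
    out = rescale_to_input_degrees(res, net)
    np.testing.assert_allclose(out.weights, np.diag([4.0, 9.0]))
    out_row = rescale_to_input_degrees(res, net, method="row")
    np.testing.assert_allclose(out_row.weights, out_row.weights.T)
    np.testing.assert_allclose(np.diag(out_row.weights), [4.0, 9.0])


def test_rescale_dimension_mismatch():
    res = diffuse_closed_form(LocalizedDSM(np.eye(3)), 0.9)
    with pytest.raises(ValidationError):
        rescale_to_input_degrees(res, WeightedNetwork(np.eye(2)))


# ---------------------------------------------------------------------------
# full pipeline


def test_two_block_flat_network_stays_disconnected():
    """Disconnected flat blocks diffuse to block-constant output with zero bridges."""
    W = np.zeros((6, 6))
    W[:3, :3] = 1.0
    W[3:, 3:] = 1.0
    np.fill_diagonal(W, 0.0)
    out = enhance(WeightedNetwork(W), DiffusionConfig(k=3, alpha=0.9))
    assert np.all(out.weights[:3, 3:] == 0.0)
    block = out.weights[:3, :3]
    off = block[~np.eye(3, dtype=bool)]
    np.testing.assert_allclose(off, off[0], atol=1e-10)


def test_single_node_enhances_to_zero_matrix():
    out = enhance(WeightedNetwork(np.zeros((1, 1)), ["solo"]))
    assert out.weights.shape == (1, 1)
    assert out.weights[0, 0] == 0.0
    assert out.node_ids == ["solo"]


def test_enhancement_widens_top_block_eigengap():
    """With clean community structure the gap below the community eigenvalues grows."""
    from netenhance.spectral import eigengap

    spec = BlockNetworkSpec(noise_sd=0.1, dropout=0.0, seed=42)
    net, _ = generate_block_network(spec)
    _, T, res = enhance(net, return_details=True)
    assert eigengap(res.denoised, 4) >= eigengap(T.operator, 4)


def test_enhance_scale_invariance(random_network_factory):
    """Pre-rescale output is invariant to positive rescaling of the input."""
    net = random_network_factory(25, 9)
    cfg = DiffusionConfig(k=5)
    base = enhance(net, cfg).weights
    for c in (1e-3, 7.0, 1e4):
        scaled = enhance(WeightedNetwork(c * net.weights), cfg).weights
        np.testing.assert_allclose(scaled, base, atol=1e-10)


def test_component_count_and_zero_blocks_preserved(random_network_factory):
    a = random_network_factory(8, 0).weights + 0.05
    b = random_network_factory(5, 1).weights + 0.05
    np.fill_diagonal(a, 0.0)
    np.fill_diagonal(b, 0.0)
    W = np.zeros((13, 13))
    W[:8, :8] = a
    W[8:, 8:] = b
    net = WeightedNetwork(W)
    _, T, res = enhance(net, DiffusionConfig(k=4), return_details=True)
    lam_T = np.linalg.eigvalsh(T.operator)
    lam_W = np.linalg.eigvalsh(res.denoised)
    assert np.sum(lam_T > 1 - 1e-8) == np.sum(lam_W > 1 - 1e-8) == 2
    assert np.all(res.denoised[:8, 8:] == 0.0)


def test_default_knn_rule():
    assert default_knn(5) == 2
    assert default_knn(100) == 10
    assert default_knn(1000) == 20
    assert default_knn(1) == 1


def test_config_validation():
    with pytest.raises(ValidationError):
        DiffusionConfig(alpha=1.0)
    with pytest.raises(ValidationError):
        DiffusionConfig(mode="magic")
    with pytest.raises(ValidationError):
        DiffusionConfig(max_iter=0)
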