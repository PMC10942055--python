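"""Capsule primitives: squash, votes, routing-by-agreement, margin loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from textoncaps.capsules import (ClassCapsule, MarginLossParams,
                                 PrimaryCapsule, capsule_lengths,
                                 class_capsule_forward, compute_votes,
                                 conv_output_size, dynamic_routing,
                                 margin_loss, margin_loss_t, squash, squash_t)
from textoncaps.tensor import Tensor


def reference_routing(votes, r):
    """Literal step-by-step transcription of routing-by-agreement (in-loop
    agreement update), kept independent of the vectorized implementation."""
    N, J, D = votes.shape
    b = np.zeros((N, J))
    for _ in range(r):
        c = np.empty_like(b)
        for i in range(N):
            e = np.exp(b[i] - b[i].max())
            c[i] = e / e.sum()
        s = np.zeros((J, D))
        for j in range(J):
            for i in range(N):
                s[j] += c[i, j] * votes[i, j]
        v = np.stack([squash(s[j]) for j in range(J)])
        for i in range(N):
            for j in range(J):
                b[i, j] += float(v[j] @ votes[i, j])
    return v, b


# -- squash -----------------------------------------------------------------

def test_squash_zero_vector_maps_to_zero():
    assert np.allclose(squash(np.zeros(5)), 0.0)


def test_squash_closed_form_3_4():
    v = squash(np.array([3.0, 4.0]))
    assert np.linalg.norm(v) == pytest.approx(25 / 26, abs=1e-9)
    assert v == pytest.approx([0.57692, 0.76923], abs=1e-4)


def test_squash_unit_vector_halves():
    v = squash(np.array([1.0, 0.0, 0.0]))
    assert np.linalg.norm(v) == pytest.approx(0.5, abs=1e-6)


def test_squash_rejects_nonfinite():
    with pytest.raises(ValueError):
        squash(np.array([1.0, np.inf]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(arrays(np.float64, (4,), elements=st.floats(-50, 50)))
def test_squash_bounds_and_direction(s):
    v = squash(s)
    n = np.linalg.norm(v)
    assert 0 <= n < 1
    if np.linalg.norm(s) > 1e-6:
        cos = (v @ s) / (np.linalg.norm(v) * np.linalg.norm(s))
        assert cos == pytest.approx(1.0, abs=1e-6)


def test_squash_length_strictly_increasing_in_input_norm():
    norms = np.linspace(0.1, 10, 25)
    lengths = [np.linalg.norm(squash(np.array([n, 0.0]))) for n in norms]
    assert np.all(np.diff(lengths) > 0)


def test_squash_tensor_matches_numpy():
    rng = np.random.default_rng(0)
    s = rng.normal(0, 2, (3, 5, 4))
    assert np.allclose(squash_t(Tensor(s)).data, squash(s), atol=1e-5)


# -- votes --------------------------------------------------------------------

def test_identity_weights_replicate_input():
    u = np.arange(6, dtype=float).reshape(2, 3)
    W = np.broadcast_to(np.eye(3), (2, 4, 3, 3))
    votes = compute_votes(u, W)
    for j in range(4):
        assert np.allclose(votes[:, j], u)


def test_zero_weights_zero_votes():
    votes = compute_votes(np.ones((3, 2)), np.zeros((3, 5, 2, 4)))
    assert not votes.any()


def test_votes_match_explicit_loop(rng):
    u = rng.normal(0, 1, (2, 3))
    W = rng.normal(0, 1, (2, 4, 3, 5))
    votes = compute_votes(u, W)
    for i in range(2):
        for j in range(4):
            assert np.allclose(votes[i, j], u[i] @ W[i, j])


def test_votes_dimension_mismatch_is_reported():
    with pytest.raises(ValueError, match="D_in"):
        compute_votes(np.ones((2, 3)), np.ones((2, 4, 5, 6)))


# -- routing ------------------------------------------------------------------

def test_single_iteration_uses_uniform_couplings(rng):
    votes = rng.normal(0, 1, (5, 3, 4))
    v, state = dynamic_routing(votes, r=1)
    assert np.allclose(state.coupling_history[0], 1 / 3)
    expected = squash(votes.mean(axis=0) * 5 / 5)  # c=1/J then sum_i c*votes
    assert np.allclose(v, squash((votes / 3).sum(axis=0)))


def test_single_lower_capsule_routes_to_coupling_scaled_squashed_votes(rng):
    # with one lower capsule the coupling softmax still spreads over the J
    # upper capsules, so v_j = squash(c_1j * vote_j), parallel to the vote
    votes = rng.normal(0, 1, (1, 4, 6))
    for r in (1, 2, 5):
        v, state = dynamic_routing(votes, r=r)
        expected = squash(state.coupling_history[-1][0, :, None] * votes[0])
        assert np.allclose(v, expected, atol=1e-12)
        cos = (v * votes[0]).sum(-1) / (
            np.linalg.norm(v, axis=-1) * np.linalg.norm(votes[0], axis=-1))
        assert np.allclose(cos, 1.0, atol=1e-9)
    # with a single upper capsule the coupling is exactly 1: v = squash(vote)
    votes1 = rng.normal(0, 1, (1, 1, 6))
    v, _ = dynamic_routing(votes1, r=3)
    assert np.allclose(v, squash(votes1[0]), atol=1e-12)


def test_routing_matches_reference_transcription(rng):
    votes = rng.normal(0, 1, (2, 2, 2))
    v, state = dynamic_routing(votes, r=3)
    v_ref, b_ref = reference_routing(votes, r=3)
    assert np.allclose(v, v_ref, atol=1e-12)
    assert np.allclose(state.logits, b_ref, atol=1e-12)


def test_couplings_normalized_every_iteration(rng):
    votes = rng.normal(0, 3, (7, 4, 5))
    _, state = dynamic_routing(votes, r=4)
    assert len(state.coupling_history) == 4
    for c in state.coupling_history:
        assert np.allclose(c.sum(axis=-1), 1.0, atol=1e-6)


def test_identical_votes_give_parallel_output(rng):
    w = rng.normal(0, 1, 4)
    votes = np.broadcast_to(w, (6, 3, 4)).copy()
    v, _ = dynamic_routing(votes, r=3)
    for j in range(3):
        cos = (v[j] @ w) / (np.linalg.norm(v[j]) * np.linalg.norm(w))
        assert cos == pytest.approx(1.0, abs=1e-9)


def test_printed_after_loop_update_differs_from_inloop(rng):
    votes = rng.normal(0, 1, (4, 3, 2))
    v_in, s_in = dynamic_routing(votes, r=3, update="inloop")
    v_after, s_after = dynamic_routing(votes, r=3, update="after")
    # the printed variant never re-weights within the loop, so its output
    # equals the r=1 result
    v1, _ = dynamic_routing(votes, r=1)
    assert np.allclose(v_after, v1)
    assert not np.allclose(v_in, v_after)


def test_routing_requires_at_least_one_iteration(rng):
    with pytest.raises(ValueError):
        dynamic_routing(rng.normal(0, 1, (2, 2, 2)), r=0)


def test_batched_routing_matches_per_sample(rng):
    votes = rng.normal(0, 1, (3, 4, 2, 5))
    v_all, _ = dynamic_routing(votes, r=2)
    for b in range(3):
        v_b, _ = dynamic_routing(votes[b], r=2)
        assert np.allclose(v_all[b], v_b, atol=1e-12)


def test_tensor_routing_matches_numpy(rng):
    votes = rng.normal(0, 1, (2, 5, 3, 4)).astype(np.float32)
    from textoncaps.capsules import _routing_t
    v_np, _ = dynamic_routing(votes, r=3)
    v_t, _ = _routing_t(Tensor(votes), r=3)
    assert np.allclose(v_t.data, v_np, atol=1e-5)


# -- margin loss ---------------------------------------------------------------

def test_margin_loss_zero_at_perfect_configuration():
    lengths = np.array([[0.95, 0.05, 0.02]])
    targets = np.array([[1, 0, 0]])
    assert margin_loss(lengths, targets) == 0.0


def test_margin_loss_hand_computed_terms():
    params = MarginLossParams(m_plus=0.9, m_minus=0.1, lam=0.5)
    # true class at length 0 contributes (0.9)^2
    assert margin_loss(np.array([[0.0, 0.0]]), np.array([[1, 0]]),
                       params) == pytest.approx(0.81)
    # absent class at length 1 contributes 0.5*(0.9)^2
    assert margin_loss(np.array([[0.9, 1.0]]), np.array([[1, 0]]),
                       params) == pytest.approx(0.405)


def test_margin_loss_batch_mean(rng):
    params = MarginLossParams()
    l1 = margin_loss(np.array([[0.3, 0.4]]), np.array([[1, 0]]), params)
    l2 = margin_loss(np.array([[0.8, 0.9]]), np.array([[0, 1]]), params)
    both = margin_loss(np.array([[0.3, 0.4], [0.8, 0.9]]),
                       np.array([[1, 0], [0, 1]]), params)
    assert both == pytest.approx((l1 + l2) / 2)


def test_margin_loss_rejects_non_one_hot():
    with pytest.raises(ValueError, match="one-hot"):
        margin_loss(np.array([[0.5, 0.5]]), np.array([[1, 1]]))


def test_margin_loss_params_validated():
    with pytest.raises(ValueError):
        MarginLossParams(m_plus=0.1, m_minus=0.9)
    with pytest.raises(ValueError):
        MarginLossParams(lam=0.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(arrays(np.float64, (3,), elements=st.floats(0, 1)),
       st.integers(0, 2))
def test_margin_loss_non_negative(lengths, k):
    targets = np.eye(3)[[k]]
    assert margin_loss(lengths[None, :], targets) >= 0.0


def test_margin_loss_tensor_matches_numpy(rng):
    lengths = rng.random((4, 3))
    targets = np.eye(3)[rng.integers(0, 3, 4)]
    params = MarginLossParams()
    lt = margin_loss_t(Tensor(lengths.astype(np.float32)), targets, params)
    assert float(lt.data) == pytest.approx(margin_loss(lengths, targets, params),
                                           abs=1e-5)


# -- capsule layers -------------------------------------------------------------

@pytest.mark.parametrize("size,kernel,stride,expected", [
    (32, 5, 2, 14), (5, 3, 2, 2), (14, 5, 2, 5)])
def test_conv_output_size_chain(size, kernel, stride, expected):
    assert conv_output_size(size, kernel, stride) == expected


def test_primary_capsule_shapes_and_squash(rng):
    pc = PrimaryCapsule(3, n_types=12, dim=8, kernel=5, stride=2,
                        rng=np.random.default_rng(0))
    x = Tensor(rng.random((2, 32, 32, 3)).astype(np.float32))
    caps, fmap = pc(x)
    assert caps.data.shape == (2, 14 * 14 * 12, 8)
    assert fmap.data.shape == (2, 14, 14, 96)
    lengths = capsule_lengths(caps.data)
    assert lengths.max() < 1.0
    # fmap is the squashed capsule tensor re-laid-out
    assert np.allclose(fmap.data.reshape(2, -1, 8), caps.data)


def test_primary_capsule_kernel_too_large(rng):
    pc = PrimaryCapsule(1, n_types=2, dim=4, kernel=9, stride=1,
                        rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        pc(Tensor(rng.random((1, 4, 4, 1)).astype(np.float32)))


def test_class_capsule_head_dims(rng):
    u = Tensor(rng.normal(0, 0.1, (2, 10, 8)).astype(np.float32))
    for out_dim in (16, 12, 10):
        head = ClassCapsule(10, 8, 4, out_dim, np.random.default_rng(1))
        v, _ = head(u)
        assert v.data.shape == (2, 4, out_dim)


def test_class_capsule_functional_agrees_with_module(rng):
    u = rng.normal(0, 0.5, (4, 8))
    head = ClassCapsule(4, 8, 2, 6, np.random.default_rng(2), r=3)
    W = head.weight.data.astype(np.float64)
    v_fn, _ = class_capsule_forward(u, n_classes=2, out_dim=6, r=3, weights=W)
    v_mod, _ = head(Tensor(u[None].astype(np.float32)))
    assert np.allclose(v_mod.data[0], v_fn, atol=1e-5)


def test_single_lower_capsule_head_parallel_to_votes(rng):
    u = rng.normal(0, 1, (1, 8))
    W = rng.normal(0, 0.1, (1, 3, 8, 5))
    v, state = class_capsule_forward(u, n_classes=3, out_dim=5, r=4, weights=W)
    votes = compute_votes(u, W)[0]
    expected = squash(state.coupling_history[-1][0, :, None] * votes)
    assert np.allclose(v, expected, atol=1e-12)
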