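"""Gradient checks: every op's backward against central finite differences."""

import numpy as np
import pytest

import emrsql.autodiff as ad
from emrsql.autodiff import Tensor


def numeric_grad(f, x, eps=1e-5):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        up = f()
        x[i] = orig - eps
        down = f()
        x[i] = orig
        g[i] = (up - down) / (2 * eps)
        it.iternext()
    return g


def check(build, *xs):
    """build(tensors) -> scalar Tensor; xs are float64 leaf arrays."""
    leaves = [Tensor(x, requires_grad=True) for x in xs]
    out = build(*leaves)
    out.backward()
    for leaf, x in zip(leaves, xs):
        num = numeric_grad(lambda: build(
            *[Tensor(y) for y in xs]).item(), x)
        np.testing.assert_allclose(leaf.grad, num, rtol=1e-4, atol=1e-6)


RNG = np.random.default_rng(0)


def r(*shape):
    return RNG.normal(size=shape).astype(np.float64)


@pytest.mark.parametrize("op", [
    lambda a, b: ad.mean_(ad.mul(ad.add(a, b), ad.sub(a, b))),
    lambda a, b: ad.mean_(ad.sigmoid(ad.concat([a, b], axis=-1))),
    lambda a, b: ad.mean_(ad.relu(ad.add(a, b))),
    lambda a, b: ad.mean_(ad.narrow(ad.mul(a, b), 1, 1, 2)),
])
def test_elementwise_grads(op):
    check(op, r(3, 4), r(3, 4))


def test_matmul_batched_and_weight_grads():
    check(lambda a, b: ad.mean_(ad.matmul(a, b)), r(3, 4), r(4, 5))
    check(lambda a, b: ad.mean_(ad.tanh(ad.matmul(a, b))), r(3, 4), r(4, 5))
    check(lambda a, b: ad.mean_(ad.matmul(a, b)), r(2, 5, 3), r(3, 4))
    check(lambda a, b: ad.mean_(ad.matmul(a, ad.transpose_last(b))),
          r(2, 5, 3), r(2, 7, 3))


def test_gather_grads():
    idx = np.array([[0, 2], [1, 1]])
    check(lambda a: ad.mean_(ad.gather_rows(a, idx)), r(4, 3))
    bidx = np.array([2, 0])
    check(lambda a: ad.mean_(ad.gather_batch(a, bidx)), r(2, 3, 4))
    tidx = np.array([[0, 1], [2, 2]])
    check(lambda a: ad.mean_(ad.gather_batch(a, tidx)), r(2, 3, 4))
    lidx = np.array([[0, 3], [1, 2]])
    check(lambda a: ad.mean_(ad.take_last(a, lidx)), r(2, 2, 4))


def test_masked_softmax_grads():
    mask = np.array([[True, True, False, True], [True, False, True, True]])
    check(lambda a: ad.mean_(ad.masked_softmax(ad.mul(a, a), mask)), r(2, 4))
    check(lambda a: ad.mean_(ad.take_last(
        ad.masked_log_softmax(a, mask), np.array([0, 2]))), r(2, 4))
    # fast path (all true)
    check(lambda a: ad.mean_(ad.masked_softmax(a, np.ones((2, 4), bool))),
          r(2, 4))
    check(lambda a: ad.mean_(
        ad.masked_log_softmax(a, np.ones((2, 4), bool))), r(2, 4))


def test_layer_norm_grads():
    check(lambda a, g, b: ad.mean_(ad.mul(ad.layer_norm(a, g, b),
                                          ad.layer_norm(a, g, b))),
          r(2, 3, 5), r(5), r(5))


def test_masked_probabilities_sum_to_one():
    mask = np.array([[True, False, True, True]])
    s = ad.masked_softmax(Tensor(r(1, 4)), mask)
    assert abs(s.data.sum() - 1.0) < 1e-6
    assert s.data[0, 1] == 0.0


def test_clip_and_adam_step():
    p = {"w": Tensor(np.ones(4, np.float32), requires_grad=True)}
    p["w"].grad = np.full(4, 10.0, np.float32)
    norm = ad.clip_grads_(p, 5.0)
    assert norm == pytest.approx(20.0)
    assert np.linalg.norm(p["w"].grad) == pytest.approx(5.0, rel=1e-5)
    opt = ad.Adam(p, lr=0.1)
    before = p["w"].data.copy()
    opt.step()
    assert np.all(p["w"].data < before)  # positive grads push weights down
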