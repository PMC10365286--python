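"""Gradient correctness of the layer library against central differences,
plus loss-function values."""

import numpy as np
import pytest

from pulmo3d import nn

from conftest import num_grad


def _check_layer(layer, x_shape, seed=0, tol=2e-2):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=x_shape).astype(np.float32)
    out = layer.forward(x.copy(), train=True)
    r = rng.normal(size=out.shape).astype(np.float32)

    def loss():
        return float((layer.forward(x.copy(), train=True) * r).sum())

    layer.zero_grad()
    layer.forward(x.copy(), train=True)
    dx = layer.backward(r.copy())
    assert np.abs(dx - num_grad(loss, x)).max() < tol
    for _, p in layer.named_parameters():
        assert np.abs(p.grad - num_grad(loss, p.data)).max() < tol


RNG = np.random.default_rng(7)

LAYER_CASES = [
    ("conv2d_pad", lambda: nn.Conv2d(2, 3, 3, padding=1, rng=RNG), (2, 2, 5, 5)),
    ("conv3d_stride", lambda: nn.Conv3d(2, 2, 3, stride=2, padding=1, rng=RNG),
     (1, 2, 6, 6, 6)),
    ("conv3d_pointwise", lambda: nn.Conv3d(3, 2, 1, rng=RNG), (2, 3, 3, 3, 3)),
    ("deconv3d_f2", lambda: nn.BlockDeconvNd(3, 2, 3, 2, rng=RNG), (1, 2, 3, 3, 3)),
    ("deconv2d_f4", lambda: nn.BlockDeconvNd(2, 2, 2, 4, rng=RNG), (1, 2, 2, 2)),
    ("maxpool2d", lambda: nn.MaxPoolNd(2, 2), (2, 2, 4, 4)),
    ("maxpool3d_f2", lambda: nn.MaxPoolNd(3, 2), (1, 2, 4, 4, 4)),
    ("batchnorm", lambda: nn.BatchNorm(3), (4, 3, 5)),
    ("linear", lambda: nn.Linear(4, 3, rng=RNG), (5, 4)),
    ("gap", lambda: nn.GlobalAvgPool(), (2, 3, 4, 4)),
]


@pytest.mark.parametrize("name,factory,shape", LAYER_CASES,
                         ids=[c[0] for c in LAYER_CASES])
def test_layer_gradients_match_central_differences(name, factory, shape):
    _check_layer(factory(), shape)


def test_residual_block_trains():
    """Finite differences are unreliable through BN + ReLU (activations sit
    on the kink), so the residual block is verified functionally: its
    gradients must drive a small regression loss down."""
    from pulmo3d.backbone import BasicBlock
    rng = np.random.default_rng(3)
    block = BasicBlock(2, np.random.default_rng(5))
    head = nn.Linear(2 * 64, 1, rng=np.random.default_rng(6))
    x = rng.normal(size=(4, 2, 4, 4, 4)).astype(np.float32)
    target = rng.normal(size=(4, 1)).astype(np.float32)
    opt = nn.SGD(block.parameters() + head.parameters(), lr=0.05,
                 momentum=0.9)
    losses = []
    for _ in range(40):
        feats = block.forward(x, train=True).reshape(4, -1)
        pred = head.forward(feats, train=True)
        diff = pred - target
        losses.append(float((diff ** 2).mean()))
        g = (2 * diff / diff.size).astype(np.float32)
        opt.zero_grad()
        block.backward(head.backward(g).reshape(4, 2, 4, 4, 4))
        opt.step()
    assert losses[-1] < 0.3 * losses[0]


class TestLosses:
    def test_softmax_ce_uniform(self):
        logits = np.zeros((3, 4), dtype=np.float32)
        loss, grad = nn.softmax_cross_entropy(logits, np.array([0, 1, 2]))
        assert loss == pytest.approx(np.log(4))
        assert grad.shape == (3, 4)

    def test_softmax_ce_gradient(self, rng):
        logits = rng.normal(size=(4, 3)).astype(np.float32)
        y = np.array([0, 2, 1, 1])
        _, grad = nn.softmax_cross_entropy(logits, y)
        g_num = num_grad(lambda: nn.softmax_cross_entropy(logits, y)[0], logits)
        np.testing.assert_allclose(grad, g_num, atol=1e-2)

    def test_bce_perfect_and_weighted(self):
        logits = np.array([50.0, -50.0])
        loss, _ = nn.bce_with_logits(logits, np.array([1.0, 0.0]))
        assert loss == pytest.approx(0.0, abs=1e-9)
        lw, _ = nn.bce_with_logits(np.zeros(2), np.array([1.0, 0.0]),
                                   weights=np.array([3.0, 1.0]))
        assert lw == pytest.approx(np.log(2))  # weights cancel symmetrically

    def test_smooth_l1_regimes(self):
        loss, grad = nn.smooth_l1(np.array([0.5]), np.array([0.0]))
        assert loss == pytest.approx(0.125)      # quadratic zone
        assert grad[0] == pytest.approx(0.5)
        loss, grad = nn.smooth_l1(np.array([3.0]), np.array([0.0]))
        assert loss == pytest.approx(2.5)        # linear zone
        assert grad[0] == pytest.approx(1.0)


class TestStateDict:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        model = nn.Sequential(nn.Conv2d(1, 2, 3, rng=rng), nn.BatchNorm(2),
                              nn.ReLU(), nn.Flatten(), nn.Linear(8, 2, rng=rng))
        model.forward(rng.normal(size=(3, 1, 4, 4)).astype(np.float32))
        state = model.state_dict()
        clone = nn.Sequential(nn.Conv2d(1, 2, 3), nn.BatchNorm(2),
                              nn.ReLU(), nn.Flatten(), nn.Linear(8, 2))
        clone.load_state_dict(state)
        for (na, pa), (_, pb) in zip(model.named_parameters(),
                                     clone.named_parameters()):
            np.testing.assert_array_equal(pa.data, pb.data), na

    def test_shape_mismatch_rejected(self):
        a = nn.Linear(3, 2)
        b = nn.Linear(4, 2)
        with pytest.raises(ValueError):
            b.load_state_dict(a.state_dict())
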