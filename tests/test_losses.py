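import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelviseg.losses import (
    LossValue,
    axis_projection,
    bbox_loss,
    bbox_loss_t,
    dice_cross_entropy_loss,
    dice_loss,
    get_loss,
    positional_dice_loss,
    positional_dice_loss_t,
    union_extent,
)
from pelviseg.nn import Tensor

from conftest import cube_pair_8, random_onehot, random_soft


def brute_force_bbox(p: np.ndarray, q: np.ndarray) -> float:
    """Independent oracle: materialise per-axis occupancy sets and count
    symmetric differences and unions."""
    n_ch = p.shape[-1]
    losses = []
    for c in range(1, n_ch):
        num = den = 0
        for axis in range(3):
            occ_p = {i for i in range(p.shape[axis])
                     if np.take(p[..., c], i, axis=axis).any()}
            occ_q = {i for i in range(q.shape[axis])
                     if np.take(q[..., c], i, axis=axis).any()}
            num += len(occ_p ^ occ_q)
            den += len(occ_p | occ_q)
        losses.append(0.0 if den == 0 else num / den)
    return float(np.mean(losses))


class TestDiceLoss:
    def test_identity_is_zero(self, rng):
        p = random_onehot(rng)
        assert dice_loss(p, p.astype(float)).total == pytest.approx(0.0)

    def test_disjoint_is_one(self):
        p = np.zeros((4, 4, 4, 2))
        q = np.zeros((4, 4, 4, 2))
        p[..., 0] = 1
        q[..., 0] = 1
        p[0, 0, 0] = [0, 1]
        q[3, 3, 3] = [0, 1]
        assert dice_loss(p, q, exclude_background=True).total == pytest.approx(1.0)

    def test_hand_worked_two_voxel_case(self):
        p = np.zeros((4, 4, 4, 2))
        q = np.zeros((4, 4, 4, 2))
        p[..., 0] = 1
        q[..., 0] = 1
        for vox in [(0, 0, 0), (1, 0, 0)]:
            p[vox] = [0, 1]
        q[0, 0, 0] = [0, 1]
        assert dice_loss(p, q, exclude_background=True).total == pytest.approx(1 / 3)

    def test_both_empty_is_zero(self):
        p = np.zeros((3, 3, 3, 2))
        p[..., 0] = 1
        assert dice_loss(p, p.copy(), exclude_background=True).total == 0.0

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(random_onehot(rng), random_onehot(rng, shape=(4, 4, 4)))

    def test_symmetry(self, rng):
        p = random_onehot(rng).astype(float)
        q = random_onehot(rng).astype(float)
        assert dice_loss(p, q).total == pytest.approx(dice_loss(q, p).total)


class TestAxisProjection:
    def test_cube_profile(self):
        m = np.zeros((8, 8, 8))
        m[:4, 2:6, 1:5] = 1
        prof = axis_projection(m, "x")
        np.testing.assert_array_equal(prof, [1, 1, 1, 1, 0, 0, 0, 0])

    def test_empty_mask(self):
        assert not axis_projection(np.zeros((4, 4, 4)), "z").any()

    def test_soft_equals_crisp_on_binary(self, rng):
        m = (rng.random((5, 6, 7)) < 0.3).astype(float)
        for ax in "xyz":
            np.testing.assert_array_equal(
                axis_projection(m, ax, soft=True), axis_projection(m, ax)
            )

    def test_union_extent_hand_count(self):
        p = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        q = np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=float)
        assert union_extent(p, q) == 4
        assert union_extent(np.zeros(8), np.zeros(8)) == 0
        assert union_extent(p, p) == 4


class TestBboxLoss:
    def test_identity_is_zero(self, rng):
        p = random_onehot(rng)
        assert bbox_loss(p, p.astype(float)).total == pytest.approx(0.0)

    def test_nested_cube_sixth(self, nested_cubes):
        p, q = nested_cubes
        assert bbox_loss(p, q).total == pytest.approx(1 / 6)

    def test_empty_prediction_is_one(self):
        p = np.zeros((8, 8, 8, 2))
        p[..., 0] = 1
        p[:4, :4, :4] = [0, 1]
        q = np.zeros_like(p)
        q[..., 0] = 1
        assert bbox_loss(p, q).total == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            p = random_onehot(rng)
            q = random_onehot(rng)
            assert abs(bbox_loss(p, q.astype(float)).total
                       - brute_force_bbox(p, q)) < 1e-12

    def test_symmetry_on_crisp(self, rng):
        p = random_onehot(rng).astype(float)
        q = random_onehot(rng).astype(float)
        assert bbox_loss(p, q).total == pytest.approx(bbox_loss(q, p).total)


class TestPositionalDiceLoss:
    def test_identity_zero(self, rng):
        p = random_onehot(rng)
        lv = positional_dice_loss(p, p.astype(float))
        assert lv.total == 0.0

    def test_nested_cube_half(self, nested_cubes):
        p, q = nested_cubes
        lv = positional_dice_loss(p, q, exclude_background=True)
        assert lv.components["dice"] == pytest.approx(1 / 3)
        assert lv.components["bbox"] == pytest.approx(1 / 6)
        assert lv.total == pytest.approx(1 / 2)

    def test_total_is_component_sum(self, rng):
        p = random_onehot(rng)
        q = random_onehot(rng).astype(float)
        lv = positional_dice_loss(p, q)
        assert lv.total == pytest.approx(sum(lv.components.values()))

    def test_translation_covariance(self, rng):
        p = np.zeros((10, 10, 10, 2))
        q = np.zeros((10, 10, 10, 2))
        p[..., 0] = 1
        q[..., 0] = 1
        p[2:5, 2:5, 2:4] = [0, 1]
        q[3:6, 2:6, 2:5] = [0, 1]
        base = positional_dice_loss(p, q).total
        shifted = positional_dice_loss(
            np.roll(p, (2, 1, 3), axis=(0, 1, 2)),
            np.roll(q, (2, 1, 3), axis=(0, 1, 2)),
        ).total
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_range_bounds(self, rng):
        for _ in range(20):
            p = random_onehot(rng, n_channels=4)
            q = random_soft(rng, shape=(8, 8, 8))
            lv = positional_dice_loss(p, q)
            assert 0 <= lv.components["dice"] <= 1
            assert 0 <= lv.components["bbox"] <= 1
            assert 0 <= lv.total <= 2


class TestDiceCrossEntropy:
    def test_near_identity(self, rng):
        p = random_onehot(rng, n_channels=4)
        q = np.where(p == 1, 1 - 3e-7, 1e-7).astype(float)
        lv = dice_cross_entropy_loss(p, q)
        assert lv.total == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_ce_is_ln4(self, rng):
        p = random_onehot(rng, n_channels=4)
        q = np.full(p.shape, 0.25)
        lv = dice_cross_entropy_loss(p, q)
        assert lv.components["cross_entropy"] == pytest.approx(np.log(4.0))

    def test_components_sum(self, rng):
        p = random_onehot(rng, n_channels=4)
        q = random_soft(rng, shape=(8, 8, 8))
        lv = dice_cross_entropy_loss(p, q)
        assert lv.total == pytest.approx(sum(lv.components.values()))


class TestLossValueContract:
    def test_inconsistent_components_rejected(self):
        with pytest.raises(ValueError):
            LossValue(total=1.0, components={"a": 0.2, "b": 0.2})


class TestGradients:
    def _fd_grad(self, f, q, coords, h=1e-6):
        g = {}
        for c in coords:
            qp = q.copy()
            qp[c] += h
            qm = q.copy()
            qm[c] -= h
            g[c] = (f(qp) - f(qm)) / (2 * h)
        return g

    @pytest.mark.parametrize("loss_name", ["dice", "pdl", "dce"])
    def test_analytic_matches_finite_difference(self, rng, loss_name):
        p = random_onehot(rng, shape=(6, 6, 6), n_channels=4)
        q = random_soft(rng, shape=(6, 6, 6))
        loss_fn = get_loss(loss_name)

        def f(q_arr):
            return float(loss_fn(p, Tensor(q_arr), False).data)

        qt = Tensor(q, requires_grad=True)
        loss = loss_fn(p, qt, False)
        loss.backward()
        coords = [tuple(rng.integers(0, s) for s in q.shape) for _ in range(40)]
        fd = self._fd_grad(f, q, coords)
        for c, g_fd in fd.items():
            assert qt.grad[c] == pytest.approx(g_fd, abs=1e-4)

    def test_gradient_descent_strictly_decreases_pdl(self, rng):
        """50 gradient steps on free softmax logits strictly decrease the PDL
        against a fixed toy target."""
        p = np.zeros((6, 6, 6, 4))
        p[..., 0] = 1
        p[1:4, 2:5, 1:4] = [0, 1, 0, 0]
        p[4:6, 0:2, 4:6] = [0, 0, 1, 0]
        z = rng.normal(0, 0.1, size=(6, 6, 6, 4))
        losses = []
        for _ in range(50):
            zt = Tensor(z, requires_grad=True)
            e = zt.exp()
            q = e / e.sum(axis=-1, keepdims=True)
            loss = positional_dice_loss_t(p, q)
            loss.backward()
            losses.append(float(loss.data))
            z = z - 10.0 * zt.grad
        final = float(positional_dice_loss_t(p, Tensor(np.exp(z) /
                      np.exp(z).sum(-1, keepdims=True))).data)
        losses.append(final)
        assert all(b < a for a, b in zip(losses, losses[1:]))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_pdl_zero_iff_identical_crisp(seed):
    """For crisp predictions the PDL vanishes exactly when the masks agree."""
    rng = np.random.default_rng(seed)
    p = random_onehot(rng, shape=(5, 5, 5), n_channels=3)
    q = random_onehot(rng, shape=(5, 5, 5), n_channels=3)
    total = positional_dice_loss(p, q.astype(float)).total
    if np.array_equal(p, q):
        assert total == 0.0
    else:
        assert total > 0.0
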