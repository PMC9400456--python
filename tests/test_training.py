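"""Template training: gradients, batch updates, binarization, convergence."""

import numpy as np
import pytest

import wavecnn as w
from wavecnn.core import Neighborhood, TemplateSet
from wavecnn.training import (
    EDGE_DETECTION_B,
    BinarizationMode,
    InitScheme,
    TemplateGradient,
    TrainingConfig,
    threshold_pct_to_value,
)


def loop_template_gradient(err, y, u, nb):
    """Explicit quadruple-loop oracle for the template update rules."""
    H, W = err.shape
    mask = nb.mask
    dA = np.zeros((3, 3))
    dB = np.zeros((3, 3))
    dI = 0.0
    for m in range(3):
        for n in range(3):
            for i in range(H):
                for j in range(W):
                    ii, jj = i + m - 1, j + n - 1
                    if 0 <= ii < H and 0 <= jj < W:
                        dA[m, n] += err[i, j] * y[ii, jj]
                        dB[m, n] += err[i, j] * u[ii, jj]
    for i in range(H):
        for j in range(W):
            dI += err[i, j]
    dA = np.where(mask, dA, 0.0) / (H * W)
    dB = np.where(mask, dB, 0.0) / (H * W)
    return dA, dB, dI / (H * W)


class TestInitialization:
    def test_zero(self):
        theta = w.initialize_templates(InitScheme.ZERO)
        assert np.all(theta.A == 0) and np.all(theta.B == 0) and theta.I == 0

    def test_edge_detection_values(self):
        theta = w.initialize_templates(InitScheme.EDGE_DETECTION)
        assert np.array_equal(theta.B, EDGE_DETECTION_B)
        assert theta.B[1, 1] == 8.0 and theta.B[0, 0] == -1.0
        assert np.all(theta.A == 0) and theta.I == 1.0

    def test_random_uniform_seeded_and_in_range(self):
        a = w.initialize_templates(InitScheme.RANDOM_UNIFORM, np.random.default_rng(3))
        b = w.initialize_templates(InitScheme.RANDOM_UNIFORM, np.random.default_rng(3))
        assert a.allclose(b, rtol=0, atol=0)
        assert np.all(np.abs(a.A) <= 1) and np.all(np.abs(a.B) <= 1) and abs(a.I) <= 1


class TestCellError:
    @pytest.mark.parametrize(
        "d, y, e", [(1.0, 1.0, 0.0), (1.0, -1.0, 2.0), (-1.0, 0.0, 0.5)]
    )
    def test_examples(self, d, y, e):
        got = w.cell_error(np.array([[d]]), np.array([[y]]))
        assert got[0, 0] == pytest.approx(e)

    def test_nonnegative_and_shape_check(self, rng):
        d = np.sign(rng.normal(size=(4, 4)))
        y = rng.uniform(-1, 1, (4, 4))
        assert np.all(w.cell_error(d, y) >= 0)
        with pytest.raises(ValueError):
            w.cell_error(d, y[:2])


class TestTemplateGradient:
    def test_zero_error_gives_zero_gradient(self, rng):
        g = w.template_gradient(np.zeros((5, 5)), rng.normal(size=(5, 5)),
                                rng.normal(size=(5, 5)))
        assert np.all(g.dA == 0) and np.all(g.dB == 0) and g.dI == 0

    def test_single_cell_grid(self):
        e, y, u = 0.3, -0.4, 0.9
        g = w.template_gradient(np.array([[e]]), np.array([[y]]), np.array([[u]]))
        assert g.dA[1, 1] == pytest.approx(e * y)
        assert g.dB[1, 1] == pytest.approx(e * u)
        assert g.dI == pytest.approx(e)
        # off-center shifts fall outside the 1x1 grid
        assert g.dA[0, 0] == 0 and g.dB[2, 1] == 0

    @pytest.mark.parametrize("nb", [Neighborhood.EIGHT, Neighborhood.FOUR])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, nb, seed):
        r = np.random.default_rng(seed)
        H, W = r.integers(3, 9, size=2)
        err = r.normal(size=(H, W))
        y = r.uniform(-1, 1, (H, W))
        u = r.uniform(-1, 1, (H, W))
        g = w.template_gradient(err, y, u, nb)
        dA, dB, dI = loop_template_gradient(err, y, u, nb)
        assert np.allclose(g.dA, dA, rtol=1e-12, atol=1e-14)
        assert np.allclose(g.dB, dB, rtol=1e-12, atol=1e-14)
        assert g.dI == pytest.approx(dI, rel=1e-12)

    def test_batched_equals_mean_of_per_sample(self, rng):
        E = rng.normal(size=(4, 6, 6))
        Y = rng.uniform(-1, 1, (4, 6, 6))
        U = rng.uniform(-1, 1, (4, 6, 6))
        g = w.template_gradient(E, Y, U)
        per = [w.template_gradient(E[k], Y[k], U[k]) for k in range(4)]
        gm = w.batch_gradient(per)
        assert np.allclose(g.dA, gm.dA, rtol=1e-12)
        assert np.allclose(g.dB, gm.dB, rtol=1e-12)
        assert g.dI == pytest.approx(gm.dI, rel=1e-12)


class TestBatchGradient:
    def test_singleton_identity(self, rng):
        g = w.template_gradient(rng.normal(size=(4, 4)),
                                rng.uniform(-1, 1, (4, 4)),
                                rng.uniform(-1, 1, (4, 4)))
        m = w.batch_gradient([g])
        assert np.array_equal(m.dA, g.dA) and m.dI == g.dI

    def test_opposite_gradients_cancel(self, rng):
        a = rng.normal(size=(3, 3))
        g1 = TemplateGradient(a, -a, 0.5)
        g2 = TemplateGradient(-a, a, -0.5)
        m = w.batch_gradient([g1, g2])
        assert np.allclose(m.dA, 0) and np.allclose(m.dB, 0) and m.dI == 0

    def test_matches_running_sum_oracle(self, rng):
        gs = [
            TemplateGradient(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)),
                             float(rng.normal()))
            for _ in range(7)
        ]
        m = w.batch_gradient(gs)
        sA = np.zeros((3, 3)); sB = np.zeros((3, 3)); sI = 0.0
        for g in gs:
            sA = sA + g.dA; sB = sB + g.dB; sI += g.dI
        assert np.allclose(m.dA, sA / 7, rtol=1e-12)
        assert np.allclose(m.dB, sB / 7, rtol=1e-12)
        assert m.dI == pytest.approx(sI / 7, rel=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            w.batch_gradient([])


class TestApplyUpdate:
    def test_null_learning_rate_is_tolerated_as_no_step(self, rng):
        theta = TemplateSet(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)), 0.1)
        g = TemplateGradient(np.zeros((3, 3)), np.zeros((3, 3)), 0.0)
        out = w.apply_update(theta, g, eta=0.5)
        assert out.allclose(theta, rtol=0, atol=0)

    def test_single_entry_arithmetic(self):
        g = TemplateGradient(np.zeros((3, 3)), np.zeros((3, 3)), 0.0)
        g.dA[1, 1] = 1.0
        out = w.apply_update(TemplateSet(), g, eta=0.1)
        assert out.A[1, 1] == pytest.approx(0.1)

    def test_clip_contract(self):
        theta = TemplateSet()
        theta.A[0, 1] = 0.9
        g = TemplateGradient(np.zeros((3, 3)), np.zeros((3, 3)), 0.0)
        g.dA[0, 1] = 8.0
        out = w.apply_update(theta, g, eta=0.1, clip=(-1, 1))
        assert out.A[0, 1] == 1.0


class TestBinarize:
    @pytest.mark.parametrize(
        "y, thr, out", [(0.2, 0.0, 1.0), (-0.2, 0.0, -1.0), (0.5, 0.5, 1.0),
                        (0.3, -1.0, 1.0), (-1.0, -1.0, 1.0)]
    )
    def test_examples_and_tie_goes_up(self, y, thr, out):
        assert w.binarize(np.array([[y]]), thr)[0, 0] == out

    @pytest.mark.parametrize("pct, value", [(25, -0.5), (50, 0.0), (75, 0.5)])
    def test_threshold_percent_map(self, pct, value):
        assert threshold_pct_to_value(pct) == pytest.approx(value)


class TestTrain:
    def test_seeded_reproducibility_bit_exact(self, small_pairs):
        train, _ = small_pairs
        cfg = TrainingConfig(epochs=4, batch_size=12, seed=11)
        t1, h1 = w.train(train[:24], cfg)
        t2, h2 = w.train(train[:24], cfg)
        assert t1.allclose(t2, rtol=0, atol=0)
        assert np.array_equal(h1.mean_errors, h2.mean_errors)

    def test_converged_fixed_point_leaves_templates_unchanged(self):
        """Labels produced by the initial templates give zero gradients."""
        theta0 = w.initialize_templates(InitScheme.EDGE_DETECTION)
        rng = np.random.default_rng(5)
        us = [rng.choice([-1.0, 1.0], size=(8, 8)) for _ in range(4)]
        # labels = binarized outputs of theta0; outputs are already saturated
        data = []
        for u in us:
            y = w.infer(u, theta0)
            assert np.all(np.abs(y) > 1 - 1e-3)  # saturated up to steady_tol
            data.append((u, w.binarize(y, 0.0)))
        cfg = TrainingConfig(epochs=3, init=InitScheme.EDGE_DETECTION,
                             binarization=BinarizationMode.DURING, seed=0)
        theta, hist = w.train(data, cfg)
        assert theta.allclose(theta0, atol=1e-9)
        assert hist.mean_errors[-1] == pytest.approx(0.0, abs=1e-12)

    def test_mean_error_trend_nonincreasing(self, small_pairs):
        """Grayscale batch training error decreases over epochs (plateaus
        allowed), across seeds."""
        train, _ = small_pairs
        for seed in (1, 2, 3):
            cfg = TrainingConfig(epochs=40, batch_size=12, seed=seed)
            _, hist = w.train(train, cfg)
            e = hist.mean_errors
            assert e[-1] < e[0]
            assert np.max(e[5:] - e[:-5]) < 5e-3  # no sustained increase

    def test_during_mode_converges_faster(self, small_pairs):
        """Thresholded-output training drives its residuals at full scale and
        reaches high sensitivity in fewer epochs than grayscale training."""
        train, _ = small_pairs
        first_crossing = {}
        for mode in (BinarizationMode.AFTER, BinarizationMode.DURING):
            cfg = TrainingConfig(epochs=60, batch_size=12, seed=1, binarization=mode)
            _, hist = w.train(train, cfg)
            s = hist.metric_series("sensitivity")
            above = np.nonzero(s >= 0.8)[0]
            first_crossing[mode] = above[0] if above.size else len(s)
        assert first_crossing[BinarizationMode.DURING] <= first_crossing[BinarizationMode.AFTER]

    def test_learning_rate_window(self, small_pairs):
        """Extreme learning rates are strictly worse (test precision) than
        the optimum eta=0.1, per seed over three seeds."""
        train, test = small_pairs
        precs = {}
        for eta in (1e-4, 0.1, 1e4):
            vals = []
            for seed in (1, 2, 3):
                cfg = TrainingConfig(eta=eta, epochs=30, batch_size=12, seed=seed)
                try:
                    theta, _ = w.train(train, cfg)
                    m, _ = w.evaluate_dataset(test, theta)
                    vals.append(0.0 if m.precision is None else m.precision)
                except w.DivergenceError:
                    vals.append(0.0)
            precs[eta] = vals
        for seed_idx in range(3):
            assert precs[0.1][seed_idx] > precs[1e-4][seed_idx]
            assert precs[0.1][seed_idx] > precs[1e4][seed_idx]

    def test_threshold_monotonicity(self, small_pairs):
        """On a fixed grayscale output, raising the threshold from 25% to 75%
        never decreases sensitivity and never increases precision."""
        train, test = small_pairs
        cfg = TrainingConfig(epochs=30, batch_size=12, seed=1)
        theta, _ = w.train(train, cfg)
        records = [
            w.evaluate_dataset(test, theta, threshold_pct=pct)[0]
            for pct in (25, 50, 75)
        ]
        sens = [r.sensitivity for r in records]
        prec = [r.precision for r in records]
        assert sens[0] <= sens[1] <= sens[2]
        assert prec[0] >= prec[1] >= prec[2]

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            w.train([], TrainingConfig(epochs=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(eta=-1)
        with pytest.raises(ValueError):
            TrainingConfig(threshold_pct=0)
        with pytest.raises(ValueError):
            TrainingConfig(quant_when="during")
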