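"""Preprocessing, segmentation, block refinement, and the identity-link
zero-inflated negative binomial testing machinery."""

import numpy as np
import pytest

from mccu.differential import (
    CountTensor,
    SegmentationBlock,
    _sse_split_gain,
    binary_segmentation,
    differential_pipeline,
    fit_zinb_identity,
    mean_difference_grid,
    preprocess_counts,
    refine_blocks,
    results_table,
    segment_blocks,
    test_blocks as run_block_tests,
)


def _zinb(rng, mu, size, pi, shape):
    y = rng.negative_binomial(size, size / (size + mu), shape).astype(float)
    y[rng.random(shape) < pi] = 0
    return y


class TestPreprocess:
    def test_identical_replicate_sets_give_zero_difference(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(10, (3, 20, 20)).astype(float)
        t = preprocess_counts(CountTensor(a.copy(), a.copy()), low_count=1)
        d = mean_difference_grid(t)
        assert np.allclose(d, 0)

    @pytest.mark.parametrize("known_c", [True, False])
    def test_multiplicative_cut_bias_is_removed(self, known_c):
        """Counts built as c_i * c_j * mu come out flat after correction
        (CV below 0.05 at simulation depth 1e5)."""
        rng = np.random.default_rng(4)
        n = 30
        c = 0.5 + 1.5 * rng.random(n)
        mu = 1e5 / np.outer(c, c).sum()
        lam = np.outer(c, c) * mu
        a = rng.poisson(lam, size=(3, n, n)).astype(float)
        b = rng.poisson(lam, size=(3, n, n)).astype(float)
        t = preprocess_counts(
            CountTensor(a, b, cut_profile=c if known_c else None), low_count=1
        )
        pooled = t.stacked.mean(axis=0)
        vals = pooled[~t.mask]
        assert vals.std() / vals.mean() < 0.05

    def test_outlier_winsorized_to_quantile(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(10, (2, 40, 40)).astype(float)
        b = rng.poisson(10, (2, 40, 40)).astype(float)
        cap = np.quantile(np.concatenate([a, b])[np.concatenate([a, b]) > 0], 0.999)
        a[0, 0, 0] = cap * 100
        t = preprocess_counts(CountTensor(a, b), low_count=1)
        # the spike is reduced to the vicinity of the quantile cap, not kept
        assert t.cond_a[0, 0, 0] < cap * 2

    def test_low_count_pixels_masked(self):
        a = np.ones((2, 10, 10))
        b = np.ones((2, 10, 10))
        a[:, 0, 0] = 0
        b[:, 0, 0] = 0
        t = preprocess_counts(CountTensor(a, b), low_count=2)
        assert t.mask[0, 0]

    def test_single_replicate_rejected(self):
        a = np.ones((1, 5, 5))
        b = np.ones((2, 5, 5))
        with pytest.raises(ValueError):
            preprocess_counts(CountTensor(a, b))


class TestSegmentation:
    def test_crossed_breakpoints_recovered_within_one_pixel(self):
        rng = np.random.default_rng(5)
        g = np.zeros((100, 100))
        g[50:, :] += 2.0
        g[:, 50:] += 1.5
        g += rng.normal(0, 0.3, g.shape)
        blocks = segment_blocks(g, min_block=10)
        assert len(blocks) == 4
        rows = sorted({b.row for b in blocks})
        cols = sorted({b.col for b in blocks})
        assert abs(rows[0][1] - 50) <= 1 and abs(cols[0][1] - 50) <= 1
        # blocks tile the grid
        assert sum(b.n_pixels for b in blocks) == g.size

    def test_matches_exhaustive_single_split_oracle(self):
        rng = np.random.default_rng(6)
        x = np.r_[rng.normal(0, 0.2, 37), rng.normal(1.7, 0.2, 63)]
        # oracle: exhaustive best split by squared error
        best = min(
            range(10, 91),
            key=lambda k: ((x[:k] - x[:k].mean()) ** 2).sum()
            + ((x[k:] - x[k:].mean()) ** 2).sum(),
        )
        k, _ = _sse_split_gain(x, 10)
        assert k == best
        assert binary_segmentation(x, min_size=10) == [best]

    def test_constant_grid_yields_single_block(self):
        blocks = segment_blocks(np.ones((60, 60)), min_block=10)
        assert len(blocks) == 1
        assert blocks[0].row == (0, 60) and blocks[0].col == (0, 60)

    def test_changepoint_budget_respected(self):
        rng = np.random.default_rng(7)
        x = np.cumsum(rng.normal(0, 1, 400))  # many apparent shifts
        cps = binary_segmentation(x, min_size=10, max_changepoints=3)
        assert len(cps) <= 3

    def test_small_grid_returns_single_block(self):
        blocks = segment_blocks(np.ones((4, 4)), min_block=10)
        assert len(blocks) == 1


class TestRefine:
    def _tensor(self, rng, n=40):
        a = rng.poisson(5, (3, n, n)).astype(float)
        b = rng.poisson(5, (3, n, n)).astype(float)
        return CountTensor(a, b)

    def test_zero_penalty_drops_nothing(self):
        rng = np.random.default_rng(8)
        t = self._tensor(rng)
        blocks = segment_blocks(mean_difference_grid(t), min_block=10)
        out = refine_blocks(blocks, t, lasso_penalty=0.0)
        assert all(b.status != "dropped_low_count" for b in out)

    def test_all_zero_block_dropped_at_positive_penalty(self):
        rng = np.random.default_rng(9)
        a = rng.poisson(20, (3, 40, 40)).astype(float)
        a[:, 20:, :] = 0
        t = CountTensor(a, a.copy())
        blocks = [SegmentationBlock((0, 20), (0, 40)), SegmentationBlock((20, 40), (0, 40))]
        out = refine_blocks(blocks, t, lasso_penalty=0.5)
        assert out[1].status == "dropped_low_count"
        assert out[0].status != "dropped_low_count"

    def test_spike_smoothed_below_half(self):
        rng = np.random.default_rng(10)
        a = rng.poisson(50, (3, 20, 20)).astype(float)
        a[:, 10, 10] = 2000.0
        t = CountTensor(a, a.copy())
        blocks = [SegmentationBlock((0, 20), (0, 20))]
        out = refine_blocks(blocks, t, lasso_penalty=0.0, smooth_df=6,
                            high_count_quantile=0.0)
        assert out[0].status == "smoothed"
        assert out[0].smoothed[10, 10] < 1000.0

    def test_negative_penalty_rejected(self):
        rng = np.random.default_rng(11)
        t = self._tensor(rng)
        with pytest.raises(ValueError):
            refine_blocks([SegmentationBlock((0, 40), (0, 40))], t, lasso_penalty=-1)


class TestZinb:
    x = np.r_[np.zeros(6), np.ones(6)]

    def test_identical_replicates_give_null_result(self):
        y = np.array([5.0, 7, 6, 5, 7, 6] * 2)
        fit = fit_zinb_identity(y, self.x)
        assert fit["effect"] == 0
        assert fit["p"] == 1.0 or np.isnan(fit["p"])

    def test_recovers_effect_and_dispersion_scale(self):
        rng = np.random.default_rng(12)
        eff = []
        for _ in range(50):
            y = np.r_[_zinb(rng, 30, 5, 0.1, 6), _zinb(rng, 60, 5, 0.1, 6)]
            f = fit_zinb_identity(y, self.x)
            eff.append(f["effect"])
        assert abs(np.mean(eff) - 30) < 8

    def test_nb_fallback_without_zero_inflation(self):
        rng = np.random.default_rng(13)
        y = np.r_[_zinb(rng, 50, 10, 0.0, 6), _zinb(rng, 50, 10, 0.0, 6)]
        f = fit_zinb_identity(y, self.x)
        assert f["model"] in ("nb", "zinb")
        if f["model"] == "nb":
            assert f["pi"] == 0.0

    def test_agrees_with_statsmodels_nb_on_dispersion_free_case(self):
        """Independent cross-check: without zeros the identity-link effect
        must match a statsmodels NB GLM with identity link."""
        import statsmodels.api as sm

        rng = np.random.default_rng(14)
        y = np.r_[_zinb(rng, 40, 8, 0.0, 6), _zinb(rng, 90, 8, 0.0, 6)]
        ours = fit_zinb_identity(y, self.x)
        X = np.c_[np.ones(12), self.x]
        ref = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(
                alpha=np.exp(ours["log_alpha"]),
                link=sm.families.links.Identity(),
            ),
        ).fit()
        assert abs(ours["effect"] - ref.params[1]) < 0.5


class TestBlocks:
    def _tensor_from_counts(self, a, b):
        return CountTensor(a[..., None, None] * np.ones((1, 1)), b[..., None, None] * np.ones((1, 1)))

    def test_type_one_error_within_band(self):
        """Null calibration: both conditions from the same ZINB; empirical
        type-I at p<0.05 within [0.02, 0.09] over 200 blocks."""
        rng = np.random.default_rng(42)
        a = _zinb(rng, 20, 5, 0.2, (6, 200, 1))
        b = _zinb(rng, 20, 5, 0.2, (6, 200, 1))
        tensor = CountTensor(a, b)
        blocks = [SegmentationBlock((i, i + 1), (0, 1)) for i in range(200)]
        res = run_block_tests(blocks, tensor)
        ps = np.array([r.p_value for r in res])
        ok = np.isfinite(ps)
        assert ok.sum() >= 190
        assert 0.02 <= np.mean(ps[ok] < 0.05) <= 0.09

    def test_effect_estimate_nearly_unbiased(self):
        """Injected 2-fold difference recovered with |bias| < 10% of mu
        across 500 blocks."""
        rng = np.random.default_rng(43)
        a = _zinb(rng, 50, 5, 0.2, (6, 500, 1))
        b = _zinb(rng, 100, 5, 0.2, (6, 500, 1))
        tensor = CountTensor(a, b)
        blocks = [SegmentationBlock((i, i + 1), (0, 1)) for i in range(500)]
        res = run_block_tests(blocks, tensor)
        effs = np.array([r.effect for r in res])
        assert abs(np.nanmean(effs) - 50) < 5.0

    def test_bh_qvalues_monotone_in_p_rank(self):
        rng = np.random.default_rng(44)
        a = _zinb(rng, 20, 5, 0.2, (6, 60, 1))
        b = _zinb(rng, 25, 5, 0.2, (6, 60, 1))
        tensor = CountTensor(a, b)
        blocks = [SegmentationBlock((i, i + 1), (0, 1)) for i in range(60)]
        res = [r for r in run_block_tests(blocks, tensor) if np.isfinite(r.p_value)]
        res.sort(key=lambda r: r.p_value)
        qs = [r.q_value for r in res]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in res)

    def test_single_replicate_rejected(self):
        a = np.ones((1, 5, 5))
        b = np.ones((3, 5, 5))
        with pytest.raises(ValueError):
            run_block_tests([SegmentationBlock((0, 5), (0, 5))], CountTensor(a, b))


def test_pipeline_is_deterministic():
    rng = np.random.default_rng(45)
    base = rng.poisson(8, (30, 30)).astype(float)
    a = rng.poisson(base, (6, 30, 30)).astype(float)
    b = rng.poisson(base, (6, 30, 30)).astype(float)
    r1 = results_table(differential_pipeline(CountTensor(a.copy(), b.copy()), min_block=10))
    r2 = results_table(differential_pipeline(CountTensor(a.copy(), b.copy()), min_block=10))
    assert r1.equals(r2)


def test_pipeline_finds_injected_block_difference():
    """End-to-end: a strong rectangular perturbation is segmented out and
    called significant."""
    rng = np.random.default_rng(46)
    base = np.full((60, 60), 20.0)
    a = rng.poisson(base, (6, 60, 60)).astype(float)
    shifted = base.copy()
    shifted[20:40, 20:40] *= 3.0
    b = rng.poisson(shifted, (6, 60, 60)).astype(float)
    res = differential_pipeline(CountTensor(a, b), min_block=10, lasso_penalty=0.0)
    hits = [
        r for r in res
        if np.isfinite(r.q_value) and r.q_value < 0.05
        and 15 <= r.block.row[0] <= 25 and 15 <= r.block.col[0] <= 25
    ]
    assert hits
    assert all(h.effect > 0 for h in hits)
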