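"""Channel ranking, surrogate construction, and CSP against a whitening oracle."""

import numpy as np
import pytest

from preictal import (
    Segment,
    apply_surrogate,
    average_surrogate,
    channel_variance,
    fit_csp,
    select_channels,
    signal_quality_index,
)

FS = 256.0


def csp_oracle(c_pre, c_inter):
    """Independent CSP route: whiten the composite covariance explicitly
    (inverse matrix square root), eigendecompose the whitened preictal
    covariance, map back.  Returns (eigenvalues desc, filters as rows)."""
    comp = c_pre + c_inter
    vals, vecs = np.linalg.eigh(comp)
    whiten = vecs @ np.diag(vals**-0.5) @ vecs.T
    s = whiten @ c_pre @ whiten.T
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    return evals[order], (whiten.T @ evecs[:, order]).T


def random_class_trials(rng, n_ch, n_trials=30, n_time=512):
    mix = rng.standard_normal((n_ch, n_ch)) + np.eye(n_ch)
    scales = rng.uniform(0.5, 2.0, n_ch)
    return np.einsum(
        "cd,ndt->nct", mix * scales[None, :], rng.standard_normal((n_trials, n_ch, n_time))
    )


class TestChannelVariance:
    def test_small_fixture_population_variance(self):
        seg = Segment(np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]), FS, 0.0)
        v = channel_variance([seg])
        np.testing.assert_allclose(v, [2.0 / 3.0, 0.0])

    def test_scaling_by_c_scales_variance_by_c_squared(self, rng):
        x = rng.standard_normal((2, 100))
        v1 = channel_variance(x[None])
        v2 = channel_variance((3.0 * x)[None])
        np.testing.assert_allclose(v2, 9.0 * v1)


class TestSqi:
    def _tone(self, freq, seconds=4):
        t = np.arange(int(seconds * FS)) / FS
        return np.sin(2 * np.pi * freq * t)

    def test_in_band_tone_scores_one(self):
        assert signal_quality_index(self._tone(10), FS) > 0.99

    def test_out_of_band_tone_scores_zero(self):
        assert signal_quality_index(self._tone(100), FS) < 0.01

    def test_equal_power_mixture_scores_half(self):
        mix = self._tone(10) + self._tone(100)
        assert abs(signal_quality_index(mix, FS) - 0.5) < 0.05

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            signal_quality_index(np.ones(100), FS)


class TestSelectChannels:
    def _fixture(self, rng):
        """4 channels with strictly distinct variances and SQIs (tie-free):
        in-band amplitude sets variance, the out-of-band admixture sets SQI."""
        t = np.arange(int(4 * FS)) / FS
        chans = [
            4.0 * np.sin(2 * np.pi * 10 * t) + 0.5 * np.sin(2 * np.pi * 100 * t),
            3.0 * np.sin(2 * np.pi * 11 * t) + 1.0 * np.sin(2 * np.pi * 90 * t),
            2.0 * np.sin(2 * np.pi * 12 * t) + 1.2 * np.sin(2 * np.pi * 80 * t),
            1.0 * np.sin(2 * np.pi * 13 * t) + 1.5 * np.sin(2 * np.pi * 70 * t),
        ]
        return np.stack(chans)[None]

    def test_best_in_both_criteria_selected_first(self, rng):
        ranking = select_channels(self._fixture(rng), FS, n_select=2)
        assert ranking.selected_indices[0] == 0

    def test_selection_matches_bruteforce_rank_sums(self, rng):
        x = self._fixture(rng)
        ranking = select_channels(x, FS, n_select=4)
        variances = channel_variance(x)
        sqis = [signal_quality_index(x[0, c], FS) for c in range(4)]

        def brute_rank(vals):
            order = sorted(range(4), key=lambda c: (-vals[c], c))
            return {c: i for i, c in enumerate(order)}

        rv, rs = brute_rank(list(variances)), brute_rank(sqis)
        expect = sorted(range(4), key=lambda c: (rv[c] + rs[c], c))
        assert ranking.selected_indices == expect

    def test_select_all_returns_everything(self, rng):
        ranking = select_channels(self._fixture(rng), FS, n_select=4)
        assert sorted(ranking.selected_indices) == [0, 1, 2, 3]

    def test_permutation_equivariance(self, rng):
        x = self._fixture(rng)
        perm = np.array([2, 0, 3, 1])
        base = select_channels(x, FS, n_select=2).selected_indices
        permuted = select_channels(x[:, perm], FS, n_select=2).selected_indices
        assert [int(perm[i]) for i in permuted] == base


class TestAverageSurrogate:
    def test_identical_channels_returned_unchanged(self, rng):
        x = rng.standard_normal(200)
        out = average_surrogate(np.stack([x, x]))
        np.testing.assert_allclose(out[0], x)

    def test_opposite_channels_cancel(self, rng):
        x = rng.standard_normal(200)
        out = average_surrogate(np.stack([x, -x]))
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_mean_of_independent_noise_has_lower_variance(self, rng):
        x = rng.standard_normal((8, 5000))
        out = average_surrogate(x)
        assert out.var() < x.var(axis=1).min()


class TestCsp:
    def test_channel_specific_activity_recovered(self, rng):
        # class A active only in channel 0, class B only in channel 1
        n = 40
        a = 0.05 * rng.standard_normal((n, 2, 512))
        a[:, 0] = 5.0 * rng.standard_normal((n, 512))
        b = 0.05 * rng.standard_normal((n, 2, 512))
        b[:, 1] = 5.0 * rng.standard_normal((n, 512))
        model = fit_csp(a, b)
        assert model.eigenvalues[0] > 0.9
        w = np.abs(model.filters[0])
        assert w[0] > 10 * w[1]

    def test_identical_distributions_give_half_eigenvalues(self, rng):
        # both classes drawn from the same mixing (same covariance)
        mix = rng.standard_normal((4, 4)) + np.eye(4)
        x = np.einsum("cd,ndt->nct", mix, rng.standard_normal((150, 4, 512)))
        y = np.einsum("cd,ndt->nct", mix, rng.standard_normal((150, 4, 512)))
        model = fit_csp(x, y)
        assert np.all(np.abs(model.eigenvalues - 0.5) < 0.05)

    def test_whitening_identity(self, rng):
        a = random_class_trials(rng, 5)
        b = random_class_trials(rng, 5)
        model = fit_csp(a, b)
        w = model.filters
        c1, c2 = model.class_covariances
        np.testing.assert_allclose(w @ (c1 + c2) @ w.T, np.eye(5), atol=1e-6)

    @pytest.mark.parametrize("n_ch", [2, 3, 6])
    def test_matches_whitening_oracle(self, rng, n_ch):
        a = random_class_trials(rng, n_ch)
        b = random_class_trials(rng, n_ch)
        model = fit_csp(a, b)
        evals, _ = csp_oracle(*model.class_covariances)
        np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-6)
        # filters agree up to sign
        _, wo = csp_oracle(*model.class_covariances)
        for wf, wb in zip(model.filters, wo):
            assert min(np.abs(wf - wb).max(), np.abs(wf + wb).max()) < 1e-6

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            fit_csp(np.empty((0, 2, 64)), rng.standard_normal((3, 2, 64)))

    def test_singular_composite_covariance_regularized(self):
        # rank-deficient: channel 1 duplicates channel 0 in both classes
        rng = np.random.default_rng(0)
        base_a = rng.standard_normal((10, 1, 128))
        base_b = rng.standard_normal((10, 1, 128))
        a = np.concatenate([base_a, base_a], axis=1)
        b = np.concatenate([base_b, base_b], axis=1)
        with pytest.warns(UserWarning, match="singular"):
            model = fit_csp(a, b)
        assert np.all(np.isfinite(model.eigenvalues))


class TestApplySurrogate:
    def _unit_filter_model(self, j, n_ch):
        from preictal import SpatialFilterModel

        filters = np.eye(n_ch)[[j]]
        return SpatialFilterModel(
            class_covariances=(np.eye(n_ch), np.eye(n_ch)),
            filters=filters,
            eigenvalues=np.array([1.0]),
        )

    def test_unit_vector_filter_extracts_channel(self, rng):
        x = rng.standard_normal((3, 100))
        model = self._unit_filter_model(1, 3)
        np.testing.assert_allclose(apply_surrogate(model, x)[0], x[1])

    def test_linearity_in_input_scale(self, rng):
        x = rng.standard_normal((3, 100))
        model = self._unit_filter_model(0, 3)
        np.testing.assert_allclose(
            apply_surrogate(model, 2.5 * x), 2.5 * apply_surrogate(model, x)
        )

    def test_heldout_projection_separates_classes(self, rng):
        n = 60
        a = 0.05 * rng.standard_normal((n, 2, 512))
        a[:, 0] = 3.0 * rng.standard_normal((n, 512))
        b = 0.05 * rng.standard_normal((n, 2, 512))
        b[:, 1] = 3.0 * rng.standard_normal((n, 512))
        model = fit_csp(a[: n // 2], b[: n // 2])
        va = np.mean([apply_surrogate(model, t).var() for t in a[n // 2 :]])
        vb = np.mean([apply_surrogate(model, t).var() for t in b[n // 2 :]])
        assert va > vb

    def test_channel_mismatch_rejected(self, rng):
        model = self._unit_filter_model(0, 3)
        with pytest.raises(ValueError, match="channel"):
            apply_surrogate(model, rng.standard_normal((2, 100)))

    def test_output_is_single_channel(self, rng):
        model = self._unit_filter_model(0, 3)
        seg = Segment(rng.standard_normal((3, 100)), FS, 0.0)
        assert apply_surrogate(model, seg).n_channels == 1
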