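import numpy as np
import pytest
from scipy.stats import multivariate_normal

from wceclean import gbc, synthetic


def _toy_pair(n_clean=30, n_cont=70, seed=0):
    """One 10x10 frame with the first n_clean pixels (row-major) clean."""
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, (10, 10, 3), dtype=np.uint8)
    mask = np.zeros(100, dtype=bool)
    mask[:n_clean] = True
    return img, mask.reshape(10, 10)


def _random_spd(rng, scale=50.0):
    a = rng.standard_normal((3, 3))
    return a @ a.T * scale + np.eye(3) * 1e-2


class TestExtractClassPixels:
    def test_all_clean_counts(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        mask = np.ones((8, 8), dtype=bool)
        x = gbc.extract_class_pixels([img], [mask], "clean")
        assert x.shape == (64, 3)

    def test_absent_class_is_fit_error(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        mask = np.ones((8, 8), dtype=bool)
        with pytest.raises(gbc.FitError):
            gbc.extract_class_pixels([img], [mask], "contaminated")

    def test_two_frames_half_masks(self):
        imgs = [np.zeros((8, 8, 3), dtype=np.uint8)] * 2
        half = np.zeros((8, 8), dtype=bool)
        half[:4] = True
        x = gbc.extract_class_pixels(imgs, [half, half], "clean")
        assert x.shape == (64, 3)

    def test_row_major_frame_order(self):
        img = np.arange(8 * 8 * 3, dtype=np.uint8).reshape(8, 8, 3)
        mask = np.ones((8, 8), dtype=bool)
        x = gbc.extract_class_pixels([img], [mask], "clean")
        assert (x == img.reshape(-1, 3)).all()


class TestFit:
    def test_priors_are_pixel_shares(self):
        img, mask = _toy_pair(30, 70)
        model = gbc.fit([img], [mask])
        assert model.clean.prior == pytest.approx(0.3)
        assert model.contaminated.prior == pytest.approx(0.7)

    def test_degenerate_class_covariance_is_ridge(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[:, :] = (10, 20, 30)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5] = True
        img[~mask] = (200, 100, 50)
        model = gbc.fit([img], [mask], epsilon=1e-3)
        assert np.allclose(model.clean.covariance, 1e-3 * np.eye(3))

    def test_too_few_pixels_rejected(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        mask = np.zeros((8, 8), dtype=bool)
        mask.flat[:2] = True
        with pytest.raises(gbc.FitError):
            gbc.fit([img], [mask])

    @pytest.mark.parametrize("n,mean_tol,cov_tol", [(1_000, 2.0, 0.25), (100_000, 0.5, 0.03)])
    def test_parameter_recovery_improves_with_n(self, n, mean_tol, cov_tol):
        """Fitting samples from known Gaussians recovers them, error -> 0 with N."""
        clean, cont = synthetic.default_palettes()
        rng = np.random.default_rng(5)
        side = int(np.ceil(np.sqrt(2 * n)))
        xc = rng.multivariate_normal(clean.mean_array, clean.cov_array, n)
        xk = rng.multivariate_normal(cont.mean_array, cont.cov_array, n)
        pixels = np.clip(np.rint(np.concatenate([xc, xk])), 0, 255).astype(np.uint8)
        pad = side * side - 2 * n
        img = np.concatenate([pixels, np.zeros((pad, 3), np.uint8)])[: side * side]
        img = img.reshape(side, side, 3)
        mask = np.zeros(side * side, dtype=bool)
        mask[:n] = True
        model = gbc.fit([img], [mask.reshape(side, side)], epsilon=0.0)
        assert np.abs(model.clean.mean - clean.mean_array).max() < mean_tol
        rel = np.linalg.norm(model.clean.covariance - clean.cov_array) / np.linalg.norm(
            clean.cov_array
        )
        assert rel < cov_tol


class TestLogLikelihood:
    def test_at_mean_identity_covariance(self):
        cm = gbc.ClassModel(np.zeros(3), np.eye(3), 0.5, 10)
        assert gbc.log_likelihood(np.zeros(3), cm) == pytest.approx(-1.5 * np.log(2 * np.pi))

    def test_determinant_scaling(self):
        cm = gbc.ClassModel(np.zeros(3), 4 * np.eye(3), 0.5, 10)
        expected = -1.5 * np.log(2 * np.pi) - np.log(8)
        assert gbc.log_likelihood(np.zeros(3), cm) == pytest.approx(expected)

    def test_matches_naive_formula(self, rng):
        """Cholesky route vs explicit inverse/determinant on random SPD cases."""
        for _ in range(200):
            cov = _random_spd(rng)
            mu = rng.uniform(0, 255, 3)
            x = rng.uniform(0, 255, 3)
            cm = gbc.ClassModel(mu, cov, 0.5, 10)
            d = x - mu
            naive = -0.5 * (
                3 * np.log(2 * np.pi) + np.log(np.linalg.det(cov)) + d @ np.linalg.inv(cov) @ d
            )
            # 1e-10 relative-or-absolute: an absolute 1e-10 on log densities of
            # magnitude ~1e4 would exceed double precision itself
            assert gbc.log_likelihood(x, cm) == pytest.approx(naive, rel=1e-10, abs=1e-10)

    def test_non_finite_observation_rejected(self):
        cm = gbc.ClassModel(np.zeros(3), np.eye(3), 0.5, 10)
        with pytest.raises(ValueError):
            gbc.log_likelihood([np.nan, 0, 0], cm)


class TestPosterior:
    def _model(self, p_clean=0.5, mu2=None):
        cm1 = gbc.ClassModel(np.full(3, 100.0), 25 * np.eye(3), p_clean, 10)
        cm2 = gbc.ClassModel(
            np.full(3, 100.0) if mu2 is None else mu2, 25 * np.eye(3), 1 - p_clean, 10
        )
        return gbc.GbcModel(clean=cm1, contaminated=cm2)

    def test_symmetry_gives_half(self):
        p1, p2 = gbc.posterior([42, 17, 200], self._model())
        assert p1 == pytest.approx(0.5) and p2 == pytest.approx(0.5)

    def test_prior_one_dominates(self):
        p1, p2 = gbc.posterior([0, 0, 0], self._model(p_clean=1.0, mu2=np.full(3, 200.0)))
        assert p1 == pytest.approx(1.0) and p2 == pytest.approx(0.0)

    def test_normalisation(self, rng):
        model = self._model(0.3, mu2=np.full(3, 150.0))
        for _ in range(50):
            p1, p2 = gbc.posterior(rng.uniform(0, 255, 3), model)
            assert p1 + p2 == pytest.approx(1.0, abs=1e-12)

    def test_ratio_matches_log_odds(self, rng):
        """Posterior ratio equals exp(delta log prior + delta log likelihood)."""
        model = self._model(0.3, mu2=np.full(3, 130.0))
        x = rng.uniform(50, 200, 3)
        p1, p2 = gbc.posterior(x, model)
        log_odds = (
            np.log(0.3 / 0.7)
            + gbc.log_likelihood(x, model.clean)
            - gbc.log_likelihood(x, model.contaminated)
        )
        assert np.log(p1 / p2) == pytest.approx(log_odds, abs=1e-9)

    def test_labels_invariant_to_prior_scaling(self, rng):
        """Scaling both priors before normalisation cannot change the argmax."""
        cm1 = gbc.ClassModel(np.full(3, 120.0), 30 * np.eye(3), 0.4, 10)
        cm2 = gbc.ClassModel(np.full(3, 140.0), 30 * np.eye(3), 0.6, 10)
        model = gbc.GbcModel(clean=cm1, contaminated=cm2)
        x = rng.uniform(0, 255, (100, 3))
        for xi in x:
            p1, p2 = gbc.posterior(xi, model)
            ll = (
                np.log(0.4) + gbc.log_likelihood(xi, cm1),
                np.log(0.6) + gbc.log_likelihood(xi, cm2),
            )
            assert (p1 >= p2) == (ll[0] >= ll[1])


class TestSegment:
    def test_clean_mean_image_all_clean(self, fitted_model):
        img = np.tile(
            np.rint(fitted_model.clean.mean).astype(np.uint8), (8, 8, 1)
        )
        mask, p = gbc.segment(img, fitted_model)
        assert mask.all()
        assert (p > 0.5).all()

    def test_vectorized_equals_pixel_loop(self, fitted_model, rng):
        """Vectorised segmentation is identical to a per-pixel scalar loop."""
        for _ in range(10):
            img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
            mask, p = gbc.segment(img, fitted_model)
            for i in range(16):
                for j in range(16):
                    p1, p2 = gbc.posterior(img[i, j], fitted_model)
                    assert abs(p[i, j] - p1) < 1e-12
                    assert mask[i, j] == (p1 >= p2)

    def test_outside_fov_contaminated(self, fitted_model):
        img = np.tile(np.rint(fitted_model.clean.mean).astype(np.uint8), (8, 8, 1))
        fov = np.zeros((8, 8), dtype=bool)
        fov[2:6, 2:6] = True
        mask, p = gbc.segment(img, fitted_model, fov=fov)
        assert mask[2:6, 2:6].all() and not mask[~fov].any()
        assert (p[~fov] == 0).all()

    def test_decision_boundary_is_quadratic_root(self, fitted_model):
        """On a 1-D slice, the label flip sits at the root of the log-odds."""
        from scipy.optimize import brentq

        model = fitted_model

        def log_odds(t):
            x = model.clean.mean * t + model.contaminated.mean * (1 - t)
            return (
                np.log(model.clean.prior)
                + gbc.log_likelihood(x, model.clean)
                - np.log(model.contaminated.prior)
                - gbc.log_likelihood(x, model.contaminated)
            )

        root = brentq(log_odds, 0.0, 1.0)
        x_root = model.clean.mean * root + model.contaminated.mean * (1 - root)
        p1, p2 = gbc.posterior(x_root, model)
        assert p1 == pytest.approx(0.5, abs=1e-6)


class TestCleanFraction:
    @pytest.mark.parametrize(
        "fill,expected", [(True, 1.0), (False, 0.0)]
    )
    def test_constant_masks(self, fill, expected):
        assert gbc.clean_fraction(np.full((4, 4), fill, dtype=bool)) == expected

    def test_partial(self):
        mask = np.zeros(12, dtype=bool)
        mask[:3] = True
        assert gbc.clean_fraction(mask.reshape(3, 4)) == pytest.approx(0.25)

    def test_empty_fov_rejected(self):
        with pytest.raises(ValueError):
            gbc.clean_fraction(np.ones((4, 4), dtype=bool), fov=np.zeros((4, 4), dtype=bool))


class TestSerialization:
    def test_round_trip_posteriors_identical(self, fitted_model, tmp_path, rng):
        p = tmp_path / "model.json"
        gbc.save_model(fitted_model, p)
        back = gbc.load_model(p)
        x = rng.uniform(0, 255, 3)
        assert gbc.posterior(x, back) == gbc.posterior(x, fitted_model)

    def test_parameter_count_is_26(self, fitted_model):
        assert gbc.parameter_count(fitted_model) == 26

    def test_bad_prior_sum_rejected(self, fitted_model, tmp_path):
        import json

        p = tmp_path / "model.json"
        gbc.save_model(fitted_model, p)
        payload = json.loads(p.read_text())
        payload["parameters"]["clean.prior"] = [0.9]
        payload["parameters"]["contaminated.prior"] = [0.9]
        p.write_text(json.dumps(payload))
        with pytest.raises(gbc.ModelFormatError):
            gbc.load_model(p)

    def test_wrong_format_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{}")
        with pytest.raises(gbc.ModelFormatError):
            gbc.load_model(p)
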