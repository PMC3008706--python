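"""Feature computation, Gaussian class training and the ML classifier."""

import numpy as np
import pytest
from scipy import stats

from blobslice.shape_model import (
    LOG_EPS,
    ShapeModel,
    classify,
    compute_features,
    find_intervening,
    generate_training_candidates,
    load_model,
    read_worksheet,
    save_model,
    train_model,
    worksheet_to_examples,
    write_worksheet,
)
from blobslice.slices import NuclearSlice


def make_slice(sid, cy, cx, plane, radius=4.0, intensity=100.0):
    return NuclearSlice(
        id=sid,
        center=(float(cy), float(cx)),
        plane=plane,
        ray_endpoints=[],
        polygon_area=np.pi * radius**2,
        equivalent_radius=radius,
        mean_intensity=intensity,
        peak_response=10.0,
    )


def features_oracle(cand, cen, iv):
    """Independent re-statement of the 7 feature definitions."""
    def lr(a, b):
        return np.log(max(a, LOG_EPS) / max(b, LOG_EPS))

    return np.array(
        [
            cand.plane - cen.plane,
            np.hypot(cand.center[0] - cen.center[0], cand.center[1] - cen.center[1])
            / cen.equivalent_radius,
            lr(cand.equivalent_radius, cen.equivalent_radius),
            lr(cand.mean_intensity, cen.mean_intensity),
            np.hypot(cand.center[0] - iv.center[0], cand.center[1] - iv.center[1])
            / iv.equivalent_radius,
            lr(cand.equivalent_radius, iv.equivalent_radius),
            lr(cand.mean_intensity, iv.mean_intensity),
        ]
    )


class TestComputeFeatures:
    def test_identical_adjacent_candidate_is_pure_z_offset(self):
        cen = make_slice(0, 10, 10, 5)
        cand = make_slice(1, 10, 10, 6)
        f = compute_features(cand, cen, cen)
        np.testing.assert_allclose(f, [1, 0, 0, 0, 0, 0, 0], atol=1e-12)

    def test_half_radius_candidate(self):
        cen = make_slice(0, 10, 10, 5, radius=4.0)
        cand = make_slice(1, 10, 10, 4, radius=2.0)
        f = compute_features(cand, cen, cen)
        np.testing.assert_allclose(
            f, [-1, 0, np.log(0.5), 0, 0, np.log(0.5), 0], atol=1e-12
        )

    def test_adjacent_duplicates_center_relative_block(self, rng):
        """With intervening == center, d5..d7 equal d2..d4."""
        for _ in range(20):
            cen = make_slice(0, *rng.uniform(5, 15, 2), 5, rng.uniform(2, 6), rng.uniform(50, 150))
            cand = make_slice(
                1, *rng.uniform(5, 15, 2), 6, rng.uniform(2, 6), rng.uniform(50, 150)
            )
            f = compute_features(cand, cen, cen)
            np.testing.assert_allclose(f[4:7], f[1:4], atol=1e-12)

    def test_matches_independent_formula(self, rng):
        for _ in range(50):
            cen = make_slice(0, *rng.uniform(0, 30, 2), 5, rng.uniform(1, 8), rng.uniform(10, 200))
            iv = make_slice(1, *rng.uniform(0, 30, 2), 6, rng.uniform(1, 8), rng.uniform(10, 200))
            cand = make_slice(2, *rng.uniform(0, 30, 2), 7, rng.uniform(1, 8), rng.uniform(10, 200))
            np.testing.assert_allclose(
                compute_features(cand, cen, iv), features_oracle(cand, cen, iv), rtol=1e-12
            )

    def test_same_plane_rejected(self):
        s = make_slice(0, 5, 5, 3)
        with pytest.raises(ValueError):
            compute_features(s, make_slice(1, 6, 6, 3), s)

    def test_intensity_rescaling_only_moves_nothing(self, rng):
        """Features use intensity ratios, so common rescaling cancels."""
        cen = make_slice(0, 10, 10, 5, 4.0, 80.0)
        iv = make_slice(1, 11, 10, 6, 3.5, 70.0)
        cand = make_slice(2, 12, 10, 7, 3.0, 60.0)
        f1 = compute_features(cand, cen, iv)
        for s in (cen, iv, cand):
            s.mean_intensity *= 13.7
        f2 = compute_features(cand, cen, iv)
        np.testing.assert_allclose(f1, f2, rtol=1e-12)


class TestFindIntervening:
    def test_adjacent_returns_center(self):
        cen = make_slice(0, 10, 10, 5)
        cand = make_slice(1, 10, 10, 6)
        assert find_intervening(cand, cen, {5: [cen], 6: [cand]}) is cen

    def test_picks_nearest_on_first_between_plane(self):
        cen = make_slice(0, 10, 10, 4)
        near = make_slice(1, 10, 11, 6)
        far = make_slice(2, 20, 20, 6)
        cand = make_slice(3, 10, 10, 7)
        by_plane = {4: [cen], 6: [near, far], 7: [cand]}
        assert find_intervening(cand, cen, by_plane) is near


def _two_class_draws(rng, n, mu_m, mu_d, cov_m=None, cov_d=None):
    dim = len(mu_m)
    cov_m = np.eye(dim) * 0.5 if cov_m is None else cov_m
    cov_d = np.eye(dim) * 0.5 if cov_d is None else cov_d
    xm = rng.multivariate_normal(mu_m, cov_m, size=n)
    xd = rng.multivariate_normal(mu_d, cov_d, size=n)
    return [(x, "member") for x in xm] + [(x, "distractor") for x in xd]


class TestTrainModel:
    def test_parameter_recovery_from_known_gaussian(self, rng):
        """Sample means land within 3 SE, covariance within 15% Frobenius."""
        mu_m = np.array([0.0, 0.2, -0.1, 0.0, 0.3, -0.2, 0.1])
        mu_d = mu_m + 1.5
        A = rng.uniform(-0.3, 0.3, (7, 7))
        cov = 0.6 * np.eye(7) + A @ A.T
        ex = _two_class_draws(rng, 500, mu_m, mu_d, cov, cov)
        m = train_model(ex, regularization=0.0)
        se = np.sqrt(np.diag(cov) / 500)
        assert np.all(np.abs(m.member_mean - mu_m) < 3 * se)
        assert np.all(np.abs(m.distractor_mean - mu_d) < 3 * se)
        for est in (m.member_cov, m.distractor_cov):
            rel = np.linalg.norm(est - cov) / np.linalg.norm(cov)
            assert rel < 0.15

    def test_convergence_rate(self, rng):
        """Mean error shrinks roughly as 1/sqrt(n)."""
        mu = np.zeros(7)
        errs = []
        for n in (100, 1000, 10000):
            ex = _two_class_draws(rng, n, mu, mu + 1.0)
            m = train_model(ex, regularization=0.0)
            errs.append(np.linalg.norm(m.member_mean - mu))
        assert errs[2] < errs[0]
        assert errs[2] < 3 * errs[0] / np.sqrt(100)

    def test_label_swap_swaps_models(self, rng):
        ex = _two_class_draws(rng, 50, np.zeros(7), np.ones(7))
        swapped = [(f, "distractor" if l == "member" else "member") for f, l in ex]
        m1 = train_model(ex)
        m2 = train_model(swapped)
        np.testing.assert_allclose(m1.member_mean, m2.distractor_mean)
        np.testing.assert_allclose(m1.member_cov, m2.distractor_cov)
        assert m1.priors[0] == pytest.approx(m2.priors[1])

    def test_insufficient_class_named(self, rng):
        ex = _two_class_draws(rng, 50, np.zeros(7), np.ones(7))
        ex = [e for e in ex if e[1] == "member"] + [e for e in ex if e[1] == "distractor"][:3]
        with pytest.raises(ValueError, match="distractor"):
            train_model(ex)

    def test_degenerate_duplicates_yield_ridge_only_covariance(self):
        f = np.arange(7.0)
        ex = [(f, "member")] * 2 + [(f + 1, "distractor")] * 2
        m = train_model(ex, regularization=1e-4, min_examples=2)
        np.testing.assert_allclose(m.member_cov, 1e-4 * np.eye(7), atol=1e-12)

    def test_priors_follow_frequencies_and_override(self, rng):
        ex = _two_class_draws(rng, 30, np.zeros(7), np.ones(7))
        ex += [e for e in ex if e[1] == "member"][:10]
        m = train_model(ex)
        assert m.priors[0] == pytest.approx(40 / 70)
        m2 = train_model(ex, priors=(0.5, 0.5))
        assert m2.priors == (0.5, 0.5)


class TestClassify:
    def _sym_model(self, delta=2.0):
        mu = np.zeros(7)
        return ShapeModel(
            member_mean=mu,
            member_cov=np.eye(7),
            distractor_mean=mu + delta / np.sqrt(7),
            distractor_cov=np.eye(7),
        )

    def test_class_means_classified_correctly(self):
        m = self._sym_model()
        label, lo = classify(m.member_mean, m)
        assert label == "member" and lo > 0
        label2, lo2 = classify(m.distractor_mean, m)
        assert label2 == "distractor" and lo2 < 0

    def test_tie_resolves_to_distractor(self):
        m = self._sym_model()
        midpoint = (m.member_mean + m.distractor_mean) / 2
        label, lo = classify(midpoint, m)
        assert lo == pytest.approx(0.0, abs=1e-12)
        assert label == "distractor"

    def test_log_odds_antisymmetric_under_class_swap(self, rng):
        m = self._sym_model()
        swapped = ShapeModel(
            member_mean=m.distractor_mean,
            member_cov=m.distractor_cov,
            distractor_mean=m.member_mean,
            distractor_cov=m.member_cov,
        )
        for _ in range(20):
            f = rng.standard_normal(7)
            assert classify(f, m)[1] == pytest.approx(-classify(f, swapped)[1])

    def test_monte_carlo_accuracy_matches_bayes(self, rng):
        """Equal-covariance two-Gaussian accuracy is Phi(Delta/2)."""
        delta = 1.8
        mu_m = np.zeros(7)
        mu_d = np.full(7, delta / np.sqrt(7))
        model = ShapeModel(
            member_mean=mu_m,
            member_cov=np.eye(7),
            distractor_mean=mu_d,
            distractor_cov=np.eye(7),
        )
        n = 10000
        xm = rng.multivariate_normal(mu_m, np.eye(7), size=n)
        xd = rng.multivariate_normal(mu_d, np.eye(7), size=n)
        # vectorized log odds (same quantity classify computes pointwise)
        lm = stats.multivariate_normal.logpdf(np.vstack([xm, xd]), mu_m, np.eye(7))
        ld = stats.multivariate_normal.logpdf(np.vstack([xm, xd]), mu_d, np.eye(7))
        lo = lm - ld
        acc = (np.sum(lo[:n] > 0) + np.sum(lo[n:] <= 0)) / (2 * n)
        bayes = stats.norm.cdf(delta / 2)
        assert acc == pytest.approx(bayes, abs=0.02)
        # spot check the scalar path agrees with the vectorized one
        lab, lo0 = classify(xm[0], model)
        assert lo0 == pytest.approx(lo[0])


class TestWorksheet:
    def test_candidates_near_seed_and_round_trip(self, tmp_path):
        cen = make_slice(0, 20, 20, 5, 4.0)
        members = [make_slice(1, 20, 20, 6, 3.5), make_slice(2, 20, 21, 4, 3.2)]
        stranger = make_slice(3, 90, 90, 6, 4.0)
        slices = [cen, *members, stranger]

        class Cfg:
            candidate_z_window = 3

        rows = generate_training_candidates(slices, [cen], Cfg())
        assert {r["candidate_slice_id"] for r in rows} == {1, 2}
        write_worksheet(rows, tmp_path / "w.csv")
        back = read_worksheet(tmp_path / "w.csv")
        assert back == rows
        ex = worksheet_to_examples(back, slices)
        assert len(ex) == 2 and all(l == "member" for _, l in ex)

    def test_seed_with_no_neighbors_empty_block(self):
        lone = make_slice(0, 50, 50, 5, 4.0)

        class Cfg:
            candidate_z_window = 3

        assert generate_training_candidates([lone], [lone], Cfg()) == []


class TestSerialization:
    def test_json_round_trip(self, tmp_path, rng):
        ex = _two_class_draws(rng, 40, np.zeros(7), np.ones(7))
        m = train_model(ex)
        save_model(m, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        np.testing.assert_allclose(back.member_mean, m.member_mean)
        np.testing.assert_allclose(back.distractor_cov, m.distractor_cov)
        assert back.priors == m.priors
        assert back.n_training == m.n_training

    def test_retraining_identical_data_identical_file(self, tmp_path, rng):
        ex = _two_class_draws(rng, 40, np.zeros(7), np.ones(7))
        save_model(train_model(ex), tmp_path / "a.json")
        save_model(train_model(ex), tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
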