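"""Filter correctness: textbook-oracle equivalence, the adaptive noise law,
and center smoothing."""

import numpy as np
import pytest

from cehd import adaptive_kalman as ak
from cehd.detection import Detection


def det(cx=10.0, cy=20.0, a=0.5, h=40.0, conf=0.9):
    return Detection(frame=0, box=(cx, cy, a, h), confidence=conf)


class TextbookKalman:
    """Independent dense-matrix reference: plain inv()-based equations,
    no Joseph form, no solve()."""

    def __init__(self, F, H, mean, cov):
        self.F, self.H = F, H
        self.mean, self.cov = mean.copy(), cov.copy()

    def predict(self, Q):
        self.mean = self.F @ self.mean
        self.cov = self.F @ self.cov @ self.F.T + Q

    def update(self, z, R):
        P, H = self.cov, self.H
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        self.mean = self.mean + K @ (z - H @ self.mean)
        self.cov = (np.eye(len(self.mean)) - K @ H) @ P


class TestInitiate:
    def test_mean_from_detection_with_zero_velocity(self):
        state = ak.initiate(det(), ak.FilterParams())
        assert np.allclose(state.mean, [10, 20, 0.5, 40, 0, 0, 0, 0])
        assert state.smoothed_center == (10.0, 20.0)

    def test_covariance_symmetric_positive_definite(self):
        state = ak.initiate(det(h=13.0), ak.FilterParams())
        assert np.allclose(state.covariance, state.covariance.T)
        assert np.linalg.eigvalsh(state.covariance).min() > 0

    def test_deterministic(self):
        p = ak.FilterParams()
        a, b = ak.initiate(det(), p), ak.initiate(det(), p)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.covariance, b.covariance)


class TestPredict:
    def test_zero_velocity_leaves_position(self):
        p = ak.FilterParams()
        state = ak.initiate(det(), p)
        out = ak.predict(state, p)
        assert np.allclose(out.mean[:4], state.mean[:4])

    def test_constant_velocity_propagation(self):
        p = ak.FilterParams()
        state = ak.TrackState(
            np.array([0.0, 0.0, 1.0, 10.0, 1.0, 0.0, 0.0, 0.0]),
            np.eye(8),
            (0.0, 0.0),
        )
        out = ak.predict(state, p)
        assert np.allclose(out.mean, [1, 0, 1, 10, 1, 0, 0, 0])

    def test_covariance_matches_dense_oracle(self):
        rng = np.random.default_rng(0)
        p = ak.FilterParams()
        for _ in range(100):
            A = rng.normal(size=(8, 8))
            cov = A @ A.T + 1e-3 * np.eye(8)
            mean = rng.normal(size=8)
            mean[3] = abs(mean[3]) + 5.0
            state = ak.TrackState(mean, cov, (0.0, 0.0))
            out = ak.predict(state, p)
            expected = p.F @ cov @ p.F.T + p.process_noise(mean[3])
            assert np.allclose(out.covariance, 0.5 * (expected + expected.T),
                               atol=1e-12)
            assert np.trace(out.covariance) >= np.trace(p.F @ cov @ p.F.T) - 1e-9


class TestAdaptiveNoise:
    def test_hand_values_at_full_confidence(self):
        p = ak.FilterParams(w=0.05, eps=0.01)
        R = ak.adaptive_noise(1.0, 100.0, p)
        std = np.sqrt(np.diag(R))
        assert std == pytest.approx([0.05, 1.0, 0.05, 0.05], abs=1e-12)

    def test_hand_values_at_zero_confidence(self):
        p = ak.FilterParams(w=0.05, eps=0.01)
        std = np.sqrt(np.diag(ak.adaptive_noise(0.0, 100.0, p)))
        assert std == pytest.approx([5.0, 5.0, 0.1, 5.0], abs=1e-12)

    @pytest.mark.parametrize("c", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_unit_grid_matches_closed_form(self, c):
        w, eps, h = 0.05, 0.01, 100.0
        p = ak.FilterParams(w=w, eps=eps)
        std = np.sqrt(np.diag(ak.adaptive_noise(c, h, p)))
        expected = [
            max(1 - c, eps) * w * h,
            max(1 - 0.8 * c, eps) * w * h,
            max(1 - 0.5 * c, eps) * 0.1,
            max(1 - c, eps) * w * h,
        ]
        assert std == pytest.approx(expected, abs=1e-12)

    def test_every_sigma_non_increasing_in_confidence(self):
        p = ak.FilterParams()
        grid = [np.sqrt(np.diag(ak.adaptive_noise(c, 80.0, p)))
                for c in np.linspace(0, 1, 21)]
        diffs = np.diff(np.stack(grid), axis=0)
        assert np.all(diffs <= 1e-12)

    def test_out_of_range_confidence_clipped_with_warning(self):
        p = ak.FilterParams()
        with pytest.warns(UserWarning):
            R = ak.adaptive_noise(1.2, 100.0, p)
        assert np.allclose(R, ak.adaptive_noise(1.0, 100.0, p))


class TestUpdate:
    def test_zero_innovation_keeps_mean(self):
        p = ak.FilterParams()
        state = ak.predict(ak.initiate(det(), p), p)
        z = p.H @ state.mean
        out = ak.update(state, z, np.eye(4), p)
        assert np.allclose(out.mean, state.mean, atol=1e-9)

    def test_infinite_noise_is_zero_gain(self):
        p = ak.FilterParams()
        state = ak.predict(ak.initiate(det(), p), p)
        out = ak.update(state, np.array([50.0, 50.0, 1.0, 60.0]),
                        1e12 * np.eye(4), p)
        assert np.allclose(out.mean, state.mean, atol=1e-6)

    def test_unit_innovation_covariance_gain_half(self):
        p = ak.FilterParams()
        # construct P with H P H^T = I
        cov = np.eye(8)
        state = ak.TrackState(np.zeros(8), cov, (0.0, 0.0))
        state.mean[3] = 10.0
        z = p.H @ state.mean + np.array([1.0, 0.0, 0.0, 0.0])
        out = ak.update(state, z, np.eye(4), p)
        assert out.mean[0] == pytest.approx(0.5, abs=1e-12)

    def test_reliable_detection_pulls_harder(self):
        """c=1 moves the posterior strictly closer to the observation than
        c=0 from the same prior."""
        p = ak.FilterParams()
        state = ak.predict(ak.initiate(det(), p), p)
        z = np.array([14.0, 26.0, 0.55, 44.0])
        h_prev = 40.0
        post_hi = ak.update(state, z, ak.adaptive_noise(1.0, h_prev, p), p)
        post_lo = ak.update(state, z, ak.adaptive_noise(0.0, h_prev, p), p)
        d_hi = np.linalg.norm(post_hi.mean[:4] - z)
        d_lo = np.linalg.norm(post_lo.mean[:4] - z)
        assert d_hi < d_lo


class TestOracleEquivalence:
    def test_constant_r_matches_textbook_over_200_cycles(self):
        """With a fixed R the mean/covariance sequence equals the plain
        textbook implementation to 1e-10 throughout."""
        rng = np.random.default_rng(42)
        p = ak.FilterParams()
        state = ak.initiate(det(cx=100, cy=100, a=0.5, h=50), p)
        oracle = TextbookKalman(p.F, p.H, state.mean, state.covariance)
        R = p.fixed_observation_noise(50.0)
        for _ in range(200):
            h = float(state.mean[3])
            Q = p.process_noise(h)
            state = ak.predict(state, p)
            oracle.predict(Q)
            z = p.H @ state.mean + rng.normal(0, 1.0, size=4)
            z[2] = abs(z[2]) + 0.1
            z[3] = abs(z[3]) + 5.0
            state = ak.update(state, z, R, p)
            oracle.update(z, R)
            assert np.allclose(state.mean, oracle.mean, atol=1e-10)
            assert np.allclose(state.covariance, oracle.cov, atol=1e-10)

    def test_covariance_stays_spd_over_1000_cycles(self):
        rng = np.random.default_rng(1)
        p = ak.FilterParams()
        state = ak.initiate(det(cx=50, cy=50, h=40), p)
        for i in range(1000):
            state = ak.predict(state, p)
            z = p.H @ state.mean + rng.normal(0, 2.0, size=4)
            z[2], z[3] = max(z[2], 0.1), max(z[3], 5.0)
            R = ak.adaptive_noise(float(rng.uniform(0, 1)), float(state.mean[3]), p)
            state = ak.update(state, z, R, p)
            cov = state.covariance
            assert np.allclose(cov, cov.T, atol=1e-9)
            assert np.linalg.eigvalsh(cov).min() > 0


class TestSmoothing:
    def test_alpha_zero_is_identity(self):
        assert ak.smooth_center((1.0, 2.0), (5.0, 6.0), 0.0) == (5.0, 6.0)

    def test_alpha_one_freezes(self):
        assert ak.smooth_center((1.0, 2.0), (5.0, 6.0), 1.0) == (1.0, 2.0)

    def test_alpha_half_is_midpoint(self):
        assert ak.smooth_center((2.0, 0.0), (4.0, 2.0), 0.5) == (3.0, 1.0)

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.7])
    def test_smoothing_reduces_variance_on_static_track(self, alpha):
        """Smoothed centers have lower variance than raw posterior centers
        for a static target with i.i.d. observation noise."""
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            p = ak.FilterParams(alpha=alpha)
            state = ak.initiate(det(cx=100, cy=100, h=50), p)
            raw, smoothed = [], []
            for _ in range(60):
                z = det(
                    cx=100 + rng.normal(0, 2), cy=100 + rng.normal(0, 2),
                    h=50.0, conf=0.9,
                )
                state = ak.step(state, z, p)
                raw.append(state.mean[:2].copy())
                smoothed.append(state.smoothed_center)
            var_raw = np.var(np.array(raw), axis=0).sum()
            var_smooth = np.var(np.array(smoothed), axis=0).sum()
            if var_smooth < var_raw:
                wins += 1
        assert wins >= 48


class TestStep:
    def test_missing_detection_is_predict_only(self):
        p = ak.FilterParams()
        state = ak.initiate(det(), p)
        out = ak.step(state, None, p)
        expected = ak.predict(state, p)
        assert np.allclose(out.mean, expected.mean)
        assert out.smoothed_center == state.smoothed_center

    def test_high_confidence_track_converges_to_observations(self):
        p = ak.FilterParams(alpha=0.0)
        state = ak.initiate(det(cx=0, cy=0, a=0.5, h=40, conf=1.0), p)
        target = det(cx=20, cy=10, a=0.5, h=40, conf=1.0)
        for _ in range(10):
            state = ak.step(state, target, p)
        assert np.allclose(state.mean[:4], target.measurement, rtol=0.05)

    def test_deterministic(self):
        p = ak.FilterParams()
        s1 = ak.initiate(det(), p)
        s2 = ak.initiate(det(), p)
        obs = det(cx=11, cy=21, conf=0.7)
        for _ in range(5):
            s1 = ak.step(s1, obs, p)
            s2 = ak.step(s2, obs, p)
        assert np.array_equal(s1.mean, s2.mean)
        assert np.array_equal(s1.covariance, s2.covariance)
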