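"""PWM creation, constraint transform, inversion, counting, standardisation."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from repfam.align import AlignmentTrace
from repfam.pwm import (FrequencyMatrix, PWM, PWMConfig, accumulate_MAT,
                        background_p1, dinucleotide_row, invert_pwm,
                        load_pwm, random_pwm, save_pwm, standardize_M,
                        transform_pwm)


class TestConfig:
    def test_defaults_mirror_operating_point(self):
        cfg = PWMConfig()
        assert (cfg.L, cfg.window, cfg.step) == (600, 650, 10)
        assert cfg.R0_sq == 300.0 * 600
        assert (cfg.Z0_first, cfg.Z0_iter) == (3.0, 5.0)
        assert (cfg.n_iterations, cfg.n_random_matrices) == (20, 50)
        assert (cfg.N_min, cfg.fdr_max) == (300, 0.04)

    def test_validation(self):
        with pytest.raises(ValueError):
            PWMConfig(L=1)
        with pytest.raises(ValueError):
            PWMConfig(L=100, window=50)

    def test_gap_scale(self):
        cfg = PWMConfig(L=100, window=120)
        assert cfg.gap_abs == pytest.approx(cfg.gap_penalty * np.sqrt(300.0))


class TestRandomPWM:
    def test_bounds_and_moments(self, rng):
        raw = random_pwm(PWMConfig(), rng)
        assert raw.shape == (16, 600)
        assert raw.min() >= -10 and raw.max() <= 10
        # uniform(-10, 10): mean 0, sem = (20/sqrt(12))/sqrt(9600) ~ 0.06
        assert abs(raw.mean()) < 0.3

    def test_seeded_determinism(self):
        cfg = PWMConfig()
        a = random_pwm(cfg, np.random.default_rng(7))
        b = random_pwm(cfg, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestTransform:
    def test_constraints_hold(self, rng, uniform_p1):
        cfg = PWMConfig()
        raw = random_pwm(cfg, rng)
        mt = transform_pwm(raw, uniform_p1, cfg.R0_sq, cfg.K0)
        assert mt.weighted_mean() == pytest.approx(cfg.K0, abs=1e-9)
        assert mt.centered_norm_sq(cfg.K0) == pytest.approx(
            cfg.R0_sq, rel=1e-9)

    def test_idempotent_and_fixed_point(self, rng, uniform_p1):
        cfg = PWMConfig(L=50, window=60)
        mt = transform_pwm(random_pwm(cfg, rng), uniform_p1, cfg.R0_sq, cfg.K0)
        again = transform_pwm(mt.weights, uniform_p1, cfg.R0_sq, cfg.K0)
        assert np.allclose(mt.weights, again.weights, atol=1e-9)

    def test_matches_independent_root_solve(self, rng, uniform_p1):
        """Cross-check the closed-form affine map against a numeric solve of
        the two-constraint system for a small matrix."""
        raw = rng.uniform(-10, 10, size=(16, 2))
        R0_sq, K0 = 300.0 * 2, -1.0
        p2 = 0.5

        def equations(ab):
            a, b = ab
            m = a * raw + b
            K = float((uniform_p1[:, None] * p2 * m).sum())
            return [K - K0, ((m - K0) ** 2).sum() - R0_sq]

        a, b = fsolve(equations, x0=[1.0, 0.0], full_output=False)
        expected = a * raw + b
        got = transform_pwm(raw, uniform_p1, R0_sq, K0).weights
        assert np.allclose(got, expected, atol=1e-6)

    def test_constant_matrix_rejected(self, uniform_p1):
        with pytest.raises(ValueError):
            transform_pwm(np.full((16, 10), 3.0), uniform_p1, 3000.0, -1.0)


class TestInvert:
    def test_involution(self, rng, uniform_p1):
        cfg = PWMConfig(L=20, window=30)
        mt = transform_pwm(random_pwm(cfg, rng), uniform_p1, cfg.R0_sq, cfg.K0)
        back = invert_pwm(invert_pwm(mt))
        assert np.array_equal(back.weights, mt.weights)
        assert np.array_equal(back.p1, mt.p1)

    def test_row_mapping(self, rng):
        # non-uniform p1 so row moves are observable
        f = np.array([0.1, 0.2, 0.3, 0.4])
        pwm = PWM(weights=rng.normal(size=(16, 3)), p1=background_p1(f))
        inv = invert_pwm(pwm)
        # 'at' (a=0 prev, t=1 cur -> row 4) is its own reverse complement
        assert inv.weights[4, 0] == pwm.weights[4, 2]
        # 'aa' (row 0) <-> 'tt' (row 5)
        assert inv.weights[5, 0] == pwm.weights[0, 2]
        assert inv.weights[0, 0] == pwm.weights[5, 2]
        # p1 mass conserved under remapping
        assert inv.p1.sum() == pytest.approx(1.0)

    def test_row_index_formula(self):
        # printed map: let(a,t,c,g)=(1,2,3,4); n = let(prev) + 4*(let(cur)-1)
        # 0-based codes a,t,c,g = 0..3 give row = n-1
        assert dinucleotide_row(0, 1) == 4   # 'at' -> n=5
        assert dinucleotide_row(3, 3) == 15  # 'gg' -> n=16
        assert dinucleotide_row(1, 1) == 5   # 'tt' -> n=6


def _trace(s1, s2):
    return AlignmentTrace(np.asarray(s1, dtype=np.int64),
                          np.asarray(s2, dtype=np.int64), score=1.0)


class TestAccumulateMAT:
    def test_perfect_three_base_trace(self):
        # s1 = (a, c, g), s2 = (1, 2, 3): first position contributes nothing
        freq = accumulate_MAT([_trace([0, 2, 3], [1, 2, 3])], L=3)
        expected = np.zeros((16, 3))
        expected[dinucleotide_row(0, 2), 1] = 1  # (a,c) at column 2
        expected[dinucleotide_row(2, 3), 2] = 1  # (c,g) at column 3
        assert np.array_equal(freq.MAT, expected)
        assert freq.N == 2

    def test_deletion_skips_neighbours(self):
        # deletion at s1(2): positions 2 and 3 both lack a full context pair
        freq = accumulate_MAT([_trace([0, -1, 3, 1], [1, 2, 3, 4])], L=4)
        expected = np.zeros((16, 4))
        expected[dinucleotide_row(3, 1), 3] = 1  # only (g,t) at column 4
        assert np.array_equal(freq.MAT, expected)

    def test_profile_deletion_skips_position(self):
        freq = accumulate_MAT([_trace([0, 2, 3], [1, -1, 3])], L=3)
        assert freq.MAT[:, 1].sum() == 0
        # (c,g) at column 3 still counted: s1(i-1), s1(i), s2(i) all real
        assert freq.MAT[dinucleotide_row(2, 3), 2] == 1

    def test_empty(self):
        freq = accumulate_MAT([], L=5)
        assert freq.N == 0

    def test_bad_column_raises(self):
        with pytest.raises(ValueError):
            accumulate_MAT([_trace([0, 1], [1, 9])], L=3)


class TestStandardize:
    def test_constant_counts_give_zero(self):
        freq = FrequencyMatrix(np.full((16, 5), 3.0))
        assert np.allclose(standardize_M(freq), 0.0)

    def test_two_by_two_hand_arithmetic(self):
        """Counts [[3,1],[1,3]] embedded in rows 1-2: frozen hand evaluation
        of the standardised deviate (3-2)/sqrt(8*.25*.75) = 0.8164966."""
        mat = np.zeros((16, 2))
        mat[0] = [3, 1]
        mat[1] = [1, 3]
        M = standardize_M(FrequencyMatrix(mat))
        v = 0.816496580927726
        assert M[0, 0] == pytest.approx(v)
        assert M[0, 1] == pytest.approx(-v)
        assert M[1, 0] == pytest.approx(-v)
        assert M[1, 1] == pytest.approx(v)
        assert np.allclose(M[2:], 0.0)

    def test_multinomial_null_moments(self, rng):
        """Under independent margins the standardised matrix has mean ~0 and
        variance ~1 (slightly deflated by margin estimation)."""
        L, N = 50, 20000
        p = np.full(16 * L, 1.0 / (16 * L))
        vals = []
        for _ in range(30):
            counts = rng.multinomial(N, p).reshape(16, L).astype(float)
            vals.append(standardize_M(FrequencyMatrix(counts)))
        vals = np.stack(vals)
        assert abs(vals.mean()) < 0.05
        assert 0.8 < vals.var() < 1.1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            standardize_M(FrequencyMatrix(np.zeros((16, 3))))

    def test_zero_weighted_residual(self, rng):
        """sum over cells of sqrt(N p (1-p)) * M equals sum(MAT - N p) = 0."""
        counts = rng.multinomial(5000, np.full(160, 1 / 160.0)).reshape(16, 10)
        freq = FrequencyMatrix(counts.astype(float))
        M = standardize_M(freq)
        p = np.outer(freq.x, freq.y) / freq.N**2
        resid = (M * np.sqrt(freq.N * p * (1 - p))).sum()
        assert resid == pytest.approx(0.0, abs=1e-8)


class TestSerialization:
    def test_roundtrip(self, tmp_path, rng, uniform_p1):
        cfg = PWMConfig(L=10, window=20)
        mt = transform_pwm(random_pwm(cfg, rng), uniform_p1, cfg.R0_sq, cfg.K0)
        path = tmp_path / "m.pwm"
        save_pwm(mt, path, meta={"family": 3})
        loaded, header = load_pwm(path)
        assert header["family"] == 3
        assert np.allclose(loaded.weights, mt.weights)
        assert np.allclose(loaded.p1, mt.p1)
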