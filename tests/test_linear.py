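"""Linearization and collective-mode analysis against algebraic oracles."""

import numpy as np
import pytest
from scipy import sparse, stats

from famcirc import circuit as cc
from famcirc import linear as ln


def _random_linearization(rng, n_exc=10, spectral=0.5):
    """Construct a Linearization directly from a random stable stacked system."""
    n = 2 * n_exc
    W = rng.standard_normal((n, n)) / np.sqrt(n)
    s = rng.uniform(0.1, 1.5, n)
    A = np.eye(n) - s[:, None] * W
    # rescale until well conditioned and invertible
    while np.linalg.cond(A) > 1e6:
        W *= spectral
        A = np.eye(n) - s[:, None] * W
    M = np.linalg.solve(A, np.eye(n))
    return ln.Linearization(sigma_prime=s, M=M, J=M * s[None, :], W=W,
                            n_exc=n_exc)


def _toy_conn(w_ee, w_ie, n):
    cfg = cc.NetworkConfig(n_rows=1, n_cols=1, n_channels=n, radius_e=0,
                           radius_i=0, w_ie=1.0)
    return cc.Connectivity(
        w_ee=np.asarray(w_ee, dtype=float),
        mask_ee=np.asarray(w_ee) != 0,
        w_ie=sparse.csr_matrix(np.asarray(w_ie, dtype=float)),
        w_ei=-1.0 / n,
        config=cfg,
        ne_sizes=np.full(n, n),
    )


class TestLinearize:
    def test_zero_attractor_gives_zero_jacobian(self):
        conn = _toy_conn(np.zeros((2, 2)), np.zeros((2, 2)), 2)
        lin = ln.linearize(conn, np.zeros(2), np.zeros(2))
        assert not lin.J.any()
        assert not lin.sigma_prime.any()

    def test_internal_identities(self):
        W = np.array([[0.0, 0.1], [0.05, 0.0]])
        conn = _toy_conn(W, np.zeros((2, 2)), 2)
        alpha = np.array([0.6, 0.4])
        rec = cc.run_to_fixed_point(conn, alpha, conn.config, max_T=5000,
                                    tol=1e-12)
        lin = ln.linearize(conn, rec.r_star, alpha)
        n = 4
        A = np.eye(n) - lin.sigma_prime[:, None] * lin.W
        np.testing.assert_allclose(A @ lin.M, np.eye(n), atol=1e-8)
        np.testing.assert_allclose(lin.J, lin.M * lin.sigma_prime[None, :],
                                   atol=1e-12)

    def test_finite_difference_jacobian(self):
        """||r*(a + e d) - r*(a) - e J_e d|| = O(e^2) on a 2-neuron toy."""
        W = np.array([[0.0, 0.12], [0.08, 0.0]])
        conn = _toy_conn(W, np.zeros((2, 2)), 2)
        alpha = np.array([0.7, 0.5])
        rec = cc.run_to_fixed_point(conn, alpha, conn.config, max_T=8000,
                                    tol=1e-13)
        lin = ln.linearize(conn, rec.r_star, alpha)
        J_e = lin.jacobian_exc()
        d = np.array([1.0, -0.5])
        errs = []
        for eps in (1e-3, 1e-4):
            pert = cc.run_to_fixed_point(conn, alpha + eps * d, conn.config,
                                         max_T=8000, tol=1e-13)
            errs.append(
                np.linalg.norm(pert.r_star - rec.r_star - eps * (J_e @ d))
            )
        # quadratic error decay in eps
        assert errs[1] < errs[0] / 50

    def test_singular_system_raises(self):
        lin_W = np.array([[1.0, 0.0], [0.0, 1.0]])
        conn = _toy_conn(lin_W, np.zeros((2, 2)), 2)
        # attractor with sigma' * W == I makes (I - S W) singular
        r_star = np.array([0.25, 0.25])  # z = 0.5, sigma' = 1
        alpha = 0.5 - lin_W @ r_star
        with pytest.raises(ln.IllConditionedLinearization):
            ln.linearize(conn, r_star, alpha)


class TestGainModes:
    def test_symmetric_m_real_spectrum_orthonormal_modes(self, rng):
        lin = _random_linearization(rng, n_exc=6)
        lin.M = 0.5 * (lin.M + lin.M.T)
        gm = ln.gain_modes(lin)
        assert np.allclose(gm.mu.imag, 0.0, atol=1e-10)
        np.testing.assert_allclose(
            np.abs(np.einsum("ij,ij->j", gm.v.conj(), gm.w)), 1.0, atol=1e-8
        )

    def test_scalar_matrix_has_constant_spectrum(self):
        lin = ln.Linearization(
            sigma_prime=np.ones(4), M=2.5 * np.eye(4), J=2.5 * np.eye(4),
            W=np.zeros((4, 4)), n_exc=2,
        )
        gm = ln.gain_modes(lin)
        np.testing.assert_allclose(gm.mu, 2.5)

    def test_reconstruction_from_modes(self, rng):
        lin = _random_linearization(rng, n_exc=8)
        gm = ln.gain_modes(lin)
        rebuilt = (gm.w * gm.mu[None, :]) @ gm.v.conj().T
        np.testing.assert_allclose(rebuilt.real, lin.M, atol=1e-8)
        np.testing.assert_allclose(rebuilt.imag, 0.0, atol=1e-8)


class TestCollectiveModes:
    def test_gram_psd_and_sorted(self, rng):
        cms = ln.collective_modes(ln.gain_modes(_random_linearization(rng)))
        assert (cms.lam >= -1e-10).all()
        assert (np.diff(cms.lam) <= 1e-12).all()

    def test_orthonormal_output_patterns_give_unit_spectrum(self):
        # M = c I on the full stack: w_i orthonormal, projection to the full
        # space gives G = I
        n = 6
        lin = ln.Linearization(
            sigma_prime=np.ones(n), M=1.7 * np.eye(n), J=1.7 * np.eye(n),
            W=np.zeros((n, n)), n_exc=n // 2,
        )
        cms = ln.collective_modes(ln.gain_modes(lin), project_exc=False)
        np.testing.assert_allclose(cms.lam, 1.0, atol=1e-10)

    def test_decomposition_exact_at_full_rank(self, rng):
        """Sum_k lam_k |phi_k^H da|^2 == ||P J [da; 0]||^2 (20-neuron systems)."""
        for _ in range(5):
            lin = _random_linearization(rng, n_exc=10)
            cms = ln.collective_modes(ln.gain_modes(lin))
            da = rng.standard_normal(10)
            lhs = float(cms.lam @ np.abs(cms.phi.conj().T @ da) ** 2)
            rhs = float(np.sum((lin.J[:10, :10] @ da) ** 2))
            assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_rank_one_m_has_single_mode(self, rng):
        u = rng.standard_normal(6)
        v = rng.standard_normal(6)
        lin = ln.Linearization(
            sigma_prime=np.ones(6), M=np.outer(u, v), J=np.outer(u, v),
            W=np.zeros((6, 6)), n_exc=3,
        )
        cms = ln.collective_modes(ln.gain_modes(lin), project_exc=False)
        assert (cms.lam > 1e-8).sum() == 1


class TestInputDeltas:
    @pytest.fixture()
    def codes(self, rng):
        codes = {}
        for tgt in (0, 1):
            codes[(0.0, tgt, 0)] = rng.standard_normal(5)
            for lvl in (0.1, 0.3):
                for k in (1, 2):
                    codes[(lvl, tgt, k)] = rng.standard_normal(5)
        return codes

    def test_unit_norms(self, codes):
        for cls in ("signal", "level", "residual"):
            deltas = ln.input_deltas(codes, cls)
            np.testing.assert_allclose(np.linalg.norm(deltas, axis=1), 1.0,
                                       rtol=1e-12)

    def test_identical_codes_dropped(self, rng):
        v = rng.standard_normal(4)
        codes = {(0.1, 0, 1): v, (0.1, 0, 2): v.copy(),
                 (0.1, 0, 3): rng.standard_normal(4)}
        deltas = ln.input_deltas(codes, "residual")
        # of the 6 ordered pairs, the two between the identical samples drop
        assert deltas.shape[0] == 4

    def test_pair_counts_match_enumeration(self, codes):
        # T=2 targets, levels {0, .1, .3}, K=2 samples
        # signal: noisy anchors pair with the other target's 2 same-level
        # samples (2 levels x 2 targets x 2 samples x 2 partners = 16); the
        # two clean anchors pair with each other (2)
        assert ln.input_deltas(codes, "signal").shape[0] == 16 + 2
        # level: anchors at .1 pair with clean (1), anchors at .3 pair with .1 (2)
        assert ln.input_deltas(codes, "level").shape[0] == 2 * 2 * 1 + 2 * 2 * 2
        # residual: within (lvl,tgt): 2 ordered pairs per cell, 4 cells
        assert ln.input_deltas(codes, "residual").shape[0] == 8

    def test_anchor_restriction(self, codes):
        deltas = ln.input_deltas(codes, "signal", anchor=(0.1, 0, 1))
        assert deltas.shape[0] == 2

    def test_empty_class_raises(self, rng):
        codes = {(0.0, 0, 0): rng.standard_normal(3)}
        with pytest.raises(ValueError):
            ln.input_deltas(codes, "signal")


class TestLinearizedDistance:
    def test_full_rank_equals_jacobian_norm(self, rng):
        lin = _random_linearization(rng, n_exc=8)
        cms = ln.collective_modes(ln.gain_modes(lin))
        deltas = rng.standard_normal((7, 8))
        deltas /= np.linalg.norm(deltas, axis=1, keepdims=True)
        got = ln.linearized_distance(cms, deltas, top_k=None)
        want = float(np.mean(
            [np.sum((lin.J[:8, :8] @ d) ** 2) for d in deltas]
        ))
        assert got == pytest.approx(want, rel=1e-8)

    def test_orthogonal_delta_contributes_nothing(self):
        lam = np.array([2.0, 1.0])
        phi = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        cms = ln.CollectiveModeSet(lam=lam, q=np.eye(2), phi=phi, n_exc=3)
        d = np.array([[0.0, 0.0, 1.0]])
        assert ln.linearized_distance(cms, d, top_k=2) == 0.0

    def test_three_mode_hand_computation(self):
        lam = np.array([3.0, 2.0, 0.5])
        phi = np.eye(3)
        cms = ln.CollectiveModeSet(lam=lam, q=np.eye(3), phi=phi, n_exc=3)
        d = np.array([[0.6, 0.8, 0.0]])
        want = 3.0 * 0.36 + 2.0 * 0.64
        assert ln.linearized_distance(cms, d, top_k=3) == pytest.approx(want)


class TestAlignment:
    def test_identity_covariance_gives_filter_norms(self, rng):
        lin = _random_linearization(rng, n_exc=5)
        cms = ln.collective_modes(ln.gain_modes(lin))
        g = ln.alignment(cms, np.eye(5), top_k=None)
        np.testing.assert_allclose(
            g, np.linalg.norm(cms.phi, axis=0) ** 2, rtol=1e-8
        )

    def test_single_direction_covariance(self, rng):
        lin = _random_linearization(rng, n_exc=5)
        cms = ln.collective_modes(ln.gain_modes(lin))
        d = rng.standard_normal(5)
        d /= np.linalg.norm(d)
        g = ln.alignment(cms, np.outer(d, d), top_k=4)
        want = np.abs(cms.phi[:, :4].conj().T @ d) ** 2
        np.testing.assert_allclose(g, want, rtol=1e-8)

    def test_alignment_consistent_with_distance(self, rng):
        # D = sum_k lam_k g_k with C built from the same unit deltas
        lin = _random_linearization(rng, n_exc=6)
        cms = ln.collective_modes(ln.gain_modes(lin))
        deltas = rng.standard_normal((9, 6))
        deltas /= np.linalg.norm(deltas, axis=1, keepdims=True)
        C = ln.delta_covariance(deltas)
        g = ln.alignment(cms, C, top_k=None)
        assert float(cms.lam @ g) == pytest.approx(
            ln.linearized_distance(cms, deltas, top_k=None), rel=1e-8
        )


class TestOrientation:
    def test_clear_signal_and_noise_modes(self):
        labels = ln.classify_orientation([1.0, 0.0], [0.0, 1.0])
        assert labels.tolist() == ["signal", "noise"]

    def test_below_threshold_is_neutral(self):
        labels = ln.classify_orientation([1.0, 0.52], [0.0, 0.48])
        assert labels.tolist() == ["signal", "neutral"]

    def test_all_equal_all_neutral(self):
        labels = ln.classify_orientation([0.5, 0.5], [0.5, 0.5])
        assert (labels == "neutral").all()


class TestModeChangeStats:
    def _cms(self, lam, phi):
        k = len(lam)
        return ln.CollectiveModeSet(lam=np.asarray(lam, float),
                                    q=np.eye(k),
                                    phi=np.asarray(phi, float),
                                    n_exc=phi.shape[0])

    def test_identical_pre_post_nothing_included(self):
        phi = np.eye(3)
        cms = self._cms([2.0, 1.0, 0.5], phi)
        al = {c: np.array([0.3, 0.2, 0.1]) for c in
              ("signal", "level", "residual")}
        df = ln.mode_change_stats(cms, cms, al, al)
        assert not df.included_lam.any()
        np.testing.assert_allclose(df.d_lam, 0.0)

    def test_doubled_spectrum_normalized_to_one(self):
        phi = np.eye(2)
        pre = self._cms([1.0, 0.5], phi)
        post = self._cms([2.0, 0.5], phi)
        al = {c: np.array([0.1, 0.1]) for c in ("signal", "level", "residual")}
        df = ln.mode_change_stats(pre, post, al, al)
        assert df.d_lam.abs().max() == pytest.approx(1.0)
        assert df.included_lam.sum() == 1

    def test_rotation_toward_signal_direction(self, rng):
        # one mode's filter rotates toward a known signal direction
        sig = np.array([1.0, 0.0, 0.0])
        phi_pre = np.stack([np.array([0.0, 1.0, 0.0])], axis=1)
        phi_post = np.stack([np.array([0.8, 0.6, 0.0])], axis=1)
        pre = self._cms([1.0], phi_pre)
        post = self._cms([1.0], phi_post)
        C_sig = np.outer(sig, sig)
        noise = np.array([0.0, 1.0, 0.0])
        C_noise = np.outer(noise, noise)
        pre_al = {"signal": ln.alignment(pre, C_sig),
                  "level": ln.alignment(pre, C_noise),
                  "residual": ln.alignment(pre, C_noise)}
        post_al = {"signal": ln.alignment(post, C_sig),
                   "level": ln.alignment(post, C_noise),
                   "residual": ln.alignment(post, C_noise)}
        df = ln.mode_change_stats(pre, post, pre_al, post_al)
        assert df.d_g_signal.iloc[0] > 0
        assert df.d_g_level.iloc[0] < 0

    def test_overlap_matching_tracks_permuted_modes(self, rng):
        phi = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        pre = self._cms([4.0, 3.0, 2.0, 1.0], phi)
        perm = [2, 0, 3, 1]
        post = self._cms(np.array([4.0, 3.0, 2.0, 1.0])[perm], phi[:, perm])
        idx = ln.match_modes(pre, post)
        np.testing.assert_array_equal(
            idx, [perm.index(i) for i in range(4)]
        )


class TestSensitivities:
    def test_equal_modes_split_evenly(self):
        out = ln.sensitivities([1.0, 1.0], [1.0, 1.0])
        np.testing.assert_allclose(out["d_lambda"], 0.5)
        np.testing.assert_allclose(out["d_g"], 0.5)

    def test_weighted_sum_identities(self, rng):
        lam = rng.uniform(0.1, 3.0, 7)
        g = rng.uniform(0.1, 2.0, 7)
        out = ln.sensitivities(lam, g)
        assert float(lam @ out["d_lambda"]) == pytest.approx(1.0, abs=1e-12)
        assert float(g @ out["d_g"]) == pytest.approx(1.0, abs=1e-12)

    def test_finite_difference_oracle(self, rng):
        lam = rng.uniform(0.5, 2.0, 5)
        g = rng.uniform(0.5, 2.0, 5)
        out = ln.sensitivities(lam, g)
        D0 = float(lam @ g)
        eps = 1e-4
        for k in range(5):
            lam2 = lam.copy()
            lam2[k] += eps
            frac = (float(lam2 @ g) - D0) / D0
            assert frac == pytest.approx(out["d_lambda"][k] * eps, rel=1e-6)

    def test_zero_distance_gives_missing(self):
        out = ln.sensitivities([1.0], [0.0])
        assert np.isnan(out["d_lambda"]).all()


class TestCompressionCondition:
    def test_equal_fractional_changes_leave_r_unchanged(self):
        out = ln.compression_condition(2.0, 1.0, 2.4, 1.2)
        assert out["delta_R"] == pytest.approx(0.0)
        assert not out["compresses"]

    def test_larger_signal_growth_compresses(self):
        out = ln.compression_condition(1.0, 1.0, 1.2, 1.1)
        assert out["delta_R"] < 0
        assert out["compresses"]

    def test_first_order_matches_exact_ratio_for_small_changes(self):
        d_sig, d_noise = 3.0, 1.5
        eps = 1e-4
        out = ln.compression_condition(d_sig, d_noise,
                                       d_sig * (1 + 2 * eps),
                                       d_noise * (1 + eps))
        exact = d_noise * (1 + eps) / (d_sig * (1 + 2 * eps)) - d_noise / d_sig
        assert out["delta_R"] == pytest.approx(exact, rel=1e-3)


class TestLinearRegimeAgreement:
    """The early relative-distance change is captured by the linearization.

    Linearized relative distances (top-10 collective modes around each
    lowest-noise attractor) should agree in sign with the full metric's
    early-training change on the trained scaled-down network.
    """

    def _linearized_R(self, cfg, exp, w_ee, table):
        import famcirc.circuit as cc

        conn = cc.build_connectivity(cfg.network)
        conn.w_ee[:] = w_ee
        level = min(l for l in cfg.levels)
        d_noise, d_sig = [], []
        for tgt in range(cfg.n_targets):
            for k in range(1, cfg.samples_per_level + 1):
                key = (level, tgt, k)
                if key not in table.data:
                    continue
                lin = ln.linearize(conn, table[key], exp.codes[key])
                cms = ln.collective_modes(ln.gain_modes(lin)).top(10)
                lev = ln.input_deltas(exp.codes, "level", anchor=key)
                res = ln.input_deltas(exp.codes, "residual", anchor=key)
                sig = ln.input_deltas(exp.codes, "signal", anchor=key)
                d_noise.append(0.5 * (
                    ln.linearized_distance(cms, lev, 10)
                    + ln.linearized_distance(cms, res, 10)))
                d_sig.append(ln.linearized_distance(cms, sig, 10))
        return float(np.mean(d_noise) / np.mean(d_sig))

    def test_sign_agreement_at_lowest_noise(self, association_run):
        cfg, probes, exp = association_run
        level = min(cfg.levels)
        pre_p, post_p = probes[0], probes[-1]

        def full_R(p):
            df = p.distances
            sel = df[df.level == level]
            return float(0.5 * (sel.R_lev.mean() + sel.R_res.mean()))

        full_change = full_R(post_p) - full_R(pre_p)
        r_hat_pre = self._linearized_R(cfg, exp, pre_p.w_ee, pre_p.table)
        r_hat_post = self._linearized_R(cfg, exp, post_p.w_ee, post_p.table)
        lin_change = r_hat_post - r_hat_pre
        assert np.sign(lin_change) == np.sign(full_change), (
            f"linearized change {lin_change:.3e}, full change {full_change:.3e}"
        )
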