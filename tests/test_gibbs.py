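"""Gibbs sampler: initialization, truncation, conditional correctness
(conjugate and GLS oracles), standardization and determinism."""

import numpy as np
import pytest
from scipy import sparse

from threshlin import _kernels
from threshlin.gibbs import (ChainConfig, CovarianceSet, PriorConfig, _run,
                             init_state, run_chain, sample_covariance_matrices,
                             sample_liabilities, sample_location_effects,
                             sample_residual_matrix, sample_scale_moves)
from threshlin.pedigree import Pedigree, inbreeding_coefficients
from threshlin.records import DesignMatrices
from threshlin.simulate import SimConfig, simulate


def gaussian_design(n=50, n_fixed=1, seed=0, n_does=5, n_litters=10):
    """Single Gaussian trait on a founder-only pedigree (A = I for kits)."""
    rng = np.random.default_rng(seed)
    ids = [f"K{i}" for i in range(n)]
    ped = Pedigree(ids, np.full(n, -1), np.full(n, -1))
    ped.f = inbreeding_coefficients(ped)
    x = np.ones((n, n_fixed))
    if n_fixed > 1:
        x[:, 1:] = rng.standard_normal((n, n_fixed - 1))
    return DesignMatrices(
        y=rng.normal(50, 10, size=(n, 1)), status=np.full((n, 1), 3),
        is_binary=np.array([False]), x=sparse.csr_matrix(x),
        x_names=[f"b{j}" for j in range(n_fixed)],
        kit_animal=np.arange(n),
        kit_dam=rng.integers(0, n_does, n),
        kit_litter=rng.integers(0, n_litters, n),
        doe_ids=[f"D{i}" for i in range(n_does)],
        litter_ids=[f"L{i}" for i in range(n_litters)],
        trait_names=("BW",)), ped


def three_trait_design(n_does=6, seed=0):
    cfg = SimConfig(seed=seed, n_does=n_does, n_sires=3)
    ped, recs, _ = simulate(cfg)
    from threshlin.records import build_design
    return build_design(recs, ped), ped


class TestInit:
    def test_deterministic(self):
        design, ped = three_trait_design()
        cfg = ChainConfig(n_iter=100, burn_in=10, thin=1, seed=9)
        s1 = init_state(design, ped, cfg)
        s2 = init_state(design, ped, cfg)
        assert np.array_equal(s1.y, s2.y)
        assert np.array_equal(s1.cov.r0, s2.cov.r0)
        assert np.all(s1.b == 0) and np.all(s1.a == 0)

    def test_liability_start_respects_category(self):
        design, ped = three_trait_design()
        st = init_state(design, ped, ChainConfig(n_iter=10, burn_in=1, seed=0))
        alive = design.status[:, 0] == 2
        dead = design.status[:, 0] == 1
        assert np.all(st.y[alive, 0] == 0.5)
        assert np.all(st.y[dead, 0] == -0.5)

    def test_threshold_residuals_start_at_one(self):
        design, ped = three_trait_design()
        st = init_state(design, ped, ChainConfig(n_iter=10, burn_in=1, seed=0))
        assert st.cov.r0[0, 0] == 1.0 and st.cov.r0[1, 1] == 1.0


class TestChainConfig:
    def test_full_protocol_saves_5000(self):
        cfg = ChainConfig(n_iter=1_000_000, burn_in=500_000, thin=100)
        assert cfg.n_saved == 5000

    def test_thin_one_no_burn_in(self):
        assert ChainConfig(n_iter=200, burn_in=0, thin=1).n_saved == 200

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(n_iter=100, burn_in=10, thin=0)


class TestTruncatedNormal:
    def test_positive_half_normal_mean(self):
        # E[z | z>0] for N(0,1) is phi(0)/(1-Phi(0)) = 0.7979
        _kernels.seed_kernels(123)
        draws = np.array([_kernels.draw_gt0(0.0, 1.0) for _ in range(100_000)])
        assert np.all(draws > 0)
        assert draws.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_deep_tail_truncation_robust(self):
        _kernels.seed_kernels(5)
        draws = np.array([_kernels.draw_gt0(-8.0, 1.0) for _ in range(2000)])
        assert np.all(draws > -8.0) and np.isfinite(draws).all()
        draws = np.array([_kernels.draw_le0(12.0, 1.0) for _ in range(2000)])
        assert np.all(draws <= 0.0)


class TestLiabilities:
    def test_truncation_honored_every_sweep(self):
        design, ped = three_trait_design(n_does=8)
        st = init_state(design, ped, ChainConfig(n_iter=10, burn_in=1, seed=1))
        for _ in range(20):
            sample_liabilities(st)
            sample_location_effects(st)
        for t in (0, 1):
            alive = design.status[:, t] == 2
            dead = design.status[:, t] == 1
            assert np.all(st.y[alive, t] > 0)
            assert np.all(st.y[dead, t] <= 0)

    def test_observed_gaussian_cells_untouched(self):
        design, ped = three_trait_design()
        st = init_state(design, ped, ChainConfig(n_iter=10, burn_in=1, seed=1))
        obs = design.status[:, 2] == 3
        before = st.y[obs, 2].copy()
        sample_liabilities(st)
        assert np.array_equal(st.y[obs, 2], before)


def fitted_values(state, design):
    fit = design.x @ state.b
    fit += state.a[design.kit_animal]
    fit += state.m[design.kit_dam]
    fit += state.c[design.kit_litter]
    return fit


class TestResidualBookkeeping:
    def test_residuals_consistent_through_all_updates(self):
        design, ped = three_trait_design(n_does=8)
        st = init_state(design, ped, ChainConfig(n_iter=10, burn_in=1, seed=4))
        for _ in range(5):
            sample_liabilities(st)
            sample_location_effects(st)
            sample_covariance_matrices(st)
            sample_scale_moves(st)
            sample_residual_matrix(st)
        assert np.allclose(st.y - st.e, fitted_values(st, design), atol=1e-8)

    def test_standardization_constraints(self):
        design, ped = three_trait_design(n_does=8)
        st = init_state(design, ped, ChainConfig(n_iter=10, burn_in=1, seed=4))
        sample_liabilities(st)
        sample_location_effects(st)
        sample_residual_matrix(st)
        assert st.cov.r0[0, 0] == 1.0 and st.cov.r0[1, 1] == 1.0
        assert st.cov.r0[0, 1] == 0.0  # SB-SW residual covariance fixed
        np.linalg.cholesky(st.cov.r0)

    def test_standardization_preserves_category_signs(self):
        design, ped = three_trait_design(n_does=8)
        st = init_state(design, ped, ChainConfig(n_iter=10, burn_in=1, seed=4))
        sample_liabilities(st)
        sample_residual_matrix(st)
        alive = design.status[:, 0] == 2
        assert np.all(st.y[alive, 0] > 0)


class TestConjugateOracles:
    def test_genetic_covariance_matches_inverse_gamma(self):
        # A = I, fixed effects vector: repeated G0 draws must match the
        # closed-form inverse gamma posterior moments
        design, ped = gaussian_design(n=50)
        cfg = ChainConfig(n_iter=10, burn_in=1, seed=5)
        st = init_state(design, ped, cfg)
        rng = np.random.default_rng(0)
        st.a = rng.normal(0, 2.0, size=(50, 1))
        psi = cfg.priors.scale_matrix("g", design.is_binary,
                                      st.ws.pheno_var)[0, 0]
        s = float(st.a[:, 0] @ st.a[:, 0]) + psi
        df = cfg.priors.df + 50
        a_fixed = st.a.copy()
        draws = []
        for _ in range(4000):
            st.a = a_fixed.copy()
            sample_covariance_matrices(st)
            draws.append(st.cov.g0[0, 0])
        mean_expect = s / (df - 2)
        var_expect = 2 * s ** 2 / ((df - 2) ** 2 * (df - 4))
        assert np.mean(draws) == pytest.approx(
            mean_expect, abs=4 * np.sqrt(var_expect / 4000))
        assert np.var(draws) == pytest.approx(var_expect, rel=0.2)

    def test_residual_matches_conjugate_form(self):
        # all-Gaussian degenerate case: R0 draws given residuals follow the
        # unconstrained inverse Wishart (no standardization for a Gaussian
        # trait)
        design, ped = gaussian_design(n=80)
        cfg = ChainConfig(n_iter=10, burn_in=1, seed=6)
        st = init_state(design, ped, cfg)
        rng = np.random.default_rng(1)
        st.e = rng.normal(0, 3.0, size=(80, 1))
        e_fixed = st.e.copy()
        psi = cfg.priors.scale_matrix("r", design.is_binary,
                                      st.ws.pheno_var)[0, 0]
        s = float(e_fixed[:, 0] @ e_fixed[:, 0]) + psi
        df = cfg.priors.df + 80
        draws = []
        for _ in range(4000):
            st.e = e_fixed.copy()
            sample_residual_matrix(st)
            draws.append(st.cov.r0[0, 0])
        var_expect = 2 * s ** 2 / ((df - 2) ** 2 * (df - 4))
        assert np.mean(draws) == pytest.approx(
            s / (df - 2), abs=4 * np.sqrt(var_expect / 4000))

    def test_fixed_effects_center_on_gls(self):
        # variance-ratio -> 0 limit: with the random effects pinned at zero,
        # fixed-effect draws center on the generalized least squares solution
        design, ped = gaussian_design(n=30, n_fixed=3, seed=3)
        cfg = ChainConfig(n_iter=10, burn_in=1, seed=7)
        st = init_state(design, ped, cfg)
        tiny = 1e-12
        st.cov = CovarianceSet(np.array([[tiny]]), np.array([[tiny]]),
                               np.array([[tiny]]), np.array([[25.0]]), ("BW",))
        y = design.y[:, 0]
        x = design.x.toarray()
        gls = np.linalg.lstsq(x, y, rcond=None)[0]
        total = np.zeros(3)
        n_draws = 3000
        for _ in range(n_draws):
            sample_location_effects(st)
            total += st.b[:, 0]
        assert np.allclose(total / n_draws, gls, atol=0.15)


class TestPriorOnly:
    def test_prior_recovered_without_data(self):
        # one kit, every cell missing: covariance draws must follow the prior
        rng = np.random.default_rng(0)
        ids = ["K0"]
        ped = Pedigree(ids, np.array([-1]), np.array([-1]))
        ped.f = inbreeding_coefficients(ped)
        design = DesignMatrices(
            y=np.full((1, 1), np.nan), status=np.zeros((1, 1), dtype=int),
            is_binary=np.array([False]), x=sparse.csr_matrix(np.ones((1, 1))),
            x_names=["b0"], kit_animal=np.zeros(1, int),
            kit_dam=np.zeros(1, int), kit_litter=np.zeros(1, int),
            doe_ids=["D0"], litter_ids=["L0"], trait_names=("BW",))
        cfg = ChainConfig(n_iter=4000, burn_in=1000, thin=1, seed=11)
        samples, _, _ = _run(design, ped, cfg)
        draws = samples.draws["M_BW_BW"].to_numpy()
        # prior: IW_1(df=5, scale=0.05) -> median of scale/chi2_5
        ref = 0.05 / np.random.default_rng(1).chisquare(5, 40_000)
        assert np.median(draws) == pytest.approx(np.median(ref), rel=0.35)


class TestRunChain:
    def test_bookkeeping_and_determinism(self):
        design, ped = three_trait_design(n_does=5)
        cfg = ChainConfig(n_iter=200, burn_in=0, thin=1, seed=21)
        s1 = run_chain(design, ped, cfg)
        assert len(s1) == 200
        s2 = run_chain(design, ped, cfg)
        assert np.array_equal(s1.draws.to_numpy(), s2.draws.to_numpy())

    def test_different_seed_differs(self):
        design, ped = three_trait_design(n_does=5)
        s1 = run_chain(design, ped, ChainConfig(n_iter=150, burn_in=50, thin=1, seed=1))
        s2 = run_chain(design, ped, ChainConfig(n_iter=150, burn_in=50, thin=1, seed=2))
        assert not np.array_equal(s1.draws.to_numpy(), s2.draws.to_numpy())

    def test_single_trait_recovery_within_posterior_uncertainty(self):
        # y = mu + a + c + e with a founder pedigree of sib families:
        # posterior must place the true variances within ~3 posterior SDs
        rng = np.random.default_rng(8)
        n_pairs, litters_per_pair, lsize = 50, 2, 5
        ids = [f"S{i}" for i in range(n_pairs)] + [f"D{i}" for i in range(n_pairs)]
        sire, dam = [-1] * (2 * n_pairs), [-1] * (2 * n_pairs)
        kit_anim, kit_lit = [], []
        n_litters = 0
        for p in range(n_pairs):
            for _ in range(litters_per_pair):
                for k in range(lsize):
                    ids.append(f"K{n_litters}_{k}")
                    sire.append(p)
                    dam.append(n_pairs + p)
                    kit_anim.append(len(ids) - 1)
                    kit_lit.append(n_litters)
                n_litters += 1
        ped = Pedigree(ids, np.array(sire), np.array(dam))
        ped.f = inbreeding_coefficients(ped)
        n = len(kit_anim)
        va, vc, ve = 30.0, 20.0, 50.0
        a = np.zeros(len(ids))
        a[:2 * n_pairs] = rng.normal(0, np.sqrt(va), 2 * n_pairs)
        for i in range(2 * n_pairs, len(ids)):
            a[i] = 0.5 * (a[sire[i]] + a[dam[i]]) \
                + rng.normal(0, np.sqrt(0.5 * va))
        c = rng.normal(0, np.sqrt(vc), n_litters)
        y = 10 + a[kit_anim] + c[kit_lit] + rng.normal(0, np.sqrt(ve), n)
        design = DesignMatrices(
            y=y[:, None], status=np.full((n, 1), 3), is_binary=np.array([False]),
            x=sparse.csr_matrix(np.ones((n, 1))), x_names=["mu"],
            kit_animal=np.array(kit_anim), kit_dam=np.zeros(n, int),
            kit_litter=np.array(kit_lit), doe_ids=["D0"],
            litter_ids=[f"L{i}" for i in range(n_litters)], trait_names=("BW",))
        samples = run_chain(design, ped,
                            ChainConfig(n_iter=6000, burn_in=2000, thin=4, seed=30))
        for col, truth in [("C_BW_BW", vc), ("R_BW_BW", ve), ("G_BW_BW", va)]:
            x = samples.draws[col]
            assert abs(x.mean() - truth) < 3 * x.std() + 1e-9, col
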