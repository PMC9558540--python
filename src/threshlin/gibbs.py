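"""Gibbs sampler for the multi-trait threshold-linear animal model.

The model is y = Xb + Za + Wm + Vc + e per trait, with direct additive
genetic effects a ~ N(0, A (x) G0), maternal permanent environmental effects
m ~ N(0, I (x) M0), common litter effects c ~ N(0, I (x) C0) and residuals
e ~ N(0, I (x) R0).  Binary survival traits are handled by data augmentation:
an underlying Gaussian liability is sampled for every cell, truncated at the
zero threshold according to the observed category.

Identifiability for threshold traits follows the usual convention: threshold
fixed at 0 and residual liability variance fixed at 1, enforced after each
residual-matrix draw by rescaling (draw-then-standardize), which leaves the
joint posterior invariant.  The residual covariance between the two survival
liabilities is fixed at 0, since survival at weaning is only observed for
kits alive at birth and that covariance carries essentially no likelihood
information.

The per-iteration scalar updates run in numba-compiled kernels; covariance
matrices are drawn from their inverse Wishart full conditionals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.stats import invwishart

from . import _kernels
from .pedigree import (Pedigree, _mendelian_variances, a_inverse,
                       inbreeding_coefficients)
from .records import CODE_ALIVE, CODE_DEAD, CODE_OBSERVED, DesignMatrices
from .posterior import PosteriorSamples, from_raw_draws

logger = logging.getLogger(__name__)

__all__ = [
    "CovarianceSet", "PriorConfig", "ChainConfig", "ChainState",
    "init_state", "sample_liabilities", "sample_location_effects",
    "sample_covariance_matrices", "sample_residual_matrix",
    "sample_additive_block", "sample_scale_moves", "run_chain",
]


@dataclass
class CovarianceSet:
    """The four trait-by-trait covariance matrices of the model."""

    g0: np.ndarray  # direct additive genetic
    m0: np.ndarray  # maternal permanent environmental
    c0: np.ndarray  # common litter
    r0: np.ndarray  # residual
    trait_names: tuple[str, ...] = ("SB", "SW", "BW")

    def copy(self) -> "CovarianceSet":
        return CovarianceSet(self.g0.copy(), self.m0.copy(), self.c0.copy(),
                             self.r0.copy(), self.trait_names)

    def validate(self) -> None:
        for name, mat in (("G0", self.g0), ("M0", self.m0),
                          ("C0", self.c0), ("R0", self.r0)):
            if not np.allclose(mat, mat.T):
                raise ValueError(f"{name} is not symmetric")
            if np.any(np.linalg.eigvalsh(mat) <= 0):
                raise ValueError(f"{name} is not positive definite")


@dataclass
class PriorConfig:
    """Inverse Wishart priors for the covariance matrices.

    Default: weakly informative proper priors with df=5 and diagonal scale
    proportional to the trait's phenotypic scale — 5% of the observed
    phenotypic variance for the genetic, maternal and litter matrices and
    100% for the residual (liability traits use scale 1, their fixed
    residual variance).  Scaling the prior to the trait is essential: a
    fixed tiny scale such as 0.01 on a trait with variance in the hundreds
    concentrates the prior at zero and traps any conjugate Gibbs sampler in
    a collapsed variance state.  ``flat=True`` switches to the improper
    |V|^-(T+1)/2 reference prior (posterior df = number of levels).
    """

    df: float = 5.0
    scale_gmc_frac: float = 0.05
    scale_r_frac: float = 0.5
    flat: bool = False

    def scale_matrix(self, which: str, is_binary: np.ndarray,
                     pheno_var: np.ndarray | None = None) -> np.ndarray:
        t = len(is_binary)
        if self.flat:
            return np.zeros((t, t))
        base = np.where(is_binary, 1.0,
                        np.ones(t) if pheno_var is None else pheno_var)
        if which == "r":
            return np.diag(self.scale_r_frac * base).astype(float)
        return np.diag(self.scale_gmc_frac * base).astype(float)

    def df0(self) -> float:
        return 0.0 if self.flat else self.df


@dataclass
class ChainConfig:
    """Gibbs chain settings.  Defaults mirror the full analysis protocol:
    1,000,000 iterations, 500,000 burn-in, keep 1 in 100."""

    n_iter: int = 1_000_000
    burn_in: int = 500_000
    thin: int = 100
    seed: int = 0
    priors: PriorConfig = field(default_factory=PriorConfig)
    fixed_effect_bounds: tuple[float, float] = (-np.inf, np.inf)
    #: every k-th iteration the whole additive-genetic block is redrawn
    #: jointly from its exact multivariate conditional (0 disables)
    block_a_every: int = 5
    #: every k-th iteration each doe's (m, litters-c) block is redrawn
    #: jointly (0 disables)
    doe_block_every: int = 1

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


class _Workspace:
    """Numba-ready views of the design: CSC fixed effects, CSR A-inverse,
    and group->kit row maps for animals, does and litters."""

    def __init__(self, design: DesignMatrices, ped: Pedigree,
                 a_inv: sparse.spmatrix | None = None):
        self.design = design
        self.ped = ped
        x = design.x.tocsc()
        self.xp = x.indptr.astype(np.int64)
        self.xi = x.indices.astype(np.int64)
        self.xv = x.data.astype(np.float64)
        self.xsq = np.asarray(x.multiply(x).sum(axis=0)).ravel()
        ainv = a_inverse(ped) if a_inv is None else sparse.csr_matrix(a_inv)
        self.a_inv = ainv
        self.ap = ainv.indptr.astype(np.int64)
        self.ai = ainv.indices.astype(np.int64)
        self.av = ainv.data.astype(np.float64)
        self.adiag = ainv.diagonal().astype(np.float64)
        n_anim = len(ped)
        self.akp, self.aki = _group_map(design.kit_animal, n_anim)
        self.mkp, self.mki = _group_map(design.kit_dam, len(design.doe_ids))
        self.ckp, self.cki = _group_map(design.kit_litter, len(design.litter_ids))
        self.kit_counts = np.bincount(design.kit_animal, minlength=n_anim).astype(float)
        f = ped.f if ped.f is not None else inbreeding_coefficients(ped)
        self.mend_var = _mendelian_variances(ped.sire, ped.dam, f)
        # litter -> doe and doe -> litters (each litter has exactly one dam)
        n_lit = len(design.litter_ids)
        self.litter_doe = np.zeros(n_lit, dtype=np.int64)
        self.litter_doe[design.kit_litter] = design.kit_dam
        self.dlp, self.dli = _group_map(self.litter_doe, len(design.doe_ids))


def _group_map(idx: np.ndarray, n_groups: int):
    order = np.argsort(idx, kind="stable").astype(np.int64)
    counts = np.bincount(idx, minlength=n_groups)
    gp = np.zeros(n_groups + 1, dtype=np.int64)
    gp[1:] = np.cumsum(counts)
    return gp, order


@dataclass
class ChainState:
    """Current state of the sampler (mutated in place by the update steps)."""

    y: np.ndarray            # augmented data / liabilities, (n_kits, T)
    e: np.ndarray            # residuals, (n_kits, T)
    b: np.ndarray            # fixed effects, (n_fixed, T)
    a: np.ndarray            # additive genetic, (n_animals, T)
    m: np.ndarray            # maternal permanent, (n_does, T)
    c: np.ndarray            # common litter, (n_litters, T)
    cov: CovarianceSet
    cfg: ChainConfig
    rng: np.random.Generator
    ws: _Workspace
    iteration: int = 0


def init_state(design: DesignMatrices, ped: Pedigree,
               cfg: ChainConfig) -> ChainState:
    """Initial chain state: zeroed location effects, liabilities at +-0.5 by
    observed category (0 for missing cells), default-diagonal covariance
    matrices with liability residual variances at exactly 1."""
    t = design.n_traits
    n = design.n_kits
    y = np.array(design.y, dtype=np.float64)
    for k in range(t):
        if design.is_binary[k]:
            y[:, k] = np.where(design.status[:, k] == CODE_ALIVE, 0.5,
                               np.where(design.status[:, k] == CODE_DEAD, -0.5, 0.0))
        else:
            obs = design.status[:, k] == CODE_OBSERVED
            fill = float(np.mean(y[obs, k])) if obs.any() else 0.0
            y[~obs, k] = fill

    var0 = np.empty(t)
    for k in range(t):
        if design.is_binary[k]:
            var0[k] = 1.0
        else:
            obs = design.status[:, k] == CODE_OBSERVED
            var0[k] = float(np.var(y[obs, k])) if obs.sum() > 1 else 1.0
    comp = np.where(design.is_binary, 0.1, 0.1 * var0)
    cov = CovarianceSet(np.diag(comp).astype(float), np.diag(comp).astype(float),
                        np.diag(comp).astype(float),
                        np.diag(np.where(design.is_binary, 1.0, 0.5 * var0)).astype(float),
                        trait_names=tuple(design.trait_names))
    cov.validate()

    ss = np.random.SeedSequence(cfg.seed)
    kernel_seed, gen_seed = (int(s) for s in ss.generate_state(2))
    _kernels.seed_kernels(kernel_seed % (2 ** 31))
    rng = np.random.default_rng(gen_seed)

    ws = _Workspace(design, ped)
    ws.pheno_var = var0
    state = ChainState(
        y=y, e=y.copy(), b=np.zeros((design.x.shape[1], t)),
        a=np.zeros((len(ped), t)), m=np.zeros((len(design.doe_ids), t)),
        c=np.zeros((len(design.litter_ids), t)), cov=cov, cfg=cfg,
        rng=rng, ws=ws)
    return state


def sample_liabilities(state: ChainState,
                       design: DesignMatrices | None = None) -> ChainState:
    """Redraw liabilities (and augmented missing Gaussian cells) from their
    truncated-normal full conditionals."""
    design = design or state.ws.design
    lam = np.linalg.inv(state.cov.r0)
    _kernels.sweep_liabilities(state.y, state.e, design.status,
                               design.is_binary, lam)
    return state


def sample_location_effects(state: ChainState,
                            design: DesignMatrices | None = None,
                            a_inv: sparse.spmatrix | None = None) -> ChainState:
    """Single-site Gauss-Seidel draws of b, a, m, c from their Gaussian full
    conditionals (flat prior on b, A^-1 (x) G0^-1 precision on a)."""
    ws = state.ws
    lam = np.linalg.inv(state.cov.r0)
    lo, hi = state.cfg.fixed_effect_bounds
    _kernels.sweep_locations(
        state.e, state.b, state.a, state.m, state.c, lam,
        np.linalg.inv(state.cov.g0), np.linalg.inv(state.cov.m0),
        np.linalg.inv(state.cov.c0),
        ws.xp, ws.xi, ws.xv, ws.xsq,
        ws.ap, ws.ai, ws.av, ws.adiag,
        ws.akp, ws.aki, ws.mkp, ws.mki, ws.ckp, ws.cki,
        float(lo), float(hi))
    return state


def _draw_invwishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    t = scale.shape[0]
    jitter = 0.0
    for _ in range(6):
        try:
            draw = invwishart.rvs(df=df, scale=scale + jitter * np.eye(t),
                                  random_state=rng)
            draw = np.atleast_2d(draw)
            return (draw + draw.T) / 2.0
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate scale
            jitter = max(jitter * 10, 1e-8 * max(np.trace(scale), 1.0))
            logger.warning("invWishart scale not PD; retrying with jitter %g", jitter)
    raise np.linalg.LinAlgError("inverse Wishart scale matrix not positive definite")


def sample_covariance_matrices(state: ChainState, ped: Pedigree | None = None,
                               a_inv: sparse.spmatrix | None = None) -> ChainState:
    """Draw G0, M0 and C0 from their inverse Wishart full conditionals."""
    ws = state.ws
    ainv = ws.a_inv if a_inv is None else a_inv
    pr = state.cfg.priors
    is_b = ws.design.is_binary
    pv = getattr(ws, "pheno_var", None)

    sa = state.a.T @ (ainv @ state.a)
    state.cov.g0 = _draw_invwishart(state.rng, pr.df0() + state.a.shape[0],
                                    sa + pr.scale_matrix("g", is_b, pv))
    sm = state.m.T @ state.m
    state.cov.m0 = _draw_invwishart(state.rng, pr.df0() + state.m.shape[0],
                                    sm + pr.scale_matrix("m", is_b, pv))
    sc = state.c.T @ state.c
    state.cov.c0 = _draw_invwishart(state.rng, pr.df0() + state.c.shape[0],
                                    sc + pr.scale_matrix("c", is_b, pv))
    return state


def sample_residual_matrix(state: ChainState,
                           design: DesignMatrices | None = None) -> ChainState:
    """Draw R0 from its inverse Wishart conditional, then standardize.

    Liability residual variances are rescaled to exactly 1 (threshold-model
    identification); the compensating scale factors are applied to the
    liabilities, residuals, every location-effect column and the rows/columns
    of G0, M0 and C0, so standardized residuals are unchanged.  The residual
    covariance between binary traits is then fixed at 0 (with a PD repair
    that shrinks the remaining off-diagonals if ever needed).
    """
    design = design or state.ws.design
    pr = state.cfg.priors
    is_b = design.is_binary
    n = design.n_kits
    se = state.e.T @ state.e
    pv = getattr(state.ws, "pheno_var", None)
    r0 = _draw_invwishart(state.rng, pr.df0() + n,
                          se + pr.scale_matrix("r", is_b, pv))

    d = np.where(is_b, 1.0 / np.sqrt(np.diag(r0)), 1.0)
    r0 = r0 * d[:, None] * d[None, :]
    t = len(is_b)
    for k in range(t):
        if is_b[k]:
            r0[k, k] = 1.0
    for i in range(t):
        for j in range(i + 1, t):
            if is_b[i] and is_b[j]:
                r0[i, j] = r0[j, i] = 0.0
    for _ in range(100):
        try:
            np.linalg.cholesky(r0)
            break
        except np.linalg.LinAlgError:
            off = ~np.eye(t, dtype=bool)
            r0[off] *= 0.9
    state.cov.r0 = r0

    # compensating rescale on the liability scale
    for k in range(t):
        if is_b[k] and d[k] != 1.0:
            dk = d[k]
            state.y[:, k] *= dk
            state.e[:, k] *= dk
            state.b[:, k] *= dk
            state.a[:, k] *= dk
            state.m[:, k] *= dk
            state.c[:, k] *= dk
            for mat in (state.cov.g0, state.cov.m0, state.cov.c0):
                mat[k, :] *= dk
                mat[:, k] *= dk
    return state


def sample_doe_blocks(state: ChainState) -> ChainState:
    """Exact joint redraw of every doe's maternal effect together with her
    litters' common-litter effects (the m/c split mixes poorly under scalar
    updates when litters-per-doe is small)."""
    ws = state.ws
    lam = np.linalg.inv(state.cov.r0)
    _kernels.sweep_doe_blocks(
        state.e, state.m, state.c, lam,
        np.linalg.inv(state.cov.m0), np.linalg.inv(state.cov.c0),
        ws.dlp, ws.dli, ws.ckp, ws.cki, ws.litter_doe)
    return state


def sample_additive_block(state: ChainState) -> ChainState:
    """Joint redraw of every additive genetic value from its exact full
    conditional, by solving the genetic block of the mixed-model equations.

    Single-site sweeps move the a-field one scalar at a time, so the
    exchange between the genetic covariance and the field decorrelates over
    thousands of iterations.  This step samples the whole (animals x traits)
    block at once using the sampling-by-perturbation identity: with
    precision P = G0^-1 (x) A^-1 + Lambda (x) diag(kit counts) and
    right-hand side built from the residuals with a removed, the draw
    mu + (a* - P^-1 rhs*) — where a* is a prior draw down the pedigree and
    rhs* uses synthetic data y* = Z a* + e* — has exactly the conditional
    mean and covariance.  One sparse LU factorization and two solves.
    """
    ws = state.ws
    design = ws.design
    t = design.n_traits
    q = state.a.shape[0]
    lam = np.linalg.inv(state.cov.r0)
    g0i = np.linalg.inv(state.cov.g0)
    kit_animal = design.kit_animal

    prec = sparse.kron(g0i, ws.a_inv) + \
        sparse.kron(lam, sparse.diags(ws.kit_counts))
    # pedigree graphs factor with almost no fill under a symmetric ordering
    lu = sparse.linalg.splu(prec.tocsc(), permc_spec="MMD_AT_PLUS_A",
                            options=dict(SymmetricMode=True))

    def rhs_from(ytil):
        lam_y = ytil @ lam
        acc = np.zeros((q, t))
        np.add.at(acc, kit_animal, lam_y)
        return acc.T.ravel()

    ytil = state.e + state.a[kit_animal]
    mu = lu.solve(rhs_from(ytil))

    lg = np.linalg.cholesky(state.cov.g0)
    z = state.rng.standard_normal((q, t))
    a_star = _kernels.pedigree_prior_draw(ws.ped.sire, ws.ped.dam,
                                          ws.mend_var, lg, z)
    lr = np.linalg.cholesky(state.cov.r0)
    e_star = state.rng.standard_normal((design.n_kits, t)) @ lr.T
    y_star = a_star[kit_animal] + e_star
    sol_star = lu.solve(rhs_from(y_star))

    a_new = (mu + a_star.T.ravel() - sol_star).reshape(t, q).T
    state.e -= (a_new - state.a)[kit_animal]
    state.a = a_new
    return state


def _log_scale_density(theta: float, qa: float, qb: float, qc: float,
                       nu: float) -> float:
    # log density of theta = log(alpha) for the group scale move
    al = np.exp(theta)
    return -0.5 * qa * al * al + qb * al - 0.5 * qc / (al * al) - nu * theta


def _slice_scale(qa: float, qb: float, qc: float, nu: float,
                 rng: np.random.Generator, width: float = 0.5,
                 max_steps: int = 20) -> float:
    """One slice-sampling update of the scale factor alpha (start alpha=1)."""
    th0 = 0.0
    ly = _log_scale_density(th0, qa, qb, qc, nu) - rng.exponential()
    lo = th0 - width * rng.random()
    hi = lo + width
    for _ in range(max_steps):
        if _log_scale_density(lo, qa, qb, qc, nu) <= ly:
            break
        lo -= width
    for _ in range(max_steps):
        if _log_scale_density(hi, qa, qb, qc, nu) <= ly:
            break
        hi += width
    for _ in range(100):
        th = lo + rng.random() * (hi - lo)
        if _log_scale_density(th, qa, qb, qc, nu) >= ly:
            return float(np.exp(th))
        if th < th0:
            lo = th
        else:
            hi = th
    return 1.0


def sample_scale_moves(state: ChainState) -> ChainState:
    """Parameter-expansion scale moves for the a, m and c blocks.

    Single-site Gibbs can trap a variance component near zero (effects
    shrink, so the variance draw shrinks, pinning the effects further).  The
    standard fix is a joint rescale of a whole random-effect column and its
    variance: for each component and trait, draw alpha from the exact
    conditional implied by the multiplicative group move
    (u_t, V) -> (alpha u_t, D_alpha V D_alpha) under Haar measure — a
    generalized Gibbs step that leaves the posterior invariant — then apply
    it.  The one-dimensional draw uses slice sampling.  Skipped under flat
    priors (the move's density is improper without the Wishart scale term).
    """
    pr = state.cfg.priors
    if pr.flat:
        return state
    ws = state.ws
    design = ws.design
    is_b = design.is_binary
    t_n = design.n_traits
    lam = np.linalg.inv(state.cov.r0)
    e = state.e
    pv = getattr(ws, "pheno_var", None)
    blocks = (
        (state.a, design.kit_animal, state.cov.g0, pr.scale_matrix("g", is_b, pv)),
        (state.m, design.kit_dam, state.cov.m0, pr.scale_matrix("m", is_b, pv)),
        (state.c, design.kit_litter, state.cov.c0, pr.scale_matrix("c", is_b, pv)),
    )
    for u, gidx, v, psi in blocks:
        v_inv = np.linalg.inv(v)
        w = u[gidx]
        for t in range(t_n):
            wt = w[:, t]
            qa = lam[t, t] * float(wt @ wt)
            r = lam[t, t] * (e[:, t] + wt)
            for s in range(t_n):
                if s != t:
                    r = r + lam[t, s] * e[:, s]
            qb = float(wt @ r)
            qc = psi[t, t] * v_inv[t, t]
            alpha = _slice_scale(qa, qb, qc, pr.df, state.rng)
            if alpha != 1.0:
                u[:, t] *= alpha
                e[:, t] -= (alpha - 1.0) * wt
                w[:, t] *= alpha
                v[t, :] *= alpha
                v[:, t] *= alpha
    return state


def _cov_columns(trait_names) -> list[str]:
    cols = []
    t = len(trait_names)
    for label in ("G", "M", "C", "R"):
        for i in range(t):
            for j in range(i, t):
                cols.append(f"{label}_{trait_names[i]}_{trait_names[j]}")
    return cols


def _flatten_cov(cov: CovarianceSet) -> np.ndarray:
    t = cov.g0.shape[0]
    out = []
    for mat in (cov.g0, cov.m0, cov.c0, cov.r0):
        for i in range(t):
            for j in range(i, t):
                out.append(mat[i, j])
    return np.array(out)


def _run(design: DesignMatrices, ped: Pedigree, cfg: ChainConfig):
    """Full Gibbs run; returns (PosteriorSamples, posterior-mean a, state)."""
    state = init_state(design, ped, cfg)
    n_saved = cfg.n_saved
    draws = np.empty((n_saved, len(_flatten_cov(state.cov))))
    ebv_sum = np.zeros_like(state.a)
    log_every = max(1, cfg.n_iter // 10)
    row = 0
    for it in range(1, cfg.n_iter + 1):
        state.iteration = it
        try:
            sample_liabilities(state)
            sample_location_effects(state)
            if cfg.doe_block_every and it % cfg.doe_block_every == 0:
                sample_doe_blocks(state)
            if cfg.block_a_every and it % cfg.block_a_every == 0:
                sample_additive_block(state)
            sample_covariance_matrices(state)
            sample_scale_moves(state)
            sample_residual_matrix(state)
        except Exception as exc:
            raise RuntimeError(f"Gibbs update failed at iteration {it}") from exc
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            draws[row] = _flatten_cov(state.cov)
            ebv_sum += state.a
            row += 1
        if it % log_every == 0:
            logger.info("iteration %d/%d (%d samples saved)", it, cfg.n_iter, row)
    meta = {
        "n_iter": cfg.n_iter, "burn_in": cfg.burn_in, "thin": cfg.thin,
        "seed": cfg.seed, "n_kits": design.n_kits, "n_animals": len(ped),
        "n_does": len(design.doe_ids), "n_litters": len(design.litter_ids),
        "traits": ",".join(design.trait_names),
        "flat_priors": cfg.priors.flat, "prior_df": cfg.priors.df,
    }
    import pandas as pd
    raw = pd.DataFrame(draws[:row], columns=_cov_columns(design.trait_names))
    samples = from_raw_draws(raw, meta, tuple(design.trait_names))
    ebv = ebv_sum / max(row, 1)
    return samples, ebv, state


def run_chain(design: DesignMatrices, ped: Pedigree,
              cfg: ChainConfig) -> PosteriorSamples:
    """Run the sampler and return thinned post-burn-in covariance draws with
    derived genetic parameters (heritabilities, fractions, correlations)."""
    samples, _, _ = _run(design, ped, cfg)
    return samples
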