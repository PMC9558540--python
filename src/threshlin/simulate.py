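"""Synthetic kit-survival datasets from the forward generative model.

Emulates a small maternal rabbit line kept in discrete generations: founder
bucks and does, up to three parities per doe with a configurable
farrowing-failure rate, truncated-Gaussian litter sizes, and three correlated
traits per kit — liability of survival at birth (SB), liability of survival
to weaning (SW) and birth weight (BW, grams) — generated as

    latent = intercept + fixed effects + a_kit + m_dam + c_litter + e

with a, m, c, e drawn from the configured G0, M0, C0, R0.  Defaults
reproduce the study structure this package targets: 81 does, 3 parities,
~208 litters, ~1,700 kits, litter size 8.15 +- 3.16, ~90.6% survival at
birth, ~89.4% at weaning, birth weight 51.4 +- 15.2 g, with variance
fractions and component correlations set to the reported point estimates.
Intercepts are calibrated analytically (probit for the liabilities) so the
realized survival rates and birth-weight mean hit their targets on average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .gibbs import CovarianceSet
from .pedigree import Pedigree, _mendelian_variances, inbreeding_coefficients
from .records import CODE_ALIVE, CODE_DEAD, CODE_MISSING, KitRecord, records_to_frame

__all__ = ["SimConfig", "simulate_pedigree", "simulate_genetic_effects",
           "simulate_phenotypes", "simulate", "generate_dataset"]

TRAITS = ("SB", "SW", "BW")

#: default true fixed-effect values per (SB liability, SW liability, BW g);
#: reference levels carry 0 and are omitted.  Magnitudes follow the
#: qualitative level differences of the descriptive statistics (lighter kits
#: in first parities, in summer, from lactating does, in females).
DEFAULT_FIXED_EFFECTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "parity": {"2": (0.05, 0.05, 5.0), "3": (0.05, 0.10, 8.0)},
    "lactation": {"nonlactating": (0.05, 0.0, 4.0)},
    "season": {"autumn": (0.10, 0.05, 5.0)},
    "nest": {"intermediate": (0.10, 0.10, 0.0), "excellent": (0.20, 0.20, 0.5)},
    "cannibalism": {"yes": (-0.30, -0.20, -5.0)},
    "inside_nest": {"no": (0.10, 0.0, 4.0)},
    "sex": {"female": (-0.05, -0.05, -1.0)},
}

DEFAULT_LEVEL_PROBS: dict[str, dict[str, float]] = {
    "season": {"summer": 0.614, "autumn": 0.386},
    "nest": {"bad": 0.014, "intermediate": 0.052, "excellent": 0.934},
    "cannibalism": {"no": 0.965, "yes": 0.035},
    "inside_nest": {"yes": 0.946, "no": 0.054},
    "sex": {"male": 0.5, "female": 0.5},
}


@dataclass
class SimConfig:
    """True parameters of the generator (defaults = study conditions)."""

    n_does: int = 81
    n_sires: int = 40
    #: ancestral generation linking the breeding animals (the study's
    #: pedigree counts ~100 more animals than kits + parents); set both to 0
    #: for a founder-only pedigree
    n_anc_sires: int = 33
    n_anc_dams: int = 70
    parities: int = 3
    farrowing_rate: float = 0.85     # litters realized per mating
    litter_mean: float = 8.15
    litter_sd: float = 3.16
    survival_birth: float = 0.906
    survival_weaning: float = 0.894
    bw_mean: float = 51.36
    bw_sd: float = 15.19
    #: per trait (SB, SW, BW): phenotypic fractions of a, m and c variance
    fractions: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "SB": (0.018, 0.043, 0.199),
        "SW": (0.023, 0.024, 0.234),
        "BW": (0.088, 0.070, 0.435),
    })
    #: per pair (SB-SW, SB-BW, SW-BW): component correlations
    corr_g: tuple[float, float, float] = (-0.111, 0.134, 0.041)
    corr_m: tuple[float, float, float] = (-0.003, -0.437, 0.098)
    corr_c: tuple[float, float, float] = (-0.029, 0.632, 0.362)
    #: target phenotypic correlations (residual covariances are backed out
    #: from these; the SB-SW residual covariance is 0)
    corr_p: tuple[float, float, float] = (-0.008, 0.341, 0.248)
    fixed_effects: dict[str, dict[str, tuple[float, float, float]]] = \
        field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FIXED_EFFECTS.items()})
    level_probs: dict[str, dict[str, float]] = \
        field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LEVEL_PROBS.items()})
    lactating_prob: float = 0.9      # P(lactating at mating) for parity >= 2
    litter_size_coeff: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bw_floor: float = 1.0            # grams; clamp for Gaussian tails
    seed: int = 0

    # -- derived truth ----------------------------------------------------
    def phenotypic_variances(self) -> np.ndarray:
        """Total variance per trait: liability traits have residual 1, so
        P = 1/(1 - h2 - m2 - c2); BW uses the configured phenotypic SD."""
        out = []
        for trait in TRAITS:
            h2, m2, c2 = self.fractions[trait]
            resid = 1.0 - h2 - m2 - c2
            if resid <= 0:
                raise ValueError(f"{trait}: fractions must sum to < 1")
            out.append(1.0 / resid if trait != "BW" else self.bw_sd ** 2)
        return np.array(out)

    def covariance_set(self) -> CovarianceSet:
        """True (G0, M0, C0, R0) implied by fractions and correlations."""
        p = self.phenotypic_variances()
        pairs = [(0, 1), (0, 2), (1, 2)]

        def build(idx: int, corr) -> np.ndarray:
            d = np.array([self.fractions[t][idx] * p[k] for k, t in enumerate(TRAITS)])
            mat = np.diag(d)
            for r, (i, j) in zip(corr, pairs):
                mat[i, j] = mat[j, i] = r * np.sqrt(d[i] * d[j])
            return mat

        g0 = build(0, self.corr_g)
        m0 = build(1, self.corr_m)
        c0 = build(2, self.corr_c)
        e_var = p - np.diag(g0) - np.diag(m0) - np.diag(c0)
        r0 = np.diag(e_var)
        for k, (i, j) in enumerate(pairs):
            if (i, j) == (0, 1):
                continue  # SB-SW residual covariance fixed at 0
            total = self.corr_p[k] * np.sqrt(p[i] * p[j])
            r0[i, j] = r0[j, i] = total - g0[i, j] - m0[i, j] - c0[i, j]
        return CovarianceSet(*(_repair_pd(x, n) for x, n in
                               ((g0, "G0"), (m0, "M0"), (c0, "C0"), (r0, "R0"))),
                             trait_names=TRAITS)

    def _expected_fixed(self) -> np.ndarray:
        """Analytic expectation of the fixed-effect contribution per trait."""
        exp = np.zeros(3)
        freq = self._level_frequencies()
        for fac, levels in self.fixed_effects.items():
            for lev, eff in levels.items():
                exp += freq[fac].get(lev, 0.0) * np.asarray(eff)
        return exp

    def _level_frequencies(self) -> dict[str, dict[str, float]]:
        freq = {k: dict(v) for k, v in self.level_probs.items()}
        freq["parity"] = {str(k + 1): 1.0 / self.parities for k in range(self.parities)}
        p_lact = (self.parities - 1) / self.parities * self.lactating_prob
        freq["lactation"] = {"lactating": p_lact, "nonlactating": 1.0 - p_lact}
        return freq

    def intercepts(self) -> np.ndarray:
        """Trait intercepts hitting the target survival rates (probit scale)
        and birth-weight mean, net of the expected fixed contribution."""
        p = self.phenotypic_variances()
        exp_fixed = self._expected_fixed()
        mean_ls = self._mean_litter_size()
        ls_adj = np.asarray(self.litter_size_coeff) * mean_ls
        return np.array([
            norm.ppf(self.survival_birth) * np.sqrt(p[0]),
            norm.ppf(self.survival_weaning) * np.sqrt(p[1]),
            self.bw_mean,
        ]) - exp_fixed - ls_adj

    def _mean_litter_size(self) -> float:
        # mean of round(N(mu, sd)) truncated at >= 1, by quadrature
        ks = np.arange(1, int(self.litter_mean + 8 * self.litter_sd))
        pk = norm.cdf((ks + 0.5 - self.litter_mean) / self.litter_sd) - \
            norm.cdf((ks - 0.5 - self.litter_mean) / self.litter_sd)
        pk[0] += norm.cdf((0.5 - self.litter_mean) / self.litter_sd)
        return float((ks * pk).sum() / pk.sum())


def _repair_pd(mat: np.ndarray, name: str) -> np.ndarray:
    """Shrink off-diagonals until the matrix is positive semidefinite.

    Zero diagonal entries (a trait with no variance in this component) are
    allowed; the matrix then only needs a valid PSD square root.
    """
    mat = mat.copy()
    for _ in range(200):
        if np.all(np.linalg.eigvalsh(mat) > -1e-10):
            return mat
        off = ~np.eye(mat.shape[0], dtype=bool)
        mat[off] *= 0.95
        warnings.warn(f"{name}: shrinking off-diagonals to restore positive "
                      "semidefiniteness", stacklevel=2)
    raise ValueError(f"{name} could not be repaired to positive semidefinite")


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    """Matrix square root for PSD covariance (Cholesky when PD)."""
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(mat)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Founder bucks and does plus their kits over ``cfg.parities`` parities.

    Returns ``(pedigree, litters)`` where litters is a list of dicts with the
    litter id, dam, sire, parity, litter-level factor levels and kit ids.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    anc_s = [f"GS{i + 1:03d}" for i in range(cfg.n_anc_sires)]
    anc_d = [f"GD{i + 1:03d}" for i in range(cfg.n_anc_dams)]
    sires = [f"S{i + 1:03d}" for i in range(cfg.n_sires)]
    does = [f"D{i + 1:03d}" for i in range(cfg.n_does)]
    ids = anc_s + anc_d + sires + does
    sire_col = ["0"] * len(anc_s + anc_d)
    dam_col = ["0"] * len(anc_s + anc_d)
    parents: dict[str, tuple[str, str]] = {}
    for animal in sires + does:
        if anc_s and anc_d:
            pair = (anc_s[rng.integers(len(anc_s))], anc_d[rng.integers(len(anc_d))])
        else:
            pair = ("0", "0")
        parents[animal] = pair
        sire_col.append(pair[0])
        dam_col.append(pair[1])

    def unrelated(buck: str, doe: str) -> bool:
        return not set(parents.get(buck, ())) & set(parents.get(doe, ())) \
            or parents.get(buck) == ("0", "0")

    litters = []
    probs = cfg.level_probs
    for parity in range(1, cfg.parities + 1):
        for doe in does:
            if rng.random() > cfg.farrowing_rate:
                continue
            size = max(1, int(round(rng.normal(cfg.litter_mean, cfg.litter_sd))))
            sire = sires[rng.integers(len(sires))]
            for _ in range(50):  # matings avoid inbreeding
                if unrelated(sire, doe):
                    break
                sire = sires[rng.integers(len(sires))]
            lid = f"L{doe}P{parity}"
            if parity == 1:
                lact = "nonlactating"
            else:
                lact = "lactating" if rng.random() < cfg.lactating_prob else "nonlactating"
            litter = {
                "litter_id": lid, "dam": doe, "sire": sire, "parity": str(parity),
                "lactation": lact,
                "season": _pick(rng, probs["season"]),
                "nest": _pick(rng, probs["nest"]),
                "kits": [f"K{lid}_{j + 1}" for j in range(size)],
            }
            litters.append(litter)
            for kit in litter["kits"]:
                ids.append(kit)
                sire_col.append(sire)
                dam_col.append(doe)
    index = {a: i for i, a in enumerate(ids)}
    ped = Pedigree(
        ids,
        np.array([index.get(s, -1) if s != "0" else -1 for s in sire_col]),
        np.array([index.get(d, -1) if d != "0" else -1 for d in dam_col]))
    ped.f = inbreeding_coefficients(ped)
    return ped, litters


def _pick(rng, prob_by_level: dict[str, float]) -> str:
    levels = list(prob_by_level)
    p = np.array([prob_by_level[l] for l in levels], dtype=float)
    return levels[rng.choice(len(levels), p=p / p.sum())]


def simulate_genetic_effects(ped: Pedigree, cfg: SimConfig,
                             rng: np.random.Generator | None = None):
    """Breeding values by Mendelian sampling down the sorted pedigree,
    plus iid maternal (per doe) and litter effect draws.

    Founders get a ~ N(0, G0); an offspring gets the parent average plus a
    Mendelian deviation ~ N(0, 0.5 * (1 - (F_s + F_d)/2) * G0).  Returns
    ``(a, chol_m, chol_c)`` — the breeding-value matrix and the Cholesky
    factors used by :func:`simulate_phenotypes` for the m and c draws.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    cov = cfg.covariance_set()
    n = len(ped)
    f = ped.f if ped.f is not None else inbreeding_coefficients(ped)
    lg = _psd_sqrt(cov.g0)
    mend = _mendelian_variances(ped.sire, ped.dam, f)
    a = np.zeros((n, 3))
    z = rng.standard_normal((n, 3))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        pa = np.zeros(3)
        if s >= 0:
            pa += 0.5 * a[s]
        if d >= 0:
            pa += 0.5 * a[d]
        a[i] = pa + np.sqrt(mend[i]) * (lg @ z[i])
    return a, _psd_sqrt(cov.m0), _psd_sqrt(cov.c0)


def simulate_phenotypes(ped: Pedigree, litters, a: np.ndarray,
                        chol_m: np.ndarray, chol_c: np.ndarray,
                        cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> list[KitRecord]:
    """Kit records from the latent three-trait model.

    SB is alive iff its latent exceeds 0; SW is generated only for kits alive
    at birth (dead kits carry the missing code); BW is the Gaussian latent
    clamped at ``cfg.bw_floor`` grams.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    cov = cfg.covariance_set()
    lr = _psd_sqrt(cov.r0)
    icept = cfg.intercepts()
    effects = cfg.fixed_effects
    ls_coef = np.asarray(cfg.litter_size_coeff)
    probs = cfg.level_probs
    m_by_doe: dict[str, np.ndarray] = {}
    recs: list[KitRecord] = []
    for lit in litters:
        doe = lit["dam"]
        if doe not in m_by_doe:
            m_by_doe[doe] = chol_m @ rng.standard_normal(3)
        m_eff = m_by_doe[doe]
        c_eff = chol_c @ rng.standard_normal(3)
        size = len(lit["kits"])
        for kit in lit["kits"]:
            levels = {
                "parity": lit["parity"], "lactation": lit["lactation"],
                "season": lit["season"], "nest": lit["nest"],
                "cannibalism": _pick(rng, probs["cannibalism"]),
                "inside_nest": _pick(rng, probs["inside_nest"]),
                "sex": _pick(rng, probs["sex"]),
            }
            fixed = icept + ls_coef * size
            for fac, lev in levels.items():
                fixed = fixed + np.asarray(effects.get(fac, {}).get(lev, (0.0, 0.0, 0.0)))
            latent = fixed + a[ped.index_of(kit)] + m_eff + c_eff \
                + lr @ rng.standard_normal(3)
            sb = CODE_ALIVE if latent[0] > 0 else CODE_DEAD
            if sb == CODE_ALIVE:
                sw = CODE_ALIVE if latent[1] > 0 else CODE_DEAD
            else:
                sw = CODE_MISSING
            recs.append(KitRecord(
                kit_id=kit, dam_id=doe, litter_id=lit["litter_id"],
                litter_size=size, sb=sb, sw=sw,
                bw=max(cfg.bw_floor, float(latent[2])), **levels))
    return recs


def simulate(cfg: SimConfig):
    """Full in-memory draw: returns (pedigree, records, truth dict)."""
    rng = np.random.default_rng(cfg.seed)
    ped, litters = simulate_pedigree(cfg, rng)
    a, lm, lc = simulate_genetic_effects(ped, cfg, rng)
    recs = simulate_phenotypes(ped, litters, a, lm, lc, cfg, rng)
    return ped, recs, truth_parameters(cfg)


def truth_parameters(cfg: SimConfig) -> dict[str, float]:
    """Every true parameter of the generator, keyed like the posterior
    trace columns (covariance entries, fractions, correlations, fixed
    effects, intercepts)."""
    cov = cfg.covariance_set()
    out: dict[str, float] = {}
    for label, mat in (("G", cov.g0), ("M", cov.m0), ("C", cov.c0), ("R", cov.r0)):
        for i in range(3):
            for j in range(i, 3):
                out[f"{label}_{TRAITS[i]}_{TRAITS[j]}"] = float(mat[i, j])
    for k, t in enumerate(TRAITS):
        h2, m2, c2 = cfg.fractions[t]
        out[f"h2_{t}"] = h2
        out[f"m2_{t}"] = m2
        out[f"c2_{t}"] = c2
    for k, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
        out[f"rg_{TRAITS[i]}_{TRAITS[j]}"] = cfg.corr_g[k]
        out[f"rm_{TRAITS[i]}_{TRAITS[j]}"] = cfg.corr_m[k]
        out[f"rc_{TRAITS[i]}_{TRAITS[j]}"] = cfg.corr_c[k]
        out[f"rp_{TRAITS[i]}_{TRAITS[j]}"] = cfg.corr_p[k]
    for k, t in enumerate(TRAITS):
        out[f"intercept_{t}"] = float(cfg.intercepts()[k])
    for fac, levels in cfg.fixed_effects.items():
        for lev, eff in levels.items():
            for k, t in enumerate(TRAITS):
                out[f"fixed_{t}_{fac}[{lev}]"] = float(eff[k])
    return out


def generate_dataset(cfg: SimConfig, out_dir) -> tuple[Path, Path, Path]:
    """Write pedigree, phenotype and truth files to ``out_dir``.

    The two data files use exactly the dialects of
    :func:`threshlin.pedigree.read_pedigree` and
    :func:`threshlin.records.read_phenotypes` and round-trip losslessly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped, recs, truth = simulate(cfg)
    ped_path = out / "pedigree.txt"
    phen_path = out / "phenotypes.csv"
    truth_path = out / "truth.txt"
    with open(ped_path, "w") as fh:
        fh.write("animal,sire,dam\n")
        for i, aid in enumerate(ped.ids):
            s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else "0"
            d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else "0"
            fh.write(f"{aid},{s},{d}\n")
    df = records_to_frame(recs)
    df["bw_g"] = df["bw_g"].map(lambda v: "" if v is None else repr(float(v)))
    df.to_csv(phen_path, index=False)
    with open(truth_path, "w") as fh:
        fh.write(f"seed = {cfg.seed}\n")
        for key, val in truth.items():
            fh.write(f"{key} = {val!r}\n")
    return ped_path, phen_path, truth_path
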