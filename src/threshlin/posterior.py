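"""Posterior summaries: derived genetic parameters, HPD intervals, sign
probabilities, Geweke convergence Z and Monte Carlo standard errors.

Derived parameters are computed per draw and then summarized (posterior mean
of the ratio, not ratio of posterior means).  For each trait t the phenotypic
variance is P_t = g_tt + m_tt + c_tt + r_tt and the reported fractions are
h2 = g_tt/P_t, m2 = m_tt/P_t, c2 = c_tt/P_t, e2 = r_tt/P_t; correlation
families are r_g, r_m, r_c on the component matrices and the phenotypic
r_p = (g_ts + m_ts + c_ts + r_ts)/sqrt(P_t P_s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_toeplitz

__all__ = [
    "PosteriorSamples", "from_raw_draws", "derive_parameters",
    "hpd95", "sign_probabilities", "geweke_z", "mcse",
    "summarize", "render_tables",
]

_FAMILIES = (("G", "h2", "rg"), ("M", "m2", "rm"), ("C", "c2", "rc"))


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws of every stored and derived parameter."""

    draws: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.draws)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(str(self.meta.get("traits", "SB,SW,BW")).split(","))

    def save(self, path) -> None:
        """Write a delimited trace: '# key = value' metadata header, then
        one tab-separated row per saved sample."""
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k} = {v}\n")
            self.draws.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        meta: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                pos = fh.tell()
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = _coerce(val.strip())
            draws = pd.read_csv(fh, sep="\t")
        return cls(draws, meta)


def _coerce(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    if v in ("True", "False"):
        return v == "True"
    return v


def derive_parameters(cov) -> dict[str, float]:
    """Derived genetic parameters from one covariance draw.

    ``cov`` needs attributes g0, m0, c0, r0 (and trait_names).  Correlations
    with a zero variance in the denominator come back as NaN.
    """
    tn = cov.trait_names
    t = len(tn)
    mats = {"G": cov.g0, "M": cov.m0, "C": cov.c0, "R": cov.r0}
    p = np.array([sum(mats[k][i, i] for k in mats) for i in range(t)])
    out: dict[str, float] = {}
    for i in range(t):
        out[f"h2_{tn[i]}"] = mats["G"][i, i] / p[i]
        out[f"m2_{tn[i]}"] = mats["M"][i, i] / p[i]
        out[f"c2_{tn[i]}"] = mats["C"][i, i] / p[i]
        out[f"e2_{tn[i]}"] = mats["R"][i, i] / p[i]
    for i in range(t):
        for j in range(i + 1, t):
            for label, _, corr in _FAMILIES:
                mat = mats[label]
                den = mat[i, i] * mat[j, j]
                out[f"{corr}_{tn[i]}_{tn[j]}"] = (
                    mat[i, j] / math.sqrt(den) if den > 0 else float("nan"))
            tot = sum(mats[k][i, j] for k in mats)
            out[f"rp_{tn[i]}_{tn[j]}"] = tot / math.sqrt(p[i] * p[j])
    return out


def from_raw_draws(raw: pd.DataFrame, meta: dict,
                   trait_names: tuple[str, ...]) -> PosteriorSamples:
    """Append derived-parameter columns to raw covariance-entry draws."""
    t = len(trait_names)
    cols = {}

    def entry(label, i, j):
        i, j = min(i, j), max(i, j)
        return raw[f"{label}_{trait_names[i]}_{trait_names[j]}"].to_numpy()

    p = [sum(entry(lbl, i, i) for lbl in "GMCR") for i in range(t)]
    for i in range(t):
        cols[f"h2_{trait_names[i]}"] = entry("G", i, i) / p[i]
        cols[f"m2_{trait_names[i]}"] = entry("M", i, i) / p[i]
        cols[f"c2_{trait_names[i]}"] = entry("C", i, i) / p[i]
        cols[f"e2_{trait_names[i]}"] = entry("R", i, i) / p[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(t):
            for j in range(i + 1, t):
                for label, _, corr in _FAMILIES:
                    den = entry(label, i, i) * entry(label, j, j)
                    cols[f"{corr}_{trait_names[i]}_{trait_names[j]}"] = np.where(
                        den > 0, entry(label, i, j) / np.sqrt(den), np.nan)
                tot = sum(entry(lbl, i, j) for lbl in "GMCR")
                cols[f"rp_{trait_names[i]}_{trait_names[j]}"] = tot / np.sqrt(p[i] * p[j])
    draws = pd.concat([raw, pd.DataFrame(cols, index=raw.index)], axis=1)
    return PosteriorSamples(draws, dict(meta))


def hpd95(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ceil(mass*n) sorted draws.

    Ties between equally short windows go to the lowest-start window.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    x = x[~np.isnan(x)]
    n = x.size
    if n == 0:
        return float("nan"), float("nan")
    k = int(math.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lowest-start) tie
    return float(x[i]), float(x[i + k - 1])


def sign_probabilities(draws) -> tuple[float, float]:
    """Empirical P(>0) and P(<0) with strict inequalities (NaNs dropped)."""
    x = np.asarray(draws, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return float("nan"), float("nan")
    return float(np.mean(x > 0)), float(np.mean(x < 0))


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero from an AR(p) fit (Yule-Walker,
    order chosen by AIC up to min(10, n/5))."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    r0 = float(xc @ xc) / n
    if r0 <= 0:
        return 0.0
    max_p = min(10, n // 5)
    acov = np.array([float(xc[:n - k] @ xc[k:]) / n for k in range(max_p + 1)])
    best_aic = n * math.log(r0)
    s0 = r0
    for p in range(1, max_p + 1):
        try:
            phi = solve_toeplitz(acov[:p], acov[1:p + 1])
        except np.linalg.LinAlgError:  # pragma: no cover
            continue
        sigma2 = acov[0] - float(phi @ acov[1:p + 1])
        if sigma2 <= 0:
            continue
        aic = n * math.log(sigma2) + 2 * p
        if aic < best_aic:
            denom = 1.0 - float(np.sum(phi))
            if abs(denom) > 1e-10:
                best_aic = aic
                s0 = sigma2 / denom ** 2
    return s0


def geweke_z(draws, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence Z: difference of early (first 10%) and late (last
    50%) window means over its spectral-density standard error.  NaN when
    either window is (numerically) constant."""
    x = np.asarray(draws, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 20:
        return float("nan")
    na = max(2, int(first * n))
    nb = max(2, int(last * n))
    xa, xb = x[:na], x[n - nb:]
    sa, sb = _spectrum0_ar(xa), _spectrum0_ar(xb)
    denom = sa / na + sb / nb
    if denom <= 0:
        return float("nan")
    return float((xa.mean() - xb.mean()) / math.sqrt(denom))


def mcse(draws) -> float:
    """Monte Carlo standard error of the mean by batch means with
    floor(sqrt(n)) batches.  A constant chain returns 0."""
    x = np.asarray(draws, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 4:
        return float("nan")
    nb = int(math.floor(math.sqrt(n)))
    bs = n // nb
    means = x[:nb * bs].reshape(nb, bs).mean(axis=1)
    return float(math.sqrt(np.var(means, ddof=1) / nb))


def summarize(samples: PosteriorSamples, *, geweke_threshold: float = 3.0,
              min_draws: int = 100) -> pd.DataFrame:
    """Per-parameter report: posterior mean, 95% HPD, sign probabilities,
    Geweke Z and MCSE, plus a flags column for convergence or undefined
    (all-NaN / constant) parameters."""
    n = len(samples)
    if n < min_draws:
        raise ValueError(f"need at least {min_draws} saved draws, have {n}")
    rows = []
    for name in samples.draws.columns:
        x = samples.draws[name].to_numpy(dtype=float)
        valid = x[~np.isnan(x)]
        flags = []
        if valid.size < x.size:
            flags.append("undefined-draws")
        lo, hi = hpd95(x)
        p_gt, p_lt = sign_probabilities(x)
        if valid.size >= 200 and np.ptp(valid) > 0:
            z = geweke_z(x)
        else:
            z = float("nan")
            flags.append("no-geweke")
        if not np.isnan(z) and abs(z) > geweke_threshold:
            flags.append("geweke")
        rows.append({
            "parameter": name,
            "mean": float(valid.mean()) if valid.size else float("nan"),
            "hpd_low": lo, "hpd_high": hi,
            "p_gt0": p_gt, "p_lt0": p_lt,
            "geweke_z": z, "mcse": mcse(x),
            "flags": ",".join(flags),
        })
    return pd.DataFrame(rows).set_index("parameter")


def _cell(report: pd.DataFrame, name: str) -> str:
    if name not in report.index:
        return ""
    r = report.loc[name]
    return f"{r['mean']:+.3f} [{r['hpd_low']:.3f}, {r['hpd_high']:.3f}]"


def render_tables(report: pd.DataFrame,
                  trait_names: tuple[str, ...] = ("SB", "SW", "BW")) -> str:
    """Triangular text tables: variance fractions on the diagonal, the
    component correlation above it (and, for the genetic table, phenotypic
    correlations below)."""
    tn = trait_names
    blocks = []
    specs = [("direct genetic (h2 diag, r_g above, r_p below)", "h2", "rg", "rp"),
             ("maternal permanent (m2 diag, r_m above)", "m2", "rm", None),
             ("common litter (c2 diag, r_c above)", "c2", "rc", None)]
    for title, diag, above, below in specs:
        lines = [title, "\t" + "\t".join(tn)]
        for i, ti in enumerate(tn):
            cells = []
            for j, tj in enumerate(tn):
                if i == j:
                    cells.append(_cell(report, f"{diag}_{ti}"))
                elif j > i:
                    cells.append(_cell(report, f"{above}_{ti}_{tj}"))
                else:
                    cells.append(_cell(report, f"{below}_{tj}_{ti}") if below else "")
            lines.append(ti + "\t" + "\t".join(cells))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
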