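"""Kit phenotype records: survival coding, design matrices, summaries.

Three traits are modelled jointly, in fixed order: survival at birth (SB) and
survival at weaning (SW) as threshold traits on an underlying liability
scale, and individual birth weight (BW, grams) as a Gaussian trait.  Survival
codes follow the 0/1/2 convention: 0 missing, 1 dead, 2 alive; a kit dead at
birth has its weaning record treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import Pedigree

TRAITS = ("SB", "SW", "BW")
CODE_MISSING, CODE_DEAD, CODE_ALIVE, CODE_OBSERVED = 0, 1, 2, 3

#: factor name -> ordered levels; the first level is the reference
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "parity": ("1", "2", "3"),
    "lactation": ("lactating", "nonlactating"),
    "season": ("summer", "autumn"),
    "nest": ("bad", "intermediate", "excellent"),
    "cannibalism": ("no", "yes"),
    "inside_nest": ("yes", "no"),
    "sex": ("male", "female"),
}

PHENOTYPE_COLUMNS = ("kit", "dam", "litter", "parity", "lactation", "season",
                     "nest", "cannibalism", "inside_nest", "sex",
                     "litter_size", "sb", "sw", "bw_g")

__all__ = [
    "KitRecord", "ModelSpec", "DesignMatrices", "RecordError",
    "read_phenotypes", "records_to_frame", "code_survival", "build_design",
    "summarize_dataset", "DatasetSummary", "TRAITS",
    "CODE_MISSING", "CODE_DEAD", "CODE_ALIVE", "CODE_OBSERVED",
]


class RecordError(ValueError):
    """Raised for malformed phenotype records."""


@dataclass
class KitRecord:
    """One kit's phenotypes and fixed-effect levels."""

    kit_id: str
    dam_id: str
    litter_id: str
    parity: str
    lactation: str
    season: str
    nest: str
    cannibalism: str
    inside_nest: str
    sex: str
    litter_size: int
    sb: int
    sw: int
    bw: float | None  # grams; None if not weighed

    def __post_init__(self) -> None:
        for name in FACTOR_LEVELS:
            val = getattr(self, name)
            if val not in FACTOR_LEVELS[name]:
                raise RecordError(
                    f"kit {self.kit_id!r}: unknown {name} level {val!r} "
                    f"(expected one of {FACTOR_LEVELS[name]})")
        if self.sb not in (0, 1, 2) or self.sw not in (0, 1, 2):
            raise RecordError(f"kit {self.kit_id!r}: survival codes must be 0/1/2")
        if self.sb == CODE_DEAD and self.sw != CODE_MISSING:
            raise RecordError(
                f"kit {self.kit_id!r}: dead at birth but sw={self.sw}; "
                "weaning survival must be coded missing (0)")
        if self.bw is not None and self.bw < 0:
            raise RecordError(f"kit {self.kit_id!r}: negative birth weight")


def code_survival(born_alive: bool, alive_at_weaning: bool | None) -> tuple[int, int]:
    """Translate survival outcomes into the 0/1/2 trait codes.

    Dead at birth -> (1, 0): the weaning trait is a missing observation.
    Born alive -> (2, 1) if lost while nursing, (2, 2) if weaned.
    """
    if not born_alive:
        if alive_at_weaning is not None:
            raise RecordError("weaning outcome given for a kit born dead")
        return CODE_DEAD, CODE_MISSING
    if alive_at_weaning is None:
        return CODE_ALIVE, CODE_MISSING
    return CODE_ALIVE, (CODE_ALIVE if alive_at_weaning else CODE_DEAD)


def read_phenotypes(path) -> list[KitRecord]:
    """Read a delimited kit phenotype file (named header columns).

    Litter sizes are recomputed as the number of kits sharing a litter id and
    cross-checked against the file's column when present.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing_cols = {"kit", "dam", "litter"} - set(df.columns)
    if missing_cols:
        raise RecordError(f"phenotype file lacks columns: {sorted(missing_cols)}")
    counts = df["litter"].value_counts()
    recs: list[KitRecord] = []
    for _, row in df.iterrows():
        n_litter = int(counts[row["litter"]])
        if "litter_size" in df.columns and not _blank(row.get("litter_size")):
            declared = int(row["litter_size"])
            if declared != n_litter:
                raise RecordError(
                    f"litter {row['litter']!r}: declared size {declared} but "
                    f"{n_litter} kits share the litter id")
        bw_cell = row.get("bw_g")
        recs.append(KitRecord(
            kit_id=row["kit"], dam_id=row["dam"], litter_id=row["litter"],
            parity=str(row["parity"]).strip(),
            lactation=row["lactation"].strip(),
            season=row["season"].strip(), nest=row["nest"].strip(),
            cannibalism=row["cannibalism"].strip(),
            inside_nest=row["inside_nest"].strip(), sex=row["sex"].strip(),
            litter_size=n_litter,
            sb=int(row["sb"]), sw=int(row["sw"]),
            bw=None if _blank(bw_cell) else float(bw_cell)))
    return recs


def _blank(cell) -> bool:
    return cell is None or (isinstance(cell, float) and np.isnan(cell)) \
        or str(cell).strip() in ("", "nan", "NA")


def records_to_frame(records: list[KitRecord]) -> pd.DataFrame:
    """Tabular view of a record list (column order of the file dialect)."""
    return pd.DataFrame({
        "kit": [r.kit_id for r in records],
        "dam": [r.dam_id for r in records],
        "litter": [r.litter_id for r in records],
        "parity": [r.parity for r in records],
        "lactation": [r.lactation for r in records],
        "season": [r.season for r in records],
        "nest": [r.nest for r in records],
        "cannibalism": [r.cannibalism for r in records],
        "inside_nest": [r.inside_nest for r in records],
        "sex": [r.sex for r in records],
        "litter_size": [r.litter_size for r in records],
        "sb": [r.sb for r in records],
        "sw": [r.sw for r in records],
        "bw_g": [r.bw for r in records],
    })


@dataclass
class ModelSpec:
    """Model configuration: trait list and shared fixed effects.

    The trait list is fixed at (SB, SW, BW).  ``adjust_for_litter_size`` adds
    total number born as a centered linear covariate to every trait.
    """

    adjust_for_litter_size: bool = False
    factors: tuple[str, ...] = tuple(FACTOR_LEVELS)


@dataclass
class DesignMatrices:
    """Assembled model terms for the sampler.

    ``y`` holds one row per kit and one column per trait; liability columns
    carry the status codes in ``status`` (0 missing / 1 dead / 2 alive), the
    Gaussian column uses 3 for an observed cell.  ``x`` is the shared
    fixed-effect incidence (reference coding, per-trait intercept applied by
    the sampler); ``kit_animal``/``kit_dam``/``kit_litter`` are the Z/W/V
    incidence index vectors.
    """

    y: np.ndarray                    # (n_kits, n_traits) observed values (NaN where latent)
    status: np.ndarray               # (n_kits, n_traits) int codes
    is_binary: np.ndarray            # (n_traits,) bool
    x: sparse.csr_matrix             # (n_kits, n_fixed)
    x_names: list[str]
    kit_animal: np.ndarray           # (n_kits,) index into pedigree
    kit_dam: np.ndarray              # (n_kits,) index into doe_ids
    kit_litter: np.ndarray           # (n_kits,) index into litter_ids
    doe_ids: list[str]
    litter_ids: list[str]
    trait_names: tuple[str, ...] = TRAITS

    @property
    def n_kits(self) -> int:
        return self.y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.y.shape[1]


def build_design(records: list[KitRecord], ped: Pedigree,
                 spec: ModelSpec | None = None) -> DesignMatrices:
    """Build the y = Xb + Za + Wm + Vc + e design from records and pedigree.

    X uses drop-first reference coding per factor plus an intercept; Z indexes
    every pedigree animal (ancestors without records included); W indexes
    does, V litters.  Each litter must belong to exactly one dam.
    """
    spec = spec or ModelSpec()
    n = len(records)
    if n == 0:
        raise RecordError("no records")

    for r in records:
        if r.kit_id not in ped._index:
            raise RecordError(f"kit {r.kit_id!r} absent from pedigree")

    litter_dam: dict[str, str] = {}
    for r in records:
        prev = litter_dam.setdefault(r.litter_id, r.dam_id)
        if prev != r.dam_id:
            raise RecordError(
                f"litter {r.litter_id!r} mapped to two dams ({prev!r}, {r.dam_id!r})")
    doe_ids = sorted({r.dam_id for r in records})
    litter_ids = sorted(litter_dam)
    doe_idx = {d: i for i, d in enumerate(doe_ids)}
    litter_idx = {l: i for i, l in enumerate(litter_ids)}

    rows, cols, vals = [], [], []
    names = ["intercept"]
    col_of: dict[tuple[str, str], int] = {}
    for fac in spec.factors:
        # drop-first reference coding over the observed levels; a factor with
        # one observed level is absorbed by the intercept
        observed = [lev for lev in FACTOR_LEVELS[fac]
                    if any(getattr(r, fac) == lev for r in records)]
        for lev in observed[1:]:
            col_of[(fac, lev)] = len(names)
            names.append(f"{fac}[{lev}]")
    ls_col = None
    if spec.adjust_for_litter_size:
        ls_col = len(names)
        names.append("litter_size")
        ls_mean = float(np.mean([r.litter_size for r in records]))

    for i, r in enumerate(records):
        rows.append(i); cols.append(0); vals.append(1.0)
        for fac in spec.factors:
            key = (fac, getattr(r, fac))
            if key in col_of:
                rows.append(i); cols.append(col_of[key]); vals.append(1.0)
        if ls_col is not None:
            rows.append(i); cols.append(ls_col)
            vals.append(r.litter_size - ls_mean)
    x = sparse.csr_matrix((vals, (rows, cols)), shape=(n, len(names)))

    y = np.full((n, 3), np.nan)
    status = np.zeros((n, 3), dtype=np.int64)
    for i, r in enumerate(records):
        status[i, 0] = r.sb
        status[i, 1] = r.sw
        if r.bw is not None:
            status[i, 2] = CODE_OBSERVED
            y[i, 2] = r.bw
    return DesignMatrices(
        y=y, status=status, is_binary=np.array([True, True, False]),
        x=x, x_names=names,
        kit_animal=np.array([ped.index_of(r.kit_id) for r in records]),
        kit_dam=np.array([doe_idx[r.dam_id] for r in records]),
        kit_litter=np.array([litter_idx[r.litter_id] for r in records]),
        doe_ids=doe_ids, litter_ids=litter_ids)


@dataclass
class DatasetSummary:
    """Descriptive statistics of a kit dataset (counts, means, SDs)."""

    n_kits: int
    bw_overall: tuple[int, float, float]      # n, mean, SD (dead kits included)
    bw_live: tuple[int, float, float]         # kits alive at birth
    bw_dead: tuple[int, float, float]         # kits dead at birth
    litter_born: tuple[int, float, float]     # litters: n, mean born, SD
    litter_born_alive: tuple[int, float, float]
    litter_weaned: tuple[int, float, float]
    survival_birth_pct: float                 # born alive / total born * 100
    survival_weaning_pct: float               # weaned / born alive * 100
    bw_by_factor: pd.DataFrame                # live/dead BW means per factor level

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        rows = [
            ("birth weight, all kits (g)",) + self.bw_overall,
            ("birth weight, live kits (g)",) + self.bw_live,
            ("birth weight, dead kits (g)",) + self.bw_dead,
            ("kits born per litter",) + self.litter_born,
            ("kits born alive per litter",) + self.litter_born_alive,
            ("kits weaned per litter",) + self.litter_weaned,
        ]
        out = [f"{t:34s} n={n:5d} mean={m:7.2f} sd={s:6.2f}" for t, n, m, s in rows]
        out.append(f"survival at birth:   {self.survival_birth_pct:.2f}%")
        out.append(f"survival at weaning: {self.survival_weaning_pct:.2f}%")
        return "\n".join(out)


def _msd(values) -> tuple[int, float, float]:
    v = np.asarray([x for x in values if x is not None], dtype=float)
    if v.size == 0:
        return 0, float("nan"), float("nan")
    return int(v.size), float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


def summarize_dataset(records: list[KitRecord]) -> DatasetSummary:
    """Descriptive summary: birth-weight and litter-size means/SDs, survival
    percentages, and live/dead birth weight by every fixed-effect level."""
    if not records:
        raise RecordError("no records to summarize")
    live = [r for r in records if r.sb == CODE_ALIVE]
    dead = [r for r in records if r.sb == CODE_DEAD]
    weaned = [r for r in records if r.sw == CODE_ALIVE]

    litters: dict[str, list[KitRecord]] = {}
    for r in records:
        litters.setdefault(r.litter_id, []).append(r)
    born = [len(v) for v in litters.values()]
    born_alive = [sum(1 for r in v if r.sb == CODE_ALIVE) for v in litters.values()]
    n_weaned = [sum(1 for r in v if r.sw == CODE_ALIVE) for v in litters.values()]

    tab_rows = []
    for fac, levels in FACTOR_LEVELS.items():
        for lev in levels:
            sub = [r for r in records if getattr(r, fac) == lev]
            nl, ml, _ = _msd([r.bw for r in sub if r.sb == CODE_ALIVE])
            nd, md, _ = _msd([r.bw for r in sub if r.sb == CODE_DEAD])
            tab_rows.append({"factor": fac, "level": lev,
                             "n_live": nl, "bw_live": ml,
                             "n_dead": nd, "bw_dead": md})

    sb_pct = 100.0 * len(live) / (len(live) + len(dead)) if (live or dead) else float("nan")
    sw_pct = 100.0 * len(weaned) / len(live) if live else float("nan")
    return DatasetSummary(
        n_kits=len(records),
        bw_overall=_msd([r.bw for r in records]),
        bw_live=_msd([r.bw for r in live]),
        bw_dead=_msd([r.bw for r in dead]),
        litter_born=_msd(born),
        litter_born_alive=_msd(born_alive),
        litter_weaned=_msd(n_weaned),
        survival_birth_pct=sb_pct,
        survival_weaning_pct=sw_pct,
        bw_by_factor=pd.DataFrame(tab_rows))
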