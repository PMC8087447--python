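"""Mutation-distance correlation stage.

Joins the packaged table of ALS disease mutants -- mutation-site distances to
the Zn and Cu centers and OPM-derived membrane binding energies -- with
patient survival times, and quantifies the linear trends: membrane binding
energy weakens (becomes less negative) as the mutation site moves away from
the Zn center, while the Cu-site distance carries no comparable signal, and
survival time after diagnosis increases with Zn-site distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MUTANT_COLUMNS = ["mutant", "d_zn_A", "d_cu_A", "dG_kcal_mol"]


@dataclass(frozen=True)
class MutantRecord:
    mutant: str
    d_zn: float  # A
    d_cu: float  # A
    dG_membrane: float  # kcal/mol (water -> bilayer transfer)
    survival: float | None = None  # years after diagnosis


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    pearson_r: float
    n: int
    p_value: float  # two-sided t-test on r; reported, never a gate


def _packaged(name: str):
    return resources.files("sodscape.data").joinpath(name)


def load_table5(path=None) -> list[MutantRecord]:
    """Load the disease-mutant table (packaged fixture by default)."""
    src = path if path is not None else _packaged("sod1_mutants.csv")
    df = pd.read_csv(src)
    if df.empty:
        raise ValueError("mutant table is empty")
    missing = [c for c in MUTANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutant table missing columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            rec = MutantRecord(
                mutant=str(row["mutant"]),
                d_zn=float(row["d_zn_A"]),
                d_cu=float(row["d_cu_A"]),
                dG_membrane=float(row["dG_kcal_mol"]),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed row {idx} ({row.to_dict()}): {exc}") from exc
        if rec.d_zn <= 0 or rec.d_cu <= 0:
            raise ValueError(f"row {rec.mutant}: distances must be positive")
        records.append(rec)
    return records


def load_survival(path=None) -> dict[str, float]:
    """Survival times (years) keyed by mutant id; packaged trio by default."""
    src = path if path is not None else _packaged("survival_times.csv")
    df = pd.read_csv(src)
    return dict(zip(df["mutant"].astype(str), df["survival_years"].astype(float)))


def records_frame(records: list[MutantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.mutant, r.d_zn, r.d_cu, r.dG_membrane, r.survival) for r in records],
        columns=["mutant", "d_zn_A", "d_cu_A", "dG_kcal_mol", "survival_years"],
    )


def trend(x, y) -> TrendFit:
    """Ordinary least squares with Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("trend needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n=int(x.size),
        p_value=float(fit.pvalue),
    )


def distance_energy_trends(records: list[MutantRecord]) -> dict[str, TrendFit]:
    """Trends of membrane binding energy against Zn- and Cu-site distances."""
    dzn = [r.d_zn for r in records]
    dcu = [r.d_cu for r in records]
    dg = [r.dG_membrane for r in records]
    return {"zn": trend(dzn, dg), "cu": trend(dcu, dg)}


def severity_join(
    records: list[MutantRecord], survival: dict[str, float]
) -> TrendFit:
    """Trend of survival time (years) against Zn-site distance for the
    mutants present in both tables; duplicates deduplicated, unmatched ids
    skipped with a log message."""
    seen: dict[str, MutantRecord] = {}
    for r in records:
        if r.mutant in seen:
            logger.warning("duplicate mutant %s; keeping first occurrence", r.mutant)
            continue
        seen[r.mutant] = r
    xs, ys = [], []
    for mut, years in survival.items():
        rec = seen.get(mut)
        if rec is None:
            logger.warning("survival entry %s has no distance record; skipped", mut)
            continue
        xs.append(rec.d_zn)
        ys.append(float(years))
    if len(xs) < 3:
        raise ValueError("need at least 3 matched mutants for a severity trend")
    return trend(xs, ys)
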