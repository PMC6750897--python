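"""Per-mutant growth rates and per-site fitness effects from pooled
turbidostat competition sequencing.

The input is a count table: one row per single-codon mutant (plus the
wild-type row), one column per sampling time (hours).  During exponential
competition the log ratio of mutant to wild-type reads is linear in time,

    ln R_t = (m_i - m_wt) * t + ln R_0,

so the OLS slope of ``ln(count_mut / count_wt)`` estimates the growth
rate difference in 1/h.  Dividing the slope by the turbidostat dilution
rate (1.37/h, the number of e-folds of growth per hour) converts it to a
relative growth difference: -0.10 means 10% slower than wild type.

Filtering follows the measurement protocol: time points where a mutant
has fewer than ``min_reads`` reads are dropped for that mutant, and a
mutant is only estimated if at least ``min_points`` time points survive.
Counts are median-normalized within mutagenesis batches (10 consecutive
codons share one batch) before estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InsufficientDataError

__all__ = [
    "MageCountTable",
    "DEFAULT_DILUTION_PER_HOUR",
    "median_normalize",
    "relative_growth_rates",
    "site_fitness_profile",
    "split_half_consistency",
]

#: Average turbidostat dilution rate: e-folds of population growth per hour.
DEFAULT_DILUTION_PER_HOUR = 1.37

WT_ID = "WT"

META_COLUMNS = ("mutant_id", "position", "codon", "aa", "wt_aa", "batch")

STOP_AA = "*"


@dataclass
class MageCountTable:
    """Mutant x time-point read counts.

    ``df`` columns: mutant_id, position, codon, aa, wt_aa, batch, then one
    column per sampling time; ``times`` are those column labels as floats
    (hours), strictly increasing.  Row with ``mutant_id == "WT"`` is the
    wild-type reference.
    """

    df: pd.DataFrame
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        missing = set(META_COLUMNS) - set(self.df.columns)
        if missing:
            raise ConfigurationError(f"count table missing columns: {sorted(missing)}")
        if WT_ID not in set(self.df["mutant_id"]):
            raise ConfigurationError("count table must contain a WT row")
        if list(self.times) != sorted(set(self.times)):
            raise ConfigurationError("sampling times must be strictly increasing")
        for t in self.times:
            if self.time_col(t) not in self.df.columns:
                raise ConfigurationError(f"missing count column for time {t}")

    @staticmethod
    def time_col(t: float) -> str:
        return f"t{t:g}"

    @property
    def count_columns(self) -> list[str]:
        return [self.time_col(t) for t in self.times]

    def counts(self) -> np.ndarray:
        return self.df[self.count_columns].to_numpy(dtype=float)

    def wt_counts(self) -> np.ndarray:
        row = self.df[self.df["mutant_id"] == WT_ID]
        return row[self.count_columns].to_numpy(dtype=float)[0]

    @classmethod
    def from_tsv(cls, path) -> "MageCountTable":
        df = pd.read_csv(path, sep="\t")
        times = tuple(
            sorted(float(c[1:]) for c in df.columns if c.startswith("t") and c[1:].replace(".", "", 1).isdigit())
        )
        return cls(df=df, times=times)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def median_normalize(table: MageCountTable) -> MageCountTable:
    """Normalize counts within each (time point, mutagenesis batch).

    Counts in a batch are divided by the batch median and rescaled so the
    batch total is preserved; this removes batch-level abundance offsets
    introduced by performing mutagenesis in batches of 10 codons.  The WT
    row is untouched.  Batches with a zero median at some time point are
    left unnormalized there (flagged in the returned table's attrs).
    """
    df = table.df.copy()
    flagged: list[tuple[object, float]] = []
    is_wt = df["mutant_id"] == WT_ID
    for col in table.count_columns:
        for batch, idx in df[~is_wt].groupby("batch").groups.items():
            vals = df.loc[idx, col].to_numpy(dtype=float)
            med = np.median(vals)
            if med == 0:
                flagged.append((batch, col))
                continue
            scaled = vals / med
            total = vals.sum()
            if scaled.sum() > 0:
                scaled *= total / scaled.sum()
            df.loc[idx, col] = scaled
    out = MageCountTable(df=df, times=table.times)
    out.df.attrs["zero_median_batches"] = flagged
    return out


def relative_growth_rates(
    table: MageCountTable,
    dilution: float = DEFAULT_DILUTION_PER_HOUR,
    min_points: int = 5,
    min_reads: int = 20,
) -> pd.DataFrame:
    """Estimate each mutant's growth-rate difference from the WT.

    Returns one row per non-WT mutant: OLS ``slope`` of ln(mut/WT) in
    1/h over the time points where the mutant has at least ``min_reads``
    reads, ``relative_growth`` = slope / dilution, ``n_usable_timepoints``
    and a ``filtered`` flag (True when fewer than ``min_points`` time
    points qualify; such mutants carry no estimate).

    Time points where the WT count is zero are dropped for all mutants.
    """
    times = np.asarray(table.times, dtype=float)
    wt = table.wt_counts()
    usable_t = wt > 0
    meta = table.df[table.df["mutant_id"] != WT_ID]
    counts = meta[table.count_columns].to_numpy(dtype=float)
    rows = []
    for (_, m), c in zip(meta.iterrows(), counts):
        ok = usable_t & (c >= min_reads)
        n_ok = int(ok.sum())
        if n_ok < min_points:
            slope = rel = np.nan
            filtered = True
        else:
            y = np.log(c[ok] / wt[ok])
            slope = float(np.polyfit(times[ok], y, 1)[0])
            rel = slope / dilution
            filtered = False
        rows.append(
            {
                "mutant_id": m["mutant_id"],
                "position": m["position"],
                "codon": m["codon"],
                "aa": m["aa"],
                "wt_aa": m["wt_aa"],
                "slope": slope,
                "relative_growth": rel,
                "n_usable_timepoints": n_ok,
                "filtered": filtered,
            }
        )
    return pd.DataFrame(rows)


def site_fitness_profile(
    growth: pd.DataFrame,
    *,
    exclude_synonymous: bool = True,
    exclude_nonsense: bool = False,
) -> pd.DataFrame:
    """Mean fitness effect of substitutions per protein site.

    Two-stage average: codon-level relative growth rates are first
    collapsed to one value per (site, amino-acid change), then averaged
    (unweighted) across the site's observed amino-acid substitutions.
    Synonymous changes (mutant aa equal to the WT residue) are excluded
    from the site mean by default; nonsense changes can be excluded too
    (they are reported separately either way via ``aa == "*"``).  Sites
    with no estimated substitutions get NaN.
    """
    g = growth[~growth["filtered"]].copy()
    if exclude_synonymous:
        g = g[g["aa"] != g["wt_aa"]]
    if exclude_nonsense:
        g = g[g["aa"] != STOP_AA]
    all_positions = sorted(growth["position"].unique())
    if g.empty:
        return pd.DataFrame(
            {
                "position": all_positions,
                "mean_fitness": np.nan,
                "n_aa": np.zeros(len(all_positions), dtype=int),
            }
        )
    per_aa = (
        g.groupby(["position", "aa"])["relative_growth"].mean().reset_index()
    )
    site = per_aa.groupby("position")["relative_growth"].agg(["mean", "count"]).reset_index()
    site.columns = ["position", "mean_fitness", "n_aa"]
    site = site.set_index("position").reindex(all_positions).reset_index()
    site["n_aa"] = site["n_aa"].fillna(0).astype(int)
    return site


def split_half_consistency(
    table: MageCountTable,
    seed: int = 0,
    dilution: float = DEFAULT_DILUTION_PER_HOUR,
    min_points: int = 5,
    min_reads: int = 20,
) -> dict:
    """Reproducibility check: Pearson correlation between site-fitness
    profiles computed from two random non-overlapping halves of the codon
    alphabet (32 codons each out of the 64 possible)."""
    rng = np.random.default_rng(seed)
    codons = sorted({c for c in table.df["codon"] if isinstance(c, str) and c != ""} - {"WT"})
    perm = rng.permutation(len(codons))
    half_a = {codons[i] for i in perm[: len(codons) // 2]}
    growth = relative_growth_rates(table, dilution=dilution, min_points=min_points, min_reads=min_reads)
    prof_a = site_fitness_profile(growth[growth["codon"].isin(half_a)])
    prof_b = site_fitness_profile(growth[~growth["codon"].isin(half_a)])
    merged = prof_a.merge(prof_b, on="position", suffixes=("_a", "_b")).dropna(
        subset=["mean_fitness_a", "mean_fitness_b"]
    )
    if len(merged) < 3:
        raise InsufficientDataError("fewer than 3 sites with both half-profiles defined")
    r = float(np.corrcoef(merged["mean_fitness_a"], merged["mean_fitness_b"])[0, 1])
    return {"pearson_r": r, "n_sites": len(merged), "half_a_codons": sorted(half_a)}
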