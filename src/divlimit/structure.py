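"""Structural divergence summaries: Kabsch RMSD, RMSD-vs-time trends,
and comparisons across levels of functional conservation.

Structure-pair records (RMSD in Å, divergence time in Gy, alignment
coverage, functional group) are consumed as tidy tables; the structural
alignments themselves (TM-align / FATCAT style) are precomputed inputs.
Pairs whose flexible alignment splits into multiple domains should be
dropped upstream or flagged in a boolean ``flexible`` column, which
:func:`coverage_filter` also honors.

Functional groups follow the EC hierarchy: ``full_EC`` (all four digits
shared, same reaction), ``three_digit_EC`` (only the substrate/cofactor
class shared), ``fold_only`` (same fold, unrelated activities).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "kabsch_rmsd",
    "coverage_filter",
    "long_term_filter",
    "rmsd_time_trend",
    "functional_group_comparison",
    "identity_by_structure_bins",
]


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD (Å) between two matched Cα coordinate sets over rigid
    rotation and translation (Kabsch superposition via SVD, with the
    determinant correction that excludes reflections)."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise InvalidParameterError("coordinate sets must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise InvalidParameterError("need at least 3 matched positions")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    if np.linalg.matrix_rank(H) < 2:
        warnings.warn("degenerate (collinear) coordinate set; RMSD may be ill-conditioned")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ Ac.T).T - Bc
    return float(np.sqrt((diff**2).sum() / n))


def coverage_filter(records: pd.DataFrame, max_unaligned: float = 0.7) -> pd.DataFrame:
    """Drop structure pairs where more than ``max_unaligned`` of the
    shorter protein could not be structurally aligned (i.e. keep
    ``coverage >= 1 - max_unaligned``); also drops rows flagged
    ``flexible`` when that column is present."""
    out = records[records["coverage"] >= 1.0 - max_unaligned - 1e-12]
    if "flexible" in out.columns:
        out = out[~out["flexible"].astype(bool)]
    return out.reset_index(drop=True)


def long_term_filter(records: pd.DataFrame, min_time: float = 2.0) -> pd.DataFrame:
    """Keep only pairs from species that diverged more than ``min_time``
    Gy ago (the long-term divergence regime)."""
    return records[records["time"] > min_time].reset_index(drop=True)


def rmsd_time_trend(
    records: pd.DataFrame,
    bin_edges: Sequence[float],
    window: int = 51,
) -> dict:
    """RMSD as a function of divergence time.

    Returns Spearman's rank correlation (rho, p) over all pairs, per-bin
    median / 25-75 / 5-95 percentiles, and a centered moving average
    (window in records) over the time-sorted values.
    """
    if len(records) < 3:
        raise InsufficientDataError("need >= 3 records for a trend")
    t = records["time"].to_numpy(dtype=float)
    r = records["rmsd"].to_numpy(dtype=float)
    if np.unique(t).size < 2:
        raise InsufficientDataError("all divergence times tied; Spearman undefined")
    rho, p = stats.spearmanr(t, r)
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        vals = r[(t >= lo) & (t < hi)]
        rows.append(
            {
                "time_lo": lo,
                "time_hi": hi,
                "n": int(vals.size),
                "median": np.median(vals) if vals.size else np.nan,
                "q25": np.percentile(vals, 25) if vals.size else np.nan,
                "q75": np.percentile(vals, 75) if vals.size else np.nan,
                "q05": np.percentile(vals, 5) if vals.size else np.nan,
                "q95": np.percentile(vals, 95) if vals.size else np.nan,
            }
        )
    order = np.argsort(t, kind="stable")
    moving = (
        pd.Series(r[order]).rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    )
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(p),
        "bins": pd.DataFrame(rows),
        "moving_average": pd.DataFrame(
            {"time": t[order], "rmsd_moving_average": moving}
        ),
    }


def functional_group_comparison(
    values_by_group: Mapping[str, Sequence[float]],
    metric: str = "value",
) -> dict:
    """Compare a divergence metric across functional-conservation groups.

    Per-group mean / median / n, plus a two-sided Mann-Whitney U test for
    every pair of groups.  Groups with fewer than 2 values are excluded
    with a warning.
    """
    groups = {}
    for name, vals in values_by_group.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size < 2:
            warnings.warn(f"group {name!r} has < 2 values; excluded")
            continue
        groups[name] = v
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups with >= 2 values each")
    summaries = pd.DataFrame(
        [
            {
                "group": name,
                "n": v.size,
                "mean": float(v.mean()),
                "median": float(np.median(v)),
            }
            for name, v in groups.items()
        ]
    )
    tests = []
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            u, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            tests.append({"group_a": a, "group_b": b, "U": float(u), "pvalue": float(p)})
    return {"metric": metric, "summaries": summaries, "tests": pd.DataFrame(tests)}


def identity_by_structure_bins(
    records: pd.DataFrame,
    rmsd_bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Sequence identity of functional groups compared at matched levels
    of structural divergence.

    ``records`` needs columns identity, rmsd, group.  Within each RMSD
    bin (left-closed, right-open) the groups' identities are summarized
    and compared by Mann-Whitney.  Bins where fewer than two groups have
    data are emitted with NaN p-values.
    """
    edges = np.asarray(rmsd_bin_edges, dtype=float)
    rows = []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        sub = records[(records["rmsd"] >= lo) & (records["rmsd"] < hi)]
        by_group = {g: d["identity"].to_numpy() for g, d in sub.groupby("group")}
        by_group = {g: v for g, v in by_group.items() if v.size >= 2}
        if len(by_group) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = functional_group_comparison(by_group, metric="identity")
            for _, s in comp["summaries"].iterrows():
                test_p = np.nan
                t = comp["tests"]
                others = t[(t["group_a"] == s["group"]) | (t["group_b"] == s["group"])]
                if len(others):
                    test_p = float(others["pvalue"].min())
                rows.append(
                    {
                        "rmsd_lo": lo,
                        "rmsd_hi": hi,
                        "group": s["group"],
                        "n": int(s["n"]),
                        "mean_identity": s["mean"],
                        "median_identity": s["median"],
                        "min_pairwise_mwu_p": test_p,
                    }
                )
        else:
            for g, v in by_group.items():
                rows.append(
                    {
                        "rmsd_lo": lo,
                        "rmsd_hi": hi,
                        "group": g,
                        "n": int(v.size),
                        "mean_identity": float(v.mean()),
                        "median_identity": float(np.median(v)),
                        "min_pairwise_mwu_p": np.nan,
                    }
                )
    return pd.DataFrame(rows)
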