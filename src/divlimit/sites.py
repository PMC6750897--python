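"""Per-site conservation and stratified divergence analyses.

All site-level statistics live on the 1-based coordinate system of an
ungapped designated reference sequence in the MSA: MSA columns where the
reference carries a gap are dropped, and for any given ortholog pair a
column is excluded from that site's denominator when either member has a
gap there.

Three stratifications of the same aggregation engine:

* fitness groups — sites binned by experimentally measured mean fitness
  effect of substitutions (deep mutational scan), identity-vs-time curve
  per group;
* distance shells — sites binned by the distance of their Cα atom to the
  centroid of the active-site residues;
* conservation across phylogenetically independent ortholog pairs — the
  per-site probability of identical residues, from which the fraction of
  universally conserved sites (>= 90% of pairs identical) follows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InsufficientDataError

__all__ = [
    "SiteConservationProfile",
    "ShellMap",
    "site_identity_profile",
    "universal_site_fraction",
    "conserved_identity_share",
    "fitness_binned_divergence",
    "identity_prob_vs_fitness",
    "assign_distance_shells",
    "shell_divergence",
    "grouped_divergence",
    "read_ca_coords",
]

GAP = "-"


@dataclass
class SiteConservationProfile:
    """Per reference site: fraction of independent ortholog pairs with
    identical residues, plus the per-site pair counts (denominators)."""

    positions: np.ndarray  # 1-based reference coordinates
    fractions: np.ndarray  # in [0, 1]
    n_pairs_per_site: np.ndarray
    n_pairs: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "fraction_identical": self.fractions,
                "n_pairs": self.n_pairs_per_site,
            }
        )


@dataclass(frozen=True)
class ShellMap:
    """Per reference site: distance-shell index around the active site."""

    shells: dict[int, int]  # position -> shell index
    shell_width: float
    active_site_indices: tuple[int, ...]

    def group_map(self) -> dict[int, int]:
        return dict(self.shells)


def _reference_columns(msa: Mapping[str, str], reference_id: str) -> list[int]:
    """MSA column indices where the reference is ungapped, in order."""
    if reference_id not in msa:
        raise ConfigurationError(f"reference {reference_id!r} not in alignment")
    ref = msa[reference_id]
    return [c for c, ch in enumerate(ref) if ch != GAP]


def site_identity_profile(
    msa: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    reference_id: str,
) -> SiteConservationProfile:
    """Fraction of ortholog pairs identical at each reference site.

    ``pairs`` should come from phylogenetically independent species pairs
    (see :func:`divlimit.phylo.select_independent_pairs`).  Pairs with a
    gap in either member at a column drop out of that site's denominator.
    """
    if not pairs:
        raise InsufficientDataError("empty pair set")
    cols = _reference_columns(msa, reference_id)
    for a, b in pairs:
        if a not in msa or b not in msa:
            raise ConfigurationError(f"pair member missing from alignment: ({a}, {b})")
    ident = np.zeros(len(cols), dtype=float)
    denom = np.zeros(len(cols), dtype=float)
    for a, b in pairs:
        sa, sb = msa[a], msa[b]
        for i, c in enumerate(cols):
            x, y = sa[c], sb[c]
            if x != GAP and y != GAP:
                denom[i] += 1
                ident[i] += x == y
    with np.errstate(invalid="ignore"):
        frac = np.where(denom > 0, ident / np.maximum(denom, 1), np.nan)
    return SiteConservationProfile(
        positions=np.arange(1, len(cols) + 1),
        fractions=frac,
        n_pairs_per_site=denom.astype(int),
        n_pairs=len(pairs),
    )


def universal_site_fraction(
    profile: SiteConservationProfile, threshold: float = 0.9
) -> float:
    """Fraction of reference sites conserved in at least ``threshold`` of
    independent pairs ("universally conserved" sites at 0.9)."""
    valid = ~np.isnan(profile.fractions)
    if not valid.any():
        raise InsufficientDataError("profile has no sites with data")
    return float(np.mean(profile.fractions[valid] >= threshold))


def conserved_identity_share(universal_fraction: float, long_term_identity: float) -> float:
    """Share (%) of the observed long-term identity attributable to
    universally conserved sites: ``100 * universal_fraction /
    (long_term_identity / 100)``.

    E.g. 14% universally conserved sites against a 40% identity floor
    means those sites explain only 35% of the conserved identity.
    """
    if long_term_identity <= 0:
        raise InsufficientDataError("long-term identity must be > 0")
    return 100.0 * universal_fraction / (long_term_identity / 100.0)


# ---------------------------------------------------------------------------
# grouped identity-vs-time curves (shared engine for fitness groups & shells)


def _pair_group_identity(
    sa: str, sb: str, cols: Sequence[int], group_sites: np.ndarray
) -> float:
    """Identity (%) of one pair over a subset of reference sites (boolean
    mask over ``cols``); NaN when every masked column is gapped."""
    num = den = 0
    for i, c in enumerate(cols):
        if not group_sites[i]:
            continue
        x, y = sa[c], sb[c]
        if x != GAP and y != GAP:
            den += 1
            num += x == y
    return 100.0 * num / den if den else np.nan


def grouped_divergence(
    msa: Mapping[str, str],
    pair_times: Mapping[tuple[str, str], float],
    site_groups: Mapping[int, object],
    bin_edges_time: Sequence[float],
    reference_id: str,
) -> pd.DataFrame:
    """Identity-vs-time curves for site groups.

    ``site_groups`` maps 1-based reference positions to a group label;
    sites absent from the map are ignored.  Per ortholog pair the percent
    identity is computed over each group's sites only; pairs are then
    averaged within time bins (left-closed, right-open).  Returns a tidy
    frame (group, time_bin left edge, bin midpoint, mean/sd/sem identity,
    n pairs); empty group-bin combinations appear with NaN.
    """
    cols = _reference_columns(msa, reference_id)
    n_sites = len(cols)
    groups = sorted({g for g in site_groups.values()}, key=str)
    masks = {
        g: np.array([site_groups.get(p) == g for p in range(1, n_sites + 1)])
        for g in groups
    }
    edges = np.asarray(bin_edges_time, dtype=float)
    records = []
    per_pair = {}
    for (a, b), t in pair_times.items():
        if a not in msa or b not in msa:
            raise ConfigurationError(f"pair member missing from alignment: ({a}, {b})")
        per_pair[(a, b)] = (
            t,
            {g: _pair_group_identity(msa[a], msa[b], cols, masks[g]) for g in groups},
        )
    for g in groups:
        for k in range(len(edges) - 1):
            lo, hi = edges[k], edges[k + 1]
            vals = [
                idents[g]
                for (t, idents) in per_pair.values()
                if lo <= t < hi and not np.isnan(idents[g])
            ]
            vals = np.asarray(vals, dtype=float)
            records.append(
                {
                    "group": g,
                    "time_lo": lo,
                    "time_hi": hi,
                    "time_mid": 0.5 * (lo + hi),
                    "mean_identity": vals.mean() if vals.size else np.nan,
                    "sd_identity": vals.std(ddof=1) if vals.size > 1 else np.nan,
                    "sem_identity": (
                        vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
                    ),
                    "n_pairs": int(vals.size),
                }
            )
    return pd.DataFrame(records)


def fitness_binned_divergence(
    msa: Mapping[str, str],
    pair_times: Mapping[tuple[str, str], float],
    site_fitness: Mapping[int, float],
    bin_edges_fitness: Sequence[float] | None,
    bin_edges_time: Sequence[float],
    reference_id: str,
) -> pd.DataFrame:
    """Identity-vs-time curves for sites grouped by mean fitness effect.

    ``bin_edges_fitness=None`` uses quartiles of the site-fitness
    distribution.  Groups are labeled ``fit[lo,hi)``.
    """
    positions = sorted(site_fitness)
    fitness = np.array([site_fitness[p] for p in positions], dtype=float)
    if bin_edges_fitness is None:
        bin_edges_fitness = np.quantile(fitness, [0.0, 0.25, 0.5, 0.75, 1.0])
    edges = np.asarray(bin_edges_fitness, dtype=float)
    groups: dict[int, str] = {}
    for p, f in zip(positions, fitness):
        k = int(np.clip(np.searchsorted(edges, f, side="right") - 1, 0, len(edges) - 2))
        groups[p] = f"fit[{edges[k]:.3g},{edges[k + 1]:.3g})"
    return grouped_divergence(msa, pair_times, groups, bin_edges_time, reference_id)


def identity_prob_vs_fitness(
    profile: SiteConservationProfile,
    site_fitness: Mapping[int, float],
    fitness_bins: Sequence[float],
) -> pd.DataFrame:
    """Probability a site is identical across independent lineages, as a
    function of its measured mean fitness effect.

    ``profile`` should be computed from pairs inside the long-divergence
    window of interest (e.g. 2 +/- 0.25 Gy).  Returns per fitness bin the
    mean conservation probability with SEM across sites.
    """
    edges = np.asarray(fitness_bins, dtype=float)
    records = []
    pos_to_frac = dict(zip(profile.positions, profile.fractions))
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        vals = [
            pos_to_frac[p]
            for p, f in site_fitness.items()
            if lo <= f < hi and p in pos_to_frac and not np.isnan(pos_to_frac[p])
        ]
        vals = np.asarray(vals, dtype=float)
        records.append(
            {
                "fitness_lo": lo,
                "fitness_hi": hi,
                "fitness_mid": 0.5 * (lo + hi),
                "mean_probability": vals.mean() if vals.size else np.nan,
                "sem_probability": (
                    vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
                ),
                "n_sites": int(vals.size),
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# structural shells


def assign_distance_shells(
    ca_coords: Mapping[int, Sequence[float]],
    active_site_indices: Sequence[int],
    shell_width: float = 5.0,
) -> ShellMap:
    """Stratify sites into concentric shells around the active site.

    The active-site centroid is the mean Cα coordinate of
    ``active_site_indices``; a site's shell is
    ``floor(distance_to_centroid / shell_width)``.  Sites without
    coordinates are skipped with a warning.
    """
    if not active_site_indices:
        raise ConfigurationError("need at least one active-site residue index")
    missing_active = [i for i in active_site_indices if i not in ca_coords]
    if missing_active:
        raise ConfigurationError(f"active-site residues without coordinates: {missing_active}")
    centroid = np.mean([np.asarray(ca_coords[i], float) for i in active_site_indices], axis=0)
    shells = {}
    for pos, xyz in ca_coords.items():
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            import warnings

            warnings.warn(f"site {pos}: missing/invalid coordinates, skipped")
            continue
        d = float(np.linalg.norm(xyz - centroid))
        shells[pos] = int(d // shell_width)
    return ShellMap(
        shells=shells,
        shell_width=float(shell_width),
        active_site_indices=tuple(active_site_indices),
    )


def shell_divergence(
    msa: Mapping[str, str],
    pair_times: Mapping[tuple[str, str], float],
    shell_map: ShellMap,
    bin_edges_time: Sequence[float],
    reference_id: str,
) -> pd.DataFrame:
    """Identity-vs-time curves per distance shell (same aggregation as
    :func:`fitness_binned_divergence`, with shells as the groups)."""
    return grouped_divergence(
        msa, pair_times, shell_map.group_map(), bin_edges_time, reference_id
    )


def read_ca_coords(pdb_path, chain_id: str | None = None) -> dict[int, np.ndarray]:
    """Cα coordinates per residue number from a PDB file (first model;
    first chain unless ``chain_id`` given).  Residues lacking a Cα atom
    are skipped."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ConfigurationError(f"chain {chain_id!r} not found")
    chain = chains[0]
    coords: dict[int, np.ndarray] = {}
    for res in chain.get_residues():
        if "CA" in res:
            coords[res.id[1]] = np.asarray(res["CA"].coord, dtype=float)
    return coords
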