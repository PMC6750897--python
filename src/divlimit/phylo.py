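"""Divergence-time assignment, distance-time calibration, topology
screens, and phylogenetically independent (edge-disjoint) pair selection.

Two leaf pairs of a tree are phylogenetically independent when the paths
connecting them share no edge: substitutions accumulated along one pair's
history are then disjoint from the other's.  Site-conservation statistics
across such pairs are free of the pseudo-replication that plagues naive
all-pairs averages.  :func:`select_independent_pairs` finds a
maximum-cardinality edge-disjoint pair set within a divergence-time
window (exact search on small trees, deepest-cherry greedy on large
ones; edge-disjointness is re-verified on every output).

Trees are handled with dendropy.  Unrooted inputs are midpoint-rooted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

from .exceptions import (
    CalibrationError,
    ConfigurationError,
    InsufficientOverlapError,
)

__all__ = [
    "IndependentPairSet",
    "LinearCalibration",
    "read_tree",
    "assign_divergence_time",
    "calibrate_distance_time",
    "flag_hgt",
    "flag_ancient_duplication",
    "select_independent_pairs",
    "PROKARYOTE_EUKARYOTE_TIME_GY",
    "TACK_EUKARYOTE_TIME_GY",
]

#: Divergence time (Gy) assigned to bacteria-archaea and
#: prokaryote-eukaryote pairs (age of their last common ancestor).
PROKARYOTE_EUKARYOTE_TIME_GY = 4.0

#: Divergence time (Gy) for TACK-superphylum archaea vs eukaryotes.
TACK_EUKARYOTE_TIME_GY = 2.7

_PROKARYOTE_DOMAINS = {"bacteria", "archaea"}


def read_tree(source, *, schema: str = "newick") -> dendropy.Tree:
    """Read a tree from a path or newick string; midpoint-root if unrooted."""
    if isinstance(source, dendropy.Tree):
        tree = source
    elif isinstance(source, str) and "(" in source and ";" in source:
        tree = dendropy.Tree.get(data=source, schema=schema)
    else:
        tree = dendropy.Tree.get(path=str(source), schema=schema)
    if not tree.is_rooted:
        tree.reroot_at_midpoint(update_bipartitions=False)
        tree.is_rooted = True
    return tree


def assign_divergence_time(
    species_a: str,
    species_b: str,
    time_table: Mapping[tuple[str, str], float] | None = None,
    domain_labels: Mapping[str, str] | None = None,
    tack_taxa: Iterable[str] = (),
) -> float:
    """Divergence time (Gy) between two species.

    Same species -> 0.  Cross-domain overrides take precedence over the
    lookup table: TACK archaea vs eukaryotes -> 2.7 Gy; any other
    bacteria-archaea or prokaryote-eukaryote pair -> 4.0 Gy.  Otherwise
    the (unordered) pair is looked up in ``time_table`` (mean literature
    time per pair).
    """
    if species_a == species_b:
        return 0.0
    domain_labels = domain_labels or {}
    tack = set(tack_taxa)
    da = domain_labels.get(species_a)
    db = domain_labels.get(species_b)
    if da and db and da != db:
        pair_domains = {da, db}
        if pair_domains == {"archaea", "eukaryote"} and (
            species_a in tack or species_b in tack
        ):
            return TACK_EUKARYOTE_TIME_GY
        if "eukaryote" in pair_domains and pair_domains & _PROKARYOTE_DOMAINS:
            return PROKARYOTE_EUKARYOTE_TIME_GY
        if pair_domains == _PROKARYOTE_DOMAINS:
            return PROKARYOTE_EUKARYOTE_TIME_GY
    if time_table is not None:
        key = (species_a, species_b)
        if key in time_table:
            return float(time_table[key])
        rkey = (species_b, species_a)
        if rkey in time_table:
            return float(time_table[rkey])
    raise KeyError(f"no divergence time known for ({species_a}, {species_b})")


@dataclass(frozen=True)
class LinearCalibration:
    """Linear map from genetic distance to divergence time (Gy)."""

    intercept: float
    slope: float
    r_squared: float

    def __call__(self, distance) -> np.ndarray | float:
        t = self.intercept + self.slope * np.asarray(distance, dtype=float)
        t = np.clip(t, 0.0, None)  # negative extrapolations clamp to 0
        return t if t.ndim else float(t)


def calibrate_distance_time(
    distances: Sequence[float], known_times: Sequence[float]
) -> LinearCalibration:
    """OLS calibration line time = b0 + b1 * distance from literature
    anchor points; predictions clamp at 0."""
    d = np.asarray(distances, dtype=float)
    t = np.asarray(known_times, dtype=float)
    if d.size != t.size or d.size < 2 or np.unique(d).size < 2:
        raise CalibrationError("need >= 2 calibration points with distinct distances")
    res = stats.linregress(d, t)
    return LinearCalibration(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
    )


# ---------------------------------------------------------------------------
# topology screens


def _nontrivial_splits(tree: dendropy.Tree, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Unrooted, non-trivial bipartitions of ``tree`` restricted to
    ``taxa``, each canonicalized as the side *not* containing a fixed
    reference taxon."""
    ref = min(taxa)
    splits: set[frozenset[str]] = set()
    leaf_sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            leaf_sets[node] = frozenset({label}) if label in taxa else frozenset()
        else:
            leaf_sets[node] = frozenset().union(*(leaf_sets[c] for c in node.child_nodes()))
    n = len(taxa)
    for node, below in leaf_sets.items():
        if node.parent_node is None or node.is_leaf():
            continue
        side = below if ref not in below else taxa - below
        if 1 < len(side) < n - 1:
            splits.add(side)
    return splits


def flag_hgt(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    threshold: float = 0.2,
) -> dict:
    """Screen a gene tree for horizontal transfer by topology conflict.

    Robinson-Foulds distance between the two trees on their shared leaf
    set, normalized by the total number of resolvable (non-trivial)
    splits in both trees; the family is flagged when the normalized
    distance exceeds ``threshold``.
    """
    gene_taxa = {l.taxon.label for l in gene_tree.leaf_node_iter()}
    sp_taxa = {l.taxon.label for l in species_tree.leaf_node_iter()}
    shared = frozenset(gene_taxa & sp_taxa)
    if len(shared) < 4:
        raise InsufficientOverlapError(
            f"gene and species trees share only {len(shared)} taxa (need >= 4)"
        )
    s1 = _nontrivial_splits(gene_tree, shared)
    s2 = _nontrivial_splits(species_tree, shared)
    rf = len(s1 ^ s2)
    denom = len(s1) + len(s2)
    norm = rf / denom if denom else 0.0
    return {"flag": bool(norm > threshold), "rf_distance": rf, "normalized_rf": norm}


def flag_ancient_duplication(
    gene_tree: dendropy.Tree,
    species_map: Mapping[str, str],
    min_species: int = 3,
) -> bool:
    """Flag families containing an ancient duplication.

    A node is a duplication when two of its child subtrees contain the
    same species; the duplication is "ancient" when the node is ancestral
    to at least ``min_species`` distinct species.
    """
    species_below: dict = {}
    flagged = False
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else ""
            species_below[node] = {species_map.get(label, label)}
            continue
        kids = [species_below[c] for c in node.child_nodes()]
        union: set[str] = set()
        dup = False
        for s in kids:
            if union & s:
                dup = True
            union |= s
        species_below[node] = union
        if dup and len(union) >= min_species:
            flagged = True
    return flagged


# ---------------------------------------------------------------------------
# edge-disjoint independent pairs


@dataclass(frozen=True)
class IndependentPairSet:
    """Edge-disjoint leaf pairs within a divergence-time window."""

    pairs: tuple[tuple[str, str], ...]
    window: tuple[float, float]
    times: tuple[float, ...] = ()
    met_min_pairs: bool = True

    def __len__(self) -> int:
        return len(self.pairs)


def _leaf_paths(tree: dendropy.Tree) -> tuple[dict[str, frozenset[int]], dict[str, float]]:
    """Per leaf label: set of edge ids on the root path, and depth (sum of
    branch lengths from root)."""
    edge_ids: dict = {}
    paths: dict[str, frozenset[int]] = {}
    depths: dict[str, float] = {}
    for i, edge in enumerate(tree.preorder_edge_iter()):
        edge_ids[edge] = i
    for leaf in tree.leaf_node_iter():
        ids = []
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            ids.append(edge_ids[node.edge])
            depth += node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = frozenset(ids)
        depths[leaf.taxon.label] = depth
    return paths, depths


def _exact_max_disjoint(cands: list[tuple[tuple[str, str], frozenset[int]]]):
    """Branch-and-bound maximum set of pairwise edge-disjoint candidates."""
    best: list[int] = []

    def recurse(i: int, used: frozenset[int], chosen: list[int]) -> None:
        nonlocal best
        if len(chosen) + (len(cands) - i) <= len(best):
            return  # cannot beat incumbent
        if i == len(cands):
            if len(chosen) > len(best):
                best = list(chosen)
            return
        pair, edges = cands[i]
        if not (edges & used):
            chosen.append(i)
            recurse(i + 1, used | edges, chosen)
            chosen.pop()
        recurse(i + 1, used, chosen)

    recurse(0, frozenset(), [])
    return [cands[i] for i in best]


def select_independent_pairs(
    tree,
    window: tuple[float, float | None],
    min_pairs: int = 20,
    *,
    pair_time_fn: Callable[[str, str], float] | None = None,
    exact_max_leaves: int = 12,
) -> IndependentPairSet:
    """Largest set of edge-disjoint leaf pairs with divergence times in
    ``window``.

    ``window`` is (t_lo, t_hi); pass ``t_hi=None`` (or inf) for the
    one-sided "diverged more than t_lo ago" style.  Pair times default to
    half the patristic distance (the depth of the pair's ancestor on a
    clock-like tree); supply ``pair_time_fn(label_a, label_b)`` to use
    externally assigned times.  Exact (branch-and-bound) search on trees
    with at most ``exact_max_leaves`` leaves; deepest-cherry greedy above
    that.  Falling short of ``min_pairs`` is reported, not raised.
    """
    tree = read_tree(tree)
    lo, hi = window
    hi = np.inf if hi is None else hi
    if hi < lo:
        raise ConfigurationError(f"invalid window ({lo}, {hi})")
    paths, depths = _leaf_paths(tree)
    labels = sorted(paths)

    cands = []
    times = {}
    for a, b in itertools.combinations(labels, 2):
        path_edges = paths[a] ^ paths[b]
        t = (
            pair_time_fn(a, b)
            if pair_time_fn is not None
            else _pair_time(tree, a, b, depths)
        )
        if lo <= t <= hi:
            cands.append(((a, b), frozenset(path_edges)))
            times[(a, b)] = t

    if not cands:
        return IndependentPairSet(pairs=(), window=(lo, hi), met_min_pairs=0 >= min_pairs)

    if len(labels) <= exact_max_leaves:
        chosen = _exact_max_disjoint(cands)
    else:
        # greedy: deepest cherries first (shortest pair time = most recent
        # ancestor uses fewest high edges); tie-break lexicographic
        order = sorted(cands, key=lambda c: (times[c[0]], c[0]))
        used: frozenset[int] = frozenset()
        chosen = []
        for pair, edges in order:
            if not (edges & used):
                chosen.append((pair, edges))
                used |= edges
    # post-hoc edge-disjointness assertion (always on)
    seen: set[int] = set()
    for _, edges in chosen:
        if seen & edges:
            raise AssertionError("internal error: selected pairs share an edge")
        seen |= edges
    pairs = tuple(sorted(p for p, _ in chosen))
    return IndependentPairSet(
        pairs=pairs,
        window=(lo, hi),
        times=tuple(times[p] for p in pairs),
        met_min_pairs=len(pairs) >= min_pairs,
    )


def _pair_time(tree, a: str, b: str, depths: dict[str, float]) -> float:
    mrca = tree.mrca(taxon_labels=[a, b])
    mrca_depth = 0.0
    node = mrca
    while node.parent_node is not None:
        mrca_depth += node.edge.length or 0.0
        node = node.parent_node
    # time back to the common ancestor, averaged over the two tips (equal
    # on an ultrametric tree)
    return 0.5 * ((depths[a] - mrca_depth) + (depths[b] - mrca_depth))
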