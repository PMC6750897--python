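"""Synthetic-data generators for every input the pipeline consumes.

The sequence simulator is the ground truth the divergence models are
tested against.  Each site i carries a fixed allowed set of ``a_i``
amino-acid types (containing the ancestral residue) and a substitution
rate ``lam_i`` per Gy; along each of the two descendant lineages the site
follows a continuous-time Markov jump process: substitution events arrive
as a Poisson process at rate ``lam_i``, and each event replaces the
current residue with one of the other ``a_i - 1`` allowed types chosen
uniformly (back substitutions are allowed).  Under this uniform-exchange
process the expected pairwise identity after divergence time t has the
closed finite-alphabet form

    E[y] = 1/a + (1 - 1/a) * exp(-2 * lam * a/(a-1) * t),

so simulator output can be checked against theory exactly.  Allowed sets
are fixed over time (no covarion-style turnover), matching the model the
fits assume.

Also here: noisy identity-vs-time observations for fit testing,
turbidostat competition count tables with multinomial sampling depth,
and random clock-like (coalescent) trees.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .alignment import AMINO_ACIDS
from .exceptions import InvalidParameterError
from .fitting import DivergenceObservation
from .mage import MageCountTable, WT_ID
from .models import ModelParams, evaluate_model

__all__ = [
    "as_rng",
    "SiteClassProfile",
    "make_site_profile",
    "evolve_pair",
    "evolve_independent_pairs",
    "pair_identity_samples",
    "simulate_observations",
    "simulate_mage",
    "simulate_tree",
    "write_fasta",
    "write_observations_tsv",
]


Seed = int | np.random.Generator


def as_rng(seed: Seed) -> np.random.Generator:
    """Accept either an integer seed or an existing Generator (so one
    stream can drive a whole experiment)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SiteClassProfile:
    """Ground-truth per-site evolutionary classes.

    ``allowed[i]`` is the site's allowed residue string (ancestral residue
    first), ``rates[i]`` its substitution rate per Gy; ``labels`` is an
    optional per-site group label (fitness bin, shell, ...).
    """

    allowed: list[str]
    rates: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.allowed) != self.rates.size:
            raise InvalidParameterError("allowed sets and rates must have equal length")
        if np.any(self.rates < 0):
            raise InvalidParameterError("substitution rates must be >= 0")
        for s in self.allowed:
            if len(set(s)) != len(s) or len(s) < 1:
                raise InvalidParameterError(f"invalid allowed set {s!r}")

    @property
    def length(self) -> int:
        return len(self.allowed)

    @property
    def alphabet_sizes(self) -> np.ndarray:
        return np.array([len(s) for s in self.allowed])

    @property
    def ancestral(self) -> str:
        return "".join(s[0] for s in self.allowed)


def make_site_profile(
    L: int,
    alphabet_sizes: int | Sequence[int] = 4,
    rates: float | tuple[float, float] | Sequence[float] = 1.0,
    seed: Seed = 0,
    labels: Sequence | None = None,
) -> SiteClassProfile:
    """Draw a per-site profile of allowed sets and rates.

    ``alphabet_sizes``: one integer for a homogeneous profile, or a
    per-site sequence.  ``rates``: a constant, a per-site sequence, or a
    ``(shape, mean)`` tuple for gamma-distributed rate variation across
    sites (the heterogeneity the gamma divergence model describes).
    Sites with alphabet size 1 are frozen (rate forced to 0).
    """
    if L < 1:
        raise InvalidParameterError("L must be >= 1")
    rng = as_rng(seed)
    if np.isscalar(alphabet_sizes):
        sizes = np.full(L, int(alphabet_sizes))
    else:
        sizes = np.asarray(alphabet_sizes, dtype=int)
        if sizes.size != L:
            raise InvalidParameterError("alphabet_sizes length must equal L")
    if np.any(sizes < 1) or np.any(sizes > len(AMINO_ACIDS)):
        raise InvalidParameterError(f"alphabet sizes must be in [1, {len(AMINO_ACIDS)}]")
    if isinstance(rates, tuple) and len(rates) == 2 and np.isscalar(rates[0]):
        shape, mean = rates
        if shape <= 0 or mean <= 0:
            raise InvalidParameterError("gamma rate parameters must be > 0")
        lam = rng.gamma(shape, mean / shape, size=L)
    elif np.isscalar(rates):
        lam = np.full(L, float(rates))
    else:
        lam = np.asarray(rates, dtype=float)
        if lam.size != L:
            raise InvalidParameterError("rates length must equal L")
    lam = np.where(sizes == 1, 0.0, lam)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    allowed = []
    for i in range(L):
        picks = rng.choice(len(AMINO_ACIDS), size=sizes[i], replace=False)
        allowed.append(b"".join(aa[picks]).decode())
    lab = np.asarray(labels) if labels is not None else None
    return SiteClassProfile(allowed=allowed, rates=lam, labels=lab)


def _evolve_states(
    sizes: np.ndarray, rates: np.ndarray, t: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized jump process: final state index per (replicate, site)
    after time ``t``, starting from state 0."""
    L = sizes.size
    lam_t = np.where(sizes > 1, rates * t, 0.0)
    k = rng.poisson(lam_t, size=(n, L))
    cur = np.zeros((n, L), dtype=np.int64)
    a = np.broadcast_to(sizes, (n, L))
    kmax = int(k.max()) if k.size else 0
    for j in range(1, kmax + 1):
        mask = k >= j
        if not mask.any():
            break
        am = a[mask]
        steps = rng.integers(1, am)  # uniform over the other a-1 states
        cur[mask] = (cur[mask] + steps) % am
    return cur


def evolve_pair(
    profile: SiteClassProfile, t: float, seed: Seed = 0
) -> tuple[str, str]:
    """Evolve one ancestral sequence independently down two lineages for
    time ``t`` (Gy) and return the two descendant sequences."""
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    rng = as_rng(seed)
    sizes = profile.alphabet_sizes
    states = _evolve_states(sizes, profile.rates, t, 2, rng)
    seqs = []
    for row in states:
        seqs.append("".join(profile.allowed[i][s] for i, s in enumerate(row)))
    return seqs[0], seqs[1]


def pair_identity_samples(
    profile: SiteClassProfile, t: float, n_pairs: int, seed: Seed = 0
) -> np.ndarray:
    """Percent identity of ``n_pairs`` independently evolved descendant
    pairs (vectorized; no sequence strings materialized)."""
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    rng = as_rng(seed)
    sizes = profile.alphabet_sizes
    sa = _evolve_states(sizes, profile.rates, t, n_pairs, rng)
    sb = _evolve_states(sizes, profile.rates, t, n_pairs, rng)
    return 100.0 * (sa == sb).mean(axis=1)


def evolve_independent_pairs(
    profile: SiteClassProfile, t: float, n_pairs: int, seed: Seed = 0
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """A gap-free MSA of ``n_pairs`` phylogenetically independent ortholog
    pairs, each pair diverged for time ``t`` from the shared ancestor.

    Returns ({sequence id: sequence}, [(id_a, id_b), ...]); ids are
    ``p{k}a`` / ``p{k}b``.
    """
    rng = as_rng(seed)
    sizes = profile.alphabet_sizes
    msa: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    sa = _evolve_states(sizes, profile.rates, t, n_pairs, rng)
    sb = _evolve_states(sizes, profile.rates, t, n_pairs, rng)
    for k in range(n_pairs):
        ida, idb = f"p{k}a", f"p{k}b"
        msa[ida] = "".join(profile.allowed[i][s] for i, s in enumerate(sa[k]))
        msa[idb] = "".join(profile.allowed[i][s] for i, s in enumerate(sb[k]))
        pairs.append((ida, idb))
    return msa, pairs


def simulate_observations(
    params: ModelParams,
    times: Sequence[float],
    noise_sd: float,
    n_per_time: int = 1,
    seed: Seed = 0,
    family_id: str = "sim",
    time_bounds_frac: float | None = None,
) -> list[DivergenceObservation]:
    """Identity-vs-time observations: model curve plus Gaussian noise,
    clamped to [0, 100].

    ``time_bounds_frac=f`` attaches symmetric time bounds
    ``[t*(1-f), t*(1+f)]`` for resampling tests.
    """
    if len(times) == 0:
        raise InvalidParameterError("times must be non-empty")
    rng = as_rng(seed)
    out = []
    for t in times:
        y = evaluate_model(params, t)
        noise = rng.normal(0.0, noise_sd, size=n_per_time) if noise_sd > 0 else np.zeros(n_per_time)
        for j, e in enumerate(noise):
            out.append(
                DivergenceObservation(
                    pair_id=f"{family_id}_t{t:g}_{j}",
                    family_id=family_id,
                    identity=float(np.clip(y + e, 0.0, 100.0)),
                    time=float(t),
                    time_min=float(t * (1 - time_bounds_frac)) if time_bounds_frac is not None else None,
                    time_max=float(t * (1 + time_bounds_frac)) if time_bounds_frac is not None else None,
                )
            )
    return out


DEFAULT_MAGE_TIMES = tuple(float(t) for t in range(0, 16, 2))  # hours, sampled every 2h


def simulate_mage(
    true_growth_diffs: Mapping[str, float] | pd.DataFrame,
    times: Sequence[float] = DEFAULT_MAGE_TIMES,
    depth_per_timepoint: int | None = 100_000,
    seed: Seed = 0,
    wt_weight: float = 1.0,
) -> MageCountTable:
    """Pooled competition read counts under exponential growth differences.

    ``true_growth_diffs``: either {mutant_id: dm} with dm the growth-rate
    difference to WT in 1/h (metadata auto-filled), or a design frame with
    columns mutant_id, position, codon, aa, wt_aa, batch, dm.  Strains
    start at equal abundance (WT at ``wt_weight`` relative to one mutant);
    deterministic exponential trajectories are sampled multinomially at
    ``depth_per_timepoint`` reads per time point.  ``depth_per_timepoint=
    None`` returns the noise-free expected counts (scaled to 1e9 reads) —
    the infinite-depth limit used to check estimator exactness.
    """
    times = tuple(float(t) for t in times)
    if list(times) != sorted(set(times)):
        raise InvalidParameterError("times must be strictly increasing")
    if isinstance(true_growth_diffs, pd.DataFrame):
        design = true_growth_diffs.copy()
    else:
        design = pd.DataFrame(
            {
                "mutant_id": list(true_growth_diffs),
                "dm": [true_growth_diffs[m] for m in true_growth_diffs],
            }
        )
        design["position"] = np.arange(len(design)) + 1
        design["codon"] = [f"c{i}" for i in range(len(design))]
        design["aa"] = "A"
        design["wt_aa"] = "G"
        design["batch"] = (np.arange(len(design)) // 10).astype(int)
    rng = as_rng(seed)
    dm = design["dm"].to_numpy(dtype=float)
    weights = np.concatenate([[wt_weight], np.ones(len(design))])
    growth = np.concatenate([[0.0], dm])  # WT first
    t_arr = np.asarray(times)
    counts = np.empty((len(weights), len(times)))
    for j, t in enumerate(t_arr):
        abundance = weights * np.exp(growth * t)
        p = abundance / abundance.sum()
        if depth_per_timepoint is None:
            counts[:, j] = p * 1e9
        else:
            counts[:, j] = rng.multinomial(int(depth_per_timepoint), p)
    meta = pd.DataFrame(
        {
            "mutant_id": [WT_ID] + list(design["mutant_id"]),
            "position": [0] + list(design["position"]),
            "codon": ["WT"] + list(design["codon"]),
            "aa": ["X"] + list(design["aa"]),
            "wt_aa": ["X"] + list(design["wt_aa"]),
            "batch": [-1] + list(design["batch"]),
        }
    )
    for j, t in enumerate(times):
        meta[MageCountTable.time_col(t)] = counts[:, j]
    return MageCountTable(df=meta, times=times)


def simulate_tree(n_leaves: int, clock_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Random clock-like rooted tree: a Kingman coalescent genealogy with
    branch lengths multiplied by ``clock_rate`` (ultrametric)."""
    if n_leaves < 2:
        raise InvalidParameterError("need at least 2 leaves")
    tns = dendropy.TaxonNamespace([f"T{i}" for i in range(1, n_leaves + 1)])
    tree = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1.0, rng=_random.Random(seed))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * clock_rate
    tree.is_rooted = True
    return tree


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_observations_tsv(obs: Sequence[DivergenceObservation], path) -> None:
    rows = []
    for o in obs:
        row = {
            "family_id": o.family_id,
            "pair_id": o.pair_id,
            "identity_pct": o.identity,
            "time_gy": o.time,
        }
        if o.time_min is not None:
            row["time_min_gy"] = o.time_min
            row["time_max_gy"] = o.time_max
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
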