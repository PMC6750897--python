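# Methods

This note records the models divlimit implements, the defaults it ships,
the design choices that were genuinely open, and what the synthetic-data
generators do and do not emulate.

## Divergence models and their fitting

Identity is percent (0–100] in every public interface; time is Gy
(10⁹ years). The three models are nested descriptions of mean pairwise
identity between orthologs:

* M1 `y = 100·e^(−R₀t)` — Poisson substitutions, infinite alphabet.
* M2 `y = Y₀ + (100−Y₀)·e^(−R₀t)` — M1 plus an identity floor.
* M3 `y = 100·(1 + R₀t/α)^(−α)` — rates gamma-distributed across sites
  with shape α (mean rate R₀). M1 is the α→∞ limit; small α means strong
  rate heterogeneity. The divergence rate is
  `−dy/dt = 100·R₀·(1+R₀t/α)^(−α−1)`, and in distance space
  (`D = 1 − y/100`) the expansion rate is `dD/dt = R₀(1−D)^((α+1)/α)`.
  We use the standard gamma-survival parameterization; an equivalent
  form with α replaced by 1/α circulates in the literature, and the two
  coincide at α = 1 — the package's α is the gamma *shape*, so larger α
  always means more homogeneous rates.

M2 is exactly the a-state uniform-exchange (Jukes–Cantor-type) model
with back substitutions: `Y₀ = 100/a`, `R₀ = 2λa/(a−1)` for per-site
rate λ. `a` is treated as real-valued ("effective number of accepted
types") and is not capped at 20; `expected_substitutions` implements
the matching distance correction and raises a saturation error at or
below `y = 1/a`.

Fitting is ordinary unweighted nonlinear least squares over all
pairwise points (phylogenetic non-independence of pairs is knowingly
ignored — the floor estimate is a descriptive asymptote, not a
likelihood-calibrated parameter). Multi-start trust-region optimization
with box bounds: R₀ ∈ (0, 50], α ∈ (0, 100], starts on log grids for
R₀/α and {0, 20, 40} for Y₀, best-RSS solution kept; non-convergence is
flagged, not raised. The floor is deliberately *not* bounded below by 0:
a least-squares floor estimate can legitimately come out slightly
negative under noise, and constraining it at zero would place the
no-floor truth on the parameter boundary and destroy the nominal
calibration of the nested F-test (measured type-I rate halves). The
covariance is the asymptotic `s²(JᵀJ)⁻¹` at the optimum.

Model comparison: `F = (RSS₁ − RSS₂) / (RSS₂ / (n−2))` with (1, n−2)
degrees of freedom (F clamped to 0 if the optimizer leaves RSS₂ > RSS₁).
The floor-vs-random test is a one-sided Wald test,
`z = (Y₀ − baseline)/SE(Y₀)`, default baseline 13.5% (see below),
significance threshold 0.05. Families must span ≥ 5 distinct divergence
times (≥ 4 via a flag, for validated-annotation subsets).

Divergence-time uncertainty is propagated by refitting under random
reassignment of each lineage pair's time to its reported minimum or
maximum (fair coin per pair per run); observations sharing the same
(time, min, max) triple flip together. Reported: the fraction of
families with Y₀ > 25% and with M3 projection at 7.8 Gy > 25%, per run
and averaged.

## Alignment and the random-identity null

`global_align` produces optimal global alignments with affine gaps
(BLOSUM62; the first residue of a gap costs `gap_open`, each further
residue `gap_extend`). Percent identity is identical aligned positions
over non-gap aligned positions.

Default gap penalties are open 17 / extend 2 — stiffer than the nominal
defaults of classic alignment tools, deliberately. Those tools rescale
their nominal penalties internally by matrix score and sequence length,
so their *effective* penalties are far stiffer than their advertised
ones; with a naive open 10 / extend 0.5 the aligner shreds unrelated
sequences into gap-rich alignments whose surviving columns are enriched
for matches, and random pairs score ~27% "identity". The stiff default
reproduces the ~13.5% mean identity between unrelated random proteins
(length 300, Robinson–Robinson background composition) that the
floor-vs-random Wald test uses as its null. Both the composition and
the scoring are configurable, and `random_identity_baseline` recomputes
the null for any choice.

## Phylogenetically independent pairs

Two ortholog pairs are independent when their connecting paths in the
species tree share no edge. `select_independent_pairs` maximizes the
number of such pairs whose divergence time falls in a window (two-sided
or one-sided): exact branch-and-bound for trees with ≤ 12 leaves,
deepest-cherry-first greedy above that; every returned set is
re-verified for edge-disjointness. Pair time defaults to half the
patristic distance (= MRCA depth on a clock-like tree); externally
assigned times can be supplied per pair. Unrooted inputs are
midpoint-rooted.

Screens that stand in for manual curation: gene-vs-species tree
conflict is flagged by normalized Robinson–Foulds distance on the
shared leaf set (threshold 0.2, configurable; splits are counted on
resolvable bipartitions only), and ancient duplications by any node
whose child subtrees share a species while being ancestral to ≥ 3
species. Distance→time calibration is an OLS line through literature
anchor points, clamped at 0.

## Site-level analyses

All site statistics live on the 1-based coordinates of an ungapped
designated reference sequence; columns where the reference is gapped
are dropped, and a pair with a gap at a column leaves that site's
denominator for that pair. Universally conserved sites are those
identical in ≥ 90% of independent pairs (threshold configurable); their
contribution to the observed floor is
`100·universal_fraction/(floor/100)`.

Fitness groups (from deep-mutational-scan site means) and structural
shells (Cα distance to the active-site centroid, 5 Å shells by default;
shell = floor(d/width)) share one aggregation engine: identity per pair
over the group's sites only, then mean ± SD/SEM within time bins
(left-closed). Per-pair-then-bin averaging was chosen over pooling
sites; with gap-free alignments the site-count-weighted group curves
exactly reconstruct the global curve (a partition identity the tests
assert). Default fitness bin edges are quartiles of the site-fitness
distribution.

## Competition fitness estimation

In exponential competition the log ratio of mutant to wild-type reads
is linear in time with slope `m_i − m_wt` (1/h). Counts are first
median-normalized within each (time point × 10-codon mutagenesis
batch), preserving batch totals; zero-median batches are flagged and
left untouched. Per mutant, time points with fewer than 20 reads are
dropped, and the slope is estimated only when ≥ 5 points remain
(mutants at 4 are excluded — the boundary is tested exactly); time
points where WT has zero reads are dropped for everyone. Slopes divide
by the turbidostat dilution rate (1.37/h = e-folds of growth per hour)
to give relative growth differences. Site fitness is a two-stage mean:
codon estimates collapse per amino-acid change, then an unweighted mean
over the site's observed substitutions; synonymous changes are excluded
from site means (reported separately), nonsense changes retained but
identifiable (`aa == "*"`). The estimator is invariant to per-time-point
depth rescaling because depth cancels in the ratio to WT.

## Structural divergence

`kabsch_rmsd` is SVD superposition with the reflection-excluding
determinant correction. Structure-pair records (RMSD, time, coverage,
EC-sharing group) are precomputed inputs; pairs with < 30% of the
shorter protein aligned, or flagged as flexible multi-domain
alignments, are dropped. Trends: Spearman rank correlation of RMSD vs
time, per-bin medians with 25–75 and 5–95 percentile bands, and a
centered moving average (default window 51 records). Group contrasts
(full EC vs 3-digit EC vs fold-only) use two-sided Mann–Whitney U,
overall and within RMSD bins (left-closed, default 0.5 Å); means and
medians are both emitted since either may be the summary of record.
A `time > 2 Gy` filter restricts comparisons to the long-term regime.

## Synthetic data: what it emulates, what it does not

Sequences: each site carries a fixed allowed set of `a_i` residues
(ancestral included) and rate λ_i; each lineage evolves by a Poisson
jump process with uniform replacement within the allowed set. Uniform
exchangeability makes the finite-alphabet closed form the *exact*
expectation, giving an analytic oracle: simulated mean identity matches
the M2-mapped curve within Monte Carlo error across (a, λ, t), and
gamma-distributed λ_i reproduce M3-shaped decay. Allowed sets are fixed
over time — no covarion-style turnover, no epistasis, no indels, no
composition bias. Passing tests therefore certify the estimators under
the fitted models' own assumptions, not robustness to real-sequence
complications (alignment error, lineage effects, selection shifts).

Observations: model curve + Gaussian noise clamped to [0, 100]
(noise SD 5 and n ≈ 30–50 points in the calibration experiments; the
F-test calibration uses R₀ = 0.35 so the curve stays within ~25–85%
and the clamp never censors the noise). Competition counts:
deterministic exponential trajectories, multinomial sampling at fixed
depth per time point (default 10⁵ reads, 8 samples 2 h apart; infinite
depth available for exactness checks). Trees: Kingman coalescent
genealogies scaled by a clock rate (ultrametric).

Problem sizes used in the recomputation tests — 2000 replicate pairs of
length 500 for simulator-vs-theory, 100 replicate data sets for
coverage, 4000 for F-test calibration (the Monte Carlo SE at 1000 leaves
the band check underpowered), 200 random trees (≤ 8 leaves) against the
brute-force pairing oracle, 100 replicate competitions across a
Δm ∈ [−0.3, 0] grid — were chosen so each check resolves its tolerance
comfortably at desk scale.

## Numerical conventions

Ties in alignment traceback resolve deterministically (first optimal
path). Bin intervals are left-closed, right-open everywhere. Empty
groups/bins yield missing values, not errors. All randomness flows
through numpy Generators; every public simulation accepts either an
integer seed or a Generator, and experiments derive all replicates from
one base stream. Degenerate inputs (single-letter compositions,
zero-median batches, collinear coordinate sets, star trees) warn or
flag rather than abort where a defined answer exists.

## Known limitations

* The floor estimate inherits the non-independence of pairwise points;
  its SE is asymptotic and mildly optimistic at small n.
* The HGT screen is a topology-distance proxy for expert curation; its
  threshold trades sensitivity against false exclusion and was not
  tuned to any curated truth set.
* The greedy pairing used above 12 leaves is not guaranteed maximal
  (the exact solver is, and anchors the tests).
* MSAs are consumed as given; alignment uncertainty is not propagated
  into site-level statistics.
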