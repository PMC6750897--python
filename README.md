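# divlimit

Tools for asking how far two proteins can diverge while continuously
keeping the same molecular function — and for showing that the answer is
"not very far": orthologous enzymes that conserve their reaction tend to
stop diverging at a sequence-identity *floor* well above the random
expectation, even after billions of years.

The package is aimed at molecular-evolution researchers who have (or can
simulate) pairwise identity-vs-divergence-time data for ortholog
families, deep-mutational-scan fitness measurements, and structural
alignments, and who want the entire analysis — model fits, significance
tests, site-level stratifications — reproducible from plain-text inputs.

## The models

Global percent identity `y` between two orthologs separated for time `t`
(in Gy, 10⁹ years) is fit with three nested descriptions:

* **Model 1** — equal independent rates, no back substitutions:
  `y = 100·e^(−R₀t)`. Identity decays to zero.
* **Model 2** — same, plus an explicit divergence floor `Y₀`:
  `y = Y₀ + (100 − Y₀)·e^(−R₀t)`.
* **Model 3** — gamma-distributed rates across sites (shape α):
  `y = 100·(1 + R₀t/α)^(−α)`.

Model 2 is algebraically identical to a finite-alphabet substitution
process with back substitutions: if every site accepts `a` amino-acid
types and substitutes at per-site rate λ, then

    y = 1/a + (1 − 1/a)·exp(−2λ·a/(a−1)·t),

i.e. Model 2 with `Y₀ = 100/a` and `R₀ = 2λa/(a−1)`. A fitted floor of
40% therefore reads as "on average 2.5 amino-acid types are acceptable
per site". Whether a family's floor is real is decided by an F-test of
Model 2 against Model 1, and whether it exceeds the ~13.5% identity that
optimal global alignment produces between *unrelated* random sequences
by a one-sided Wald test on `Y₀`.

Around that core the package provides: a global aligner and the
random-identity null (`alignment`), edge-disjoint phylogenetically
independent pair selection plus HGT/duplication screens (`phylo`),
per-site conservation and fitness/structure-stratified divergence
(`sites`), growth-rate estimation from pooled turbidostat competitions
(`mage`), Cα-RMSD trends and functional-specificity comparisons
(`structure`), and generators for every input with known ground truth
(`simulate`).

## Worked example

Fit one synthetic enzyme family (floor `Y₀ = 38`, `R₀ = 1.6/Gy`, noise
SD 4, eight pairs at each of six divergence times):

```python
from divlimit.models import ModelParams, limit_to_alphabet
from divlimit.simulate import simulate_observations
from divlimit.fitting import (fit_divergence_model, f_test_nested,
                              wald_test_floor, project_identity)

truth = ModelParams("M2", r0=1.6, y0=38.0)
obs = simulate_observations(truth, [0.3, 0.7, 1.2, 2.0, 3.0, 4.0],
                            noise_sd=4.0, n_per_time=8, seed=11)
m1 = fit_divergence_model(obs, "M1")
m2 = fit_divergence_model(obs, "M2")
m3 = fit_divergence_model(obs, "M3")
F, p_f = f_test_nested(m1, m2)
z, p_w = wald_test_floor(m2)          # against the 13.5% random baseline
ap = limit_to_alphabet(m2.params)     # effective alphabet interpretation
```

which prints, formatted:

```
M2 fit: Y0 = 36.6 +/- 0.8 %, R0 = 1.53 /Gy
F-test (M1 vs M2): F = 692.1, p = 2.28e-29
Wald vs 13.5% baseline: z = 28.6, p = 1.24e-179
effective alphabet a = 2.73 types/site, lam = 0.484 /Gy
M3: R0 = 1.57, alpha = 0.39; projection at 7.8 Gy = 25.6 %
```

Read: the floor is detected decisively (F-test), it is far above the
random-alignment null (Wald), it corresponds to fewer than three
acceptable residues per site, and even the floorless gamma-rates model
projects >25% identity after another ~4 Gy.

The same operations are scriptable from the shell:

```sh
divlimit sim obs --model M2 --y0 40 --r0 1.5 --out obs.tsv
divlimit fit --obs obs.tsv
divlimit baseline --n-pairs 500 --length 300
divlimit pairs --tree species.nwk --window 1.75:2.25
divlimit mage --counts counts.tsv --dilution 1.37
```

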