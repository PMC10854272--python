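# connharm — harmonizing structural connectivity matrices across sites

`connharm` is a pipeline for studying *matrix-level harmonization* of
multi-site diffusion-MRI structural connectomes. Connectivity matrices from
different scanners/protocols carry systematic site effects that swamp
biological signal in pooled analyses. This package simulates two age- and
sex-matched 84-subject cohorts of 84-node connectomes with realistic,
block-structured site effects, harmonizes them three ways, and quantifies
each method on the two questions that matter:

1. **Is the site effect gone?** — pooled coefficient of variation and a
   Mann-Whitney U test between the sites' graph-measure distributions
   (p > 0.05 ⇒ removed);
2. **Is biology preserved?** — Pearson correlation between age and each graph
   measure on the pooled cohort (p < 0.05 ⇒ preserved).

It is written for methods researchers in network neuroscience who need a
controlled, fully reproducible testbed for batch-correction methods on
connectomes (where real multi-site cohorts are rarely shareable).

## What's inside

**Harmonization methods** (`connharm.harmonize`, `connharm.combat`):

* *Mean shift*: S′ = max(0, S − S̄_source + S̄_target) per matrix entry, using
  the element-wise site-mean matrices; exposed in both directions.
* *ComBat*: per-edge location/scale batch model
  y = α + Xβ + γ_site + δ_site·ε on the vectorized cohort (the 3570 × 168
  table of matrix-triangle entries), with parametric empirical-Bayes
  shrinkage of (γ, δ²) across edges and age/sex retained as covariates.
  Cross-validated against the Bioconductor reference (`sva::ComBat`) in the
  test suite.
* *GAN input normalizations*: the deterministic [−1, 1] transforms
  (log-scale for counts, linear for lengths, anchored at the global maximum)
  that an image-translation network needs, plus exact inverses. The network
  itself is intentionally out of scope.

**Graph measures** (`connharm.measures`) — the three streamline-count
invariant measures, each on its proper weighting: modularity Q (raw counts;
deterministic Newman spectral bisection with Kernighan–Lin refinement),
global efficiency E (max-normalized counts, inverse-weight shortest paths),
average betweenness centrality (mean-length matrices as connection lengths).
All are verified against exhaustive brute-force oracles on small graphs.

**Synthetic cohorts** (`connharm.synthetic`) — modular + hemispheric network
model with calibrated site effects (fewer/shorter inter-hemispheric
streamlines at site 2) and a linear age effect (older ⇒ more modular, less
efficient). Defaults are frozen against the calibration anchors described in
`docs/methods.md`. Includes the greedy age/sex matcher.

**Evaluation** (`connharm.evaluation`) and **orchestration**
(`connharm.pipeline`, the `connharm` CLI, and the numbered drivers under
`analysis/`).

## Worked example

Run the four analysis stages (or equivalently `connharm run-all`):

```bash
python analysis/01_simulate_cohort.py   # cohort -> scratch/cohort/
python analysis/02_harmonize.py         # mean shift x2, ComBat
python analysis/03_graph_measures.py    # tables  -> results/measures/
python analysis/04_evaluate.py          # reports -> results/reports/
```

At the default seed 0 the evaluation prints, per method and measure, the
U test (site-effect removal) and the age correlation (preservation):

```
site-effect removal (Mann-Whitney p > 0.05 = removed):
     reference / modularity         U=    0.0 p=4.56e-29 -> remains***
     reference / global_efficiency  U= 5795.0 p=6.48e-13 -> remains***
        combat / modularity         U= 3710.0 p=0.565 -> removed
        combat / global_efficiency  U= 3759.0 p=0.465 -> removed
   shift_site1 / modularity         U= 3532.0 p=0.991 -> removed

age associations (Pearson p < 0.05 = preserved):
     reference / modularity         r=+0.230 p=0.00268 -> significant**
        combat / modularity         r=+0.460 p=3.62e-10 -> significant***
        combat / global_efficiency  r=-0.243 p=0.00147 -> significant**
   shift_site1 / global_efficiency  r=-0.274 p=0.000318 -> significant***
```

Reading this: before harmonization the sites are decisively separable on
modularity (U = 0: every site-1 subject ranks below every site-2 subject) and
on efficiency; after ComBat or mean shift the rank tests are indistinguishable
from the null. Meanwhile the age associations do not merely survive
harmonization — removing the site-driven variance *strengthens* them (e.g.
age–modularity r rises from 0.230 to 0.460 under ComBat), the signature of a
harmonization that removes technical, not biological, variation. Betweenness
centrality (computed from mean-length matrices) shows the weakest site effect
and no age association either way — mean-length weightings are the hard case
for every method here.

The per-site cohort statistics behind this run (reference modularity 0.627 vs
0.695, efficiency 0.0168 vs 0.0134 at seed 0) are recorded per method in
`results/reports/evaluation_cov.csv`, with the per-subject measure tables
under `results/measures/`.

## Repository layout

```
src/connharm/       library: io, synthetic, measures, harmonize, combat,
                    evaluation, pipeline, config, cli
analysis/           numbered narrative drivers (simulate -> evaluate)
scripts/acceptance.py
tests/              pytest suite incl. brute-force oracles, an R (sva)
                    cross-check, and a 20-seed acceptance study
docs/methods.md     model, parameters, calibration, limitations
```
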