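# phylosdm

Spatiotemporal pattern analysis for clades of georeferenced species: where
is the suitable habitat, how old are the lineages that live there, and do
the oldest lineages sit in the best habitat — the signature of a group
that diversified in place and dispersed outward?

The package is aimed at biogeographers and mycologists/botanists working
with occurrence compilations (GBIF-style records), environmental rasters
(WorldClim-style layers) and a time-calibrated phylogeny. The motivating
system is a wood-inhabiting macrofungal genus in China whose suitable
habitat concentrates in the southeast; the full analysis design is
reproduced here on synthetic data with known ground truth, so every stage
is testable without external downloads.

## The analysis

1. **Occurrence preparation.** Records within 10 km are replicates
   (haversine distance, R = 6371.0088 km); one survives. Environmental
   layers with pairwise Pearson |r| > 0.8 are reduced to an uncorrelated
   subset.
2. **Ensemble SDM.** With presences P and three sets of 500 uniform
   pseudo-absences, four learner families (GLM, GAM, GBM, RF) are fitted
   over 3 pseudo-absence sets x 10 cross-validation runs (75/25 splits) =
   120 members. Each member is scored on held-out data by
   AUC = Pr(score(presence) > score(absence)) (ties ½) and the True Skill
   Statistic TSS = sensitivity + specificity − 1 at the max-TSS
   threshold. Two ensembles mix all members: Committee Averaging
   (fraction of binarized member votes) and the Weighted Mean
   WM(x) = Σᵢ wᵢ sᵢ(x) / Σᵢ wᵢ with wᵢ = member AUC. Variable importance
   is permutation-based: 1 − |r(predictions, predictions with one
   variable shuffled)|.
3. **Habitat classes.** Exact Fisher–Jenks natural breaks (dynamic
   program minimizing within-class squared deviation) cut the WM map into
   four levels, unsuitable (1) to highly suitable (4).
4. **Divergence times.** Each species' divergence time is its stem age —
   the age of the node where its branch attaches to the rest of the
   chronogram. The mean divergence time (MDT) of a 100 × 100 km grid cell
   is the mean stem age of the species occurring in it.
5. **Ancestral areas.** Tip areas (NE/NW/SE/SW) evolve under a k-state
   Mk model with rate matrix Q (equal-rates, symmetric, or
   all-rates-different); Felsenstein pruning with P(t) = e^{Qt} gives the
   likelihood, L-BFGS-B the ML rates, AIC the model choice, and a
   two-pass algorithm the marginal ancestral-state probabilities.
6. **The spatiotemporal test.** Cells are grouped by habitat class and
   their MDTs compared with the tie-corrected Kruskal–Wallis H
   (chi-square p, optional exact permutation p) and Dunn–Holm pairwise
   comparisons.

`docs/methods.md` documents the model assumptions, defaults, numerical
choices, and what the synthetic generator does and does not emulate.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
bundled synthetic scenario and print what they find:

```sh
python analysis/01_simulate.py
python analysis/02_prepare_occurrences.py
python analysis/03_sdm_ensemble.py
python analysis/04_divergence_times.py
python analysis/05_spatiotemporal.py
```

Selected output (seed 1):

```
scenario seed 1: 576 records for 36 species; root age 77.74 Myr

thinning: 444 of 576 records retained (132 replicates within 10 km dropped)
collinearity filter: kept ['env1', 'env2', 'env3', 'env4']
  dropped env5 (|r| = 0.900 with env4)

120 members fitted (120 usable, 0 pass QC); AUC 0.647 +/- 0.032, TSS 0.285 +/- 0.051
CA ensemble: AUC 0.910, TSS 0.792 (pooled evaluation)
WM ensemble: AUC 0.918, TSS 0.777 (pooled evaluation)
variable importance: env1 0.68, env4 0.16, env2 0.14, env3 0.14
Jenks breaks: [0.33, 0.449, 0.633]

root age 77.74 Myr; 36 species; oldest stem 50.70 Myr (sp11)
  ER: logL -46.453 (1 rate(s))
  SYM: logL -44.982 (6 rate(s))
  ARD: logL -44.523 (12 rate(s))
selected ER by AIC; root modal area NW (p = 0.25)

97 occupied 100-km cells; MDT Jenks breaks [5.4, 12.3, 20.6] Myr
  suitability class 1: n =  15, mean MDT   5.52 Myr
  suitability class 2: n =  54, mean MDT   5.35 Myr
  suitability class 3: n =   6, mean MDT  11.95 Myr
  suitability class 4: n =  22, mean MDT  20.24 Myr
Kruskal-Wallis: H = 51.625, df = 3, p = 3.6e-11
  class 1 vs 4: z = -5.00, Holm p = 2.9e-06 *
  class 2 vs 4: z = -6.92, Holm p = 2.67e-11 *
```

Reading the numbers: 576 records thin to 444 (132 were replicates within
10 km); the deliberately collinear layer env5 (r = 0.9 with env4) is
dropped. All 120 ensemble members fit; individual held-out AUCs are
modest because presences are drawn probabilistically from a mid-spread
suitability surface, but the ensembles concentrate the signal, and the
permutation importance correctly singles out env1, the layer that drives
the truth. The Kruskal–Wallis test recovers the planted pattern: cells in
the highest suitability class carry by far the oldest mean divergence
times (20.2 vs ~5.4 Myr), with the top-vs-bottom contrasts significant
after Holm adjustment — the old lineages of the simulated clade really do
sit in its best habitat, and the pipeline finds them there. The
ancestral-area reconstruction is honestly uncertain (root modal
probability 0.25 ≈ uniform): at the simulated dispersal rate, ~5 expected
changes per root-to-tip path erase the deep signal, a caveat that applies
equally to real chronogram-depth reconstructions.

The same pipeline runs from one config via the CLI
(`phylosdm run --seed 1 --out runs/demo`), and each stage is available as
a separate subcommand (`phylosdm thin`, `filter-vars`, `stem-ages`,
`ancestral`, `grid-mdt`, `kw-test`).

## Layout

```
src/phylosdm/      library: rasters, occurrences, synthetic, sdm,
                   phylo, ancestral, spatial, pipeline, cli
analysis/          numbered drivers for the worked example
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    models, assumptions, parameter choices, limitations
```

Published reference values that depend on external data (WorldClim
rasters, GBIF host records, GenBank sequences) are discussed in the
methods note but are outside what this repository can recompute.
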