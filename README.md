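# earlyburst

Tools for asking whether an adaptive radiation shows an *early burst* —
in lineage diversification, in morphological disparity, or in both —
from a time-calibrated phylogeny and continuous trait data.

The package grew out of the analysis stack used for marine adaptive
radiations (its synthetic fixtures mimic a 49-species, ~13.4-myr-old
radiation of cold-water fishes with one very young species-rich clade),
but every component is generic:

- **`treesim`** — Gillespie simulation of Yule/birth–death trees,
  rejection-conditioned on crown age *and* extant richness
  (e.g. exactly 100 tips at 15 myr, speciation rate λ ~ U(0.1, 0.4)),
  plus random / diversified / semidiversified taxon-sampling schemes
  and lineage-through-time curves.
- **`traitsim`** — exact-transition simulation of Brownian motion (rate
  σ²) and single-optimum Ornstein–Uhlenbeck (pull α toward optimum θ)
  trait evolution, with piecewise time windows in which σ² is
  multiplied (10-fold in the canonical staged-radiation design).
- **`disparity`** — disparity-through-time (DTT) curves (average
  relative subclade disparity, where disparity is the mean squared
  pairwise distance), simulated null envelopes, and the morphological
  disparity index: MDI = ∫₀^0.9 (DTT_obs − median DTT_null) dt.
  Negative MDI is the early-burst signature.
- **`modelfit`** — ML fitting of BM and root-at-optimum OU models
  (statsmodels-style `TraitEvolutionModel(...).fit()`), AICc
  comparison, and batch medians/preference counts across posterior
  tree samples.
- **`shiftscan`** — stepwise-AICc detection of diversification-rate
  shifts on *diversity trees* (tips carry unresolved species-richness
  counts): per-regime net rate r = λ − μ and turnover ε = μ/λ, a
  Nee-style backbone likelihood plus geometric
  (Magallón–Sanderson-type) richness probabilities,
  `RateShiftModel(dtree).fit(max_shifts=15)`.
- **`kmrates`** — per-interval Kendall–Moran rate estimates (branching
  events over lineage-time in named geological stages, Tortonian
  through Pleistocene) compared against quantile envelopes from
  conditioned simulated phylogenies.
- **`synthdata`** — seeded generators for study-shaped fixtures (tree +
  five-trait table + richness table) and planted-rate-shift trees.

## Worked example

```python
import earlyburst as eb

# study-shaped synthetic bundle: 49-tip tree (crown 13.4 myr),
# 5 traits, richness table summing to 132 species
tree, traits, richness = eb.make_fixture(eb.FixtureSpec(), seed=1)

# disparity through time for one trait, BM null fitted by ML
res = eb.dtt_mdi(tree, traits["cv2"], model="fitted", n_sims=100, seed=0)
print(f"MDI(cv2) = {res.mdi:.3f}")

# BM vs OU model comparison
print(eb.fit_model(tree, traits["cv2"], "ou").summary())

# diversification-rate shifts on the diversity tree
scan = eb.fit_rate_shifts(eb.DiversityTree(tree, richness), max_shifts=5)
print(scan.summary())
```

prints (seed 1):

```
MDI(cv2) = 0.044
Trait evolution model: OU  (n tips = 49, k = 3)
  sigma2 = 28.9879
  alpha  = 0.193562  (theta = z0)
  z0     = 1.48178
  lnL    = -155.8714
  AICc   = 318.2761
  converged: True
Rate-shift scan: 2 shift(s) retained (AICc 350.01 -> 295.56, improvement 54.44)
  regime @ root: r = 0.1089, eps = 0.9369
  regime @ node 78: r = 10.0000, eps = 0.9836  [at bound]
  regime @ node 8: r = 0.0169, eps = 0.9990  [at bound]
```

Here the fitted OU pull (α ≈ 0.19/myr) sits near the generating value
of the cv2 trait (0.30) and its near-zero/positive MDI reflects
constrained rather than early-burst evolution, while the rate scan
flags the young
species-rich clade (node 8 subtends the seven `fast_*` tips carrying 30
species in 1.2 myr; on the turnover boundary its implied speciation
rate λ = r/(1−ε) ≈ 17/myr vastly exceeds the background λ ≈ 1.7).

A CLI mirrors the library (`earlyburst simulate-trees | simulate-traits
| dtt | fit | shiftscan | kmrates | make-fixtures | run`); see
`earlyburst --help`.

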