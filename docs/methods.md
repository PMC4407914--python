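# Methods

This note documents the models, conventions and numerical choices
behind `earlyburst`, and what its synthetic experiments do and do not
establish about real data.

## Time conventions

Internally every tree stores node *ages below the root* (root = 0,
tips = crown age on an ultrametric tree); all I/O and geological
arithmetic use ages *before present* (tips = 0). Branch lengths are in
millions of years (myr). Nodes are kept in a canonical order in which
every parent precedes its children, so forward index order is a
preorder and reverse order a postorder; all traversals and all random
draws rely on this single ordering, which is what makes seeded runs
bit-reproducible.

## Tree simulation and conditioning

Trees grow forward from the two crown lineages by the Gillespie
algorithm: waiting times are exponential at rate n(λ+μ), the affected
lineage is uniform, and the event is a speciation with probability
λ/(λ+μ). Extinct lineages are pruned; if either crown lineage leaves
no survivor the replicate is reported extinct, because the survivors'
MRCA would be younger than the requested crown age.

Joint conditioning on crown age and extant richness is by rejection:
rates are (re)drawn (fixed, or λ ~ U(low, high) for the pure-birth
design), a tree is grown, and the attempt is discarded unless the tip
count matches exactly. Under pure birth the lineage count never
decreases, so attempts are aborted as soon as it exceeds the target —
a pure speed-up that leaves the accepted distribution untouched; with
extinction no such shortcut is applied. The analytic crown pure-birth
tip-count law P(N=n) = (n−1)p²(1−p)^(n−2), p = e^(−λT), serves as the
oracle for the acceptance rate and for goodness-of-fit tests.
Conditioning failure after `max_attempts` (default 10⁶) raises rather
than silently relaxing the condition.

Taxon sampling: *random* keeps a uniform subset; *diversified* keeps
one uniformly chosen tip from each subtree stemming from the k−1
oldest splits (the set of oldest internal nodes is automatically
closed under ancestry, so it defines exactly k pendant subtrees);
*semidiversified* applies the diversified rule to ⌊k/2⌋ oldest splits
and fills the remaining slots uniformly. The semidiversified rule is a
documented stand-in for a scheme whose published definition lives in
supplementary material not available here; the deep fraction (default
0.5) is exposed as a parameter. Induced subtrees preserve path lengths
and re-root at the MRCA of the retained tips. Age ties are broken by
stable node index.

## Trait simulation

Traits evolve by the exact OU transition over each branch segment:
mean x·e^(−αΔ) + θ(1−e^(−αΔ)), variance σ²(1−e^(−2αΔ))/(2α), with the
BM limit (mean x, variance σ²Δ) taken analytically below α = 1e−12 to
avoid catastrophic cancellation. Stage-wise radiation scenarios
multiply σ² (not α) inside root-forward time windows — the window is a
statement about the *tempo* of trait evolution, while α is the
constraint — and branches are split at window boundaries so the
transition stays exact. The canonical stages on a tree of crown age T
are the first, second and final thirds of its history (for T = 15 myr:
15–10, 10–5 and 5–0 Ma), with a 10-fold multiplier. Draws are consumed
one standard normal per (branch segment, replicate) in node-index
order, so the α = 0 path is bit-identical to a plain BM simulator fed
the same stream.

## Disparity through time and MDI

Disparity is the mean squared pairwise Euclidean distance,
Σ_{i<j}|x_i−x_j|²/(n(n−1)/2), computed per node in one postorder pass
via the identity Σ_{i<j}(x_i−x_j)² = nΣx² − (Σx)². The DTT curve opens
at (0, 1) (whole-clade relative disparity) and, at each later
divergence time, records the mean relative disparity of the lineages
alive just before that divergence; simultaneous divergences are merged
into one time point. Curves are right-continuous step functions; the
MDI integrates observed − null-median by exact step areas (never
trapezoids) over the first 90% of relative time, discounting the
overdispersed tip region. Relative disparity is scale-free, which has
two consequences used throughout: MDI is exactly invariant under
affine transformation of the trait, and a BM null's fitted σ² has no
effect on the null curve — the BM null median is therefore computed
once per tree and shared across experimental conditions, pairing the
contrasts. Null envelopes default to 100 simulations with parameters
fitted by ML ("fitted"); 5%/95% quantiles use linear interpolation
between order statistics (type 7).

A note on the crossing convention: the average at divergence time t is
taken over lineages alive on the interval ending at t (the splitting
lineage included, its children not yet). This reproduces the worked
small-tree values used as frozen oracles and keeps the curve's first
informative point distinct from the root point.

## BM/OU likelihoods and fitting

Both models are multivariate normal in the tip values. BM covariance
is σ²·s_ij (shared root-to-MRCA path); the root-at-optimum OU model
(θ = z0, the classical fitting convention; stationary-root variants
are out of scope) has covariance
σ²/(2α)(1−e^(−2α s_ij))e^(−α(d_i+d_j−2 s_ij)), which on an ultrametric
tree is the BM covariance of a tree with warped node heights
h(s) = (e^(−2α(T−s)) − e^(−2αT))/(2α). Likelihoods are evaluated two
ways — dense Cholesky (reference) and O(n) Felsenstein pruning on the
(possibly warped) tree — and the two agree to 1e−8 on trees up to 200
tips; α below 1e−9 switches to the exact BM branch. For fixed α the
profile estimates ẑ0 (GLS mean) and σ̂² = Q/n fall out of the pruning
pass, so OU fitting is a 1-D search over α: a log-spaced grid on
[1e−8, 10] followed by bounded refinement, with the exact α = 0
boundary always compared so that lnL(OU) ≥ lnL(BM) holds identically.
AICc = −2lnL + 2k + 2k(k+1)/(n−k−1), k = 2 (BM) or 3 (OU). Across
tree samples, medians (robust to outlier fits) and AICc preference
counts are reported. Missing trait values drop the tip (logged),
never imputed.

## Rate-shift scan on diversity trees

Each regime is parameterized by (r, ε) with λ = r/(1−ε). The
likelihood factorizes per regime into (i) a backbone part for resolved
branching times — along a surviving lineage, observed births arrive at
the thinned rate λP(t), P(t) = r/(λ−μe^(−rt)), so each internal branch
contributes the exact integral −[ln(λe^(rt₁)−μ) − ln(λe^(rt₂)−μ)] and
each internal node ln(λP(t)) — and (ii) a geometric richness term per
tip, P(N=n | survival) = (1−β)β^(n−1), β = (e^(rt)−1)/(e^(rt)−ε), with
t the tip's stem age, conditioning on survival of every observed
lineage. With ε = 0 and all richness 1 this collapses exactly to the
Yule form B·lnλ − λL, whose maximum is the closed-form estimate B/L;
with extinction it is an approximate composite likelihood of the
family used by stepwise-AICc shift methods, and recovers (r, ε) within
the documented 25% band in simulation. The exact conditioning choice
and the AICc sample-size convention (here: internal nodes plus tips
with richness > 1; base model k = 2, each shift +3) are conventions the
original tooling does not pin down, so both are stated and kept
configurable in code.

The stepwise search fits the one-regime model, then greedily adds the
shift (stem placement: the shift applies from the branch's parent node
down) with the best AICc, retaining on *any* AICc improvement — the
deliberately liberal historical rule, not later threshold-corrected
variants — up to 15 shifts. Candidates are scanned in node-index order
(earliest index wins ties); only the two affected regimes are refitted
per candidate, warm-started, and the accepted assignment is refitted
thoroughly. Box bounds r ∈ [1e−6, 10], ε ∈ [0, 0.999]; boundary hits
are flagged on the results object. On the high-turnover ridge the net
rate r can understate a regime's tempo, so reported regimes should be
read together with λ = r/(1−ε).

## Interval rates

The Kendall–Moran-type per-interval estimate is B/L: branching events
with ages in (young, old] over summed branch-length overlap with the
interval. Half-open intervals make event counts and lineage-times
partition exactly over adjacent stages (asserted to 1e−9); the root is
the conditioning event and never counted. The five canonical stages
(Tortonian 11.6–7.2, Messinian 7.2–5.3, Zanclean 5.3–3.6, Piacenzian
3.6–2.6, Pleistocene 2.6–0 Ma) ship as defaults. "Floating" estimation
is per fixed named stage. Envelopes simulate conditioned trees, trim
them to the empirical tip count under a sampling scheme, and report
50/95/99.9% quantiles.

A caveat the tests encode: the single-tree ratio B/L is the MLE but
not unbiased — at deep, sparsely populated intervals its expectation
sits a few percent below the generating rate (Jensen bias), and
conditioning on a large richness biases it upward instead. Recovery is
therefore asserted on the pooled ensemble estimator ΣB/ΣL (within 3
Poisson standard errors), which is the consistent recovery statement;
per-tree values are still what the envelopes compare, since empirical
and simulated trees share the bias.

## Synthetic fixtures

`make_fixture` builds a 49-tip ultrametric tree of crown age 13.4 myr:
a 46-tip focal clade (crown at 95% of the root age) containing a
7-tip subclade of crown age 1.2 myr grafted onto the oldest available
stem, joined to a 3-tip outgroup grade (crown 8 myr). Richness totals
132 species with 122 in the focal clade, 30 of them in the young
subclade. Five traits are simulated with the package's canonical
model table (BM: cv1 σ² = 3.47, buoyancy σ² = 0.23; OU: cv2
σ² = 39.05/α = 0.30, log body size σ² = 0.12/α = 0.11, temperature
σ² = 2.37/α = 0.25). Habitat temperature is truncated at −1.86 °C
(freezing sea water) and one tip is forced to 7.64 °C — attached to
the tip whose sister split lies nearest 2.7 Ma at the end of a long
stem, because the outlier's MDI signature travels through the lineage
subtending the pair and a too-recent pair falls outside the 90%
integration window. The fixture claims only the *shape* of such a
study system, not any real topology or trait values: passing tests
show the estimators behave correctly on data generated under their own
model class, not that any real clade follows these models.

`make_planted_shift_tree` grows the fast clade forward *from an
existing node* (stem-age-conditioned, stem window 0.7–1.2 Ma, 15 tips,
10× the 0.2/myr background rate), matching the scan's stem-placement
convention; grafting a crown-conditioned clade below a slow stem would
instead make the ML optimum sit one node inside the clade. The shallow
stem window guarantees that excluding an event-free tip branch can
never out-score including it, which is what puts detection at the true
node or its parent in ≳95% of replicates.

## Replication scales

The documented experiment sizes are: 200 trees per condition for the
staged-radiation MDI experiment (null envelopes of 100 BM
simulations, trees of 100 tips, crown 15 myr); 10⁵ draws for the OU
transition check; 150–200 replicates of 100-tip trees for σ² and
model-selection recovery; 50 replicates each for planted-shift and
homogeneous-tree scans; 500 pure-birth trees for pooled interval-rate
recovery. These are the package's own choices for routine validation;
all are driven by a single seed.

## Known limitations

- No multivariate (correlated-trait) simulation or DTT combination;
  traits are univariate throughout, matching the analysis design.
- No early-burst (continuously decaying rate) trait model: the staged
  design is deliberately abrupt, and ACDC-style models are a
  non-goal.
- The OU fit is single-optimum with θ fixed at the root state;
  stationary-root and multi-optimum variants are out of scope.
- The shift scan's likelihood is composite; its ε estimates are
  weakly identified on short, richness-dominated regimes and often at
  the turnover bound — flagged, and λ should be read alongside r.
- Diversity-tree analysis assumes every extant species is assigned to
  exactly one tip; no uncertainty in richness counts is modelled.
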