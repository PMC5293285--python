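# Methods

## MaxRank normalization

A RAD is the vector of a sample's counts sorted in decreasing order, with
zeros removed; counts must be integers because normalization draws
individuals from the counted pool (tables of relative abundances are
rejected rather than silently rescaled).  Given a target MaxRank
*R* (2 ≤ *R* ≤ *R<sub>s</sub>*), one sub-sample is drawn by taking
individuals uniformly at random without replacement; the draw that would
introduce the (*R*+1)-th distinct rank is rejected and sampling stops, so
the sub-sample contains exactly *R* ranks.  Sub-sampled counts are
re-sorted in decreasing order (sub-sampling can invert near-equal ranks)
and divided by the sub-sample's own total, so each repetition is a sorted
probability vector; the NRAD is the rank-wise mean of `n_reps` repetitions
(default 100, the upper end of the typical 10–100 range).  Means of sorted
normalized vectors are themselves sorted and normalized, so the NRAD
invariants (Σ aᵣ = 1, non-increasing) hold by construction, and for
*R* = *R<sub>s</sub>* every draw exhausts the pool and the procedure is the
exact identity.

**Confidence intervals.** The 90% band per rank is the empirical 5%/95%
percentile interval (linear interpolation) of the `n_reps` normalized
vectors, clipped elementwise to bracket the mean; the clip is a guard for
pathologically skewed repetition distributions and has no effect in
practice.  Group averages of NRADs use the same percentile construction
over bootstrap resamples of the group members (default 1000).

**Sampling algorithm.** The draw is realized through arrival times rather
than an explicit pool permutation: each individual receives an iid U(0,1)
arrival time, so a rank with *c* individuals has first arrival
min of *c* uniforms ~ Beta(1, *c*).  The sub-sample keeps every arrival
strictly before *T*, the (*R*+1)-th smallest first arrival; conditional on
its first arrival *t* < *T*, the remaining *c*−1 individuals of an included
rank arrive iid uniform on (*t*, 1), so the retained count is
1 + Binomial(*c*−1, (*T*−*t*)/(1−*t*)).  This is exactly equal in
distribution to the one-at-a-time draw with the stop rule (a random
permutation of the pool truncated before the first occurrence of the
(*R*+1)-th distinct rank) and costs O(*R<sub>s</sub>*) per repetition
instead of O(*N<sub>s</sub>*).  The test suite checks it against exhaustive
enumeration of all draw orders on small pools and against a literal
pool-permutation implementation on larger ones.

**Choice of R.** The largest admissible common *R* for a sample set is the
minimum richness in the set; `choose_max_R` returns it and it is the
default, since it retains the most abundance structure for every sample.
Per-sample random streams are spawned from one user seed, so results do
not depend on the order in which samples are processed.

**Baselines.** Cutoff normalization truncates a RAD at rank *R* and
renormalizes the kept mass to 1 (deterministic, zero-width CIs).
Renormalization is our choice — it keeps cutoff distances on the same
scale as NRAD distances; whether the original comparison renormalized is
not documented anywhere we know of.  `downsample_individuals` applies the
same stop rule to emulate a shallower sequencing run at a target richness.

## Distances

The working metric between NRADs of equal *R* is the Manhattan distance;
it gives the few large head differences and the many small tail
differences comparable total weight.  Distances are computed between mean
vectors; CI information is not propagated.  Mixed-*R* input is an error,
never silently truncated.  The two-sample Kolmogorov–Smirnov statistic on
rank-indexed cumulative abundance curves (shorter RAD zero-padded) is
provided only as the baseline it is: it compresses tail structure and is
excluded from ordination defaults.

## Diversity

Entropies are Shannon entropies of the mean NRAD vector in nats; evenness
is J = H / log R, well defined because an NRAD's richness equals *R* by
construction.  The scaling relation H_R ≈ c log R (per sample) makes
entropies computed at different *R* approximately comparable, but it is a
first-order approximation: for moderately skewed communities (log-normal
σ ≲ 1.6, slowly decaying geometric laws, broken stick) the evenness drift
across a full order of magnitude in *R* stays within 0.05, while strongly
skewed communities (σ ≳ 2) can drift by 0.1 or more.  The 0.05 band is our
operationalization of "approximately" and is configurable in the study
helper; the acceptance study runs inside the relation's domain of
validity and the limitation is stated here deliberately.

## Reference models

**Broken stick.** Expected sorted segment lengths of a unit stick broken
at *R*−1 uniform points: aᵣ = (1/R) Σ_{k=r}^{R} 1/k, computed by reverse
cumulative sum (no free parameters).  `simulate_broken_stick` is the
Monte-Carlo oracle used by tests.

**Geometric counts.** Support starts at 1 (a category that is present has
at least one variant); some libraries start at 0, hence the explicit note.
The ML estimate is p̂ = 1/mean.  The KS consistency statistic is the
supremum of |ecdf − cdf| evaluated on the integer support — the naive
continuous-sample formula badly overstates D on tied integer data — with a
p-value from the continuous-null KS distribution, which is conservative
for discrete data and ignores that p̂ is estimated from the same sample;
borderline rejections should not be over-interpreted.

**Entropy vs age.** H(t) = H_max − (H_max − H₀)e^(−λt): entropy rises from
H₀ (shortly after birth) to the asymptote H_max at rate λ (1/yr); the
model is monotone for H_max > H₀, λ > 0.  Fitting uses
Levenberg–Marquardt least squares (scipy `curve_fit`, method="lm") with
default start (3.5, 0.19, 6.0) — a rough data-scale estimate for
gut-microbiome-like cohorts.  90% CI half-widths are Student-t quantiles
times the Jacobian-based standard errors; a simulation in the test suite
confirms ~90% coverage at n = 500, σ = 0.5.  Non-convergence or a singular
Jacobian raises `FitError` with the optimizer message; there is no silent
fallback.  Because the model is linear in (H₀, H_max) at fixed λ, an
overall rescaling of the entropies (as induced by changing *R* under the
scaling relation) shifts the H-parameters and leaves λ invariant, which
the tests exercise with independently re-noised data.

## Ordination, clustering, classification

**cMDS** is the standard double-centered eigendecomposition
B = −½ J D² J.  Coordinates use the top-k positive eigenvalues; the
explained fraction is their sum over the sum of *positive* eigenvalues
only — negative eigenvalues are the non-Euclidean residual and counting
them would understate the explained share.  If fewer than k positive
eigenvalues exist, k is reduced with a warning.  The implementation is
cross-checked against scikit-bio's principal-coordinates analysis in the
tests.

**Clustering** delegates to scipy's agglomerative linkage (complete
linkage by default) on the condensed distance matrix; trees export to
Newick with branch lengths taken as differences of merge heights, giving
an ultrametric tree whose leaf depth equals the root merge height.

**Classification** trains a random forest (500 trees by default; no
guidance existed for hyperparameters, so sklearn defaults plus a fixed
seed) on NRAD ranks as predictors, with stratified threefold
cross-validation — stratification stabilizes κ under class imbalance.
ACC = n_correct/N, and κ = (ACC − ACC_exp)/(1 − ACC_exp) with ACC_exp the
marginal-product expected accuracy; the implementation generalizes to any
number of classes and agrees with Cohen's kappa (verified against an
independent implementation on random confusion tables).  Per-rank
importance is out-of-bag permutation importance: each tree of a bagged
forest is scored on its own out-of-bag samples before and after permuting
one feature, and the accuracy drops are averaged over trees.  We chose
the out-of-bag variant over single-model held-out permutation because
tree-level averaging is decisively less noisy when many informative,
mutually correlated ranks share the signal; with a 120-rank signal band,
held-out permutation of one rank almost never changes a prediction and
its importance estimate is indistinguishable from zero.

## Synthetic data

`generate_community` draws true relative abundances from a family —
uniform, geometric(p), log-normal(μ, σ) (sorted draws), or the expected
broken stick — then samples `depth` individuals multinomially and drops
unobserved species, so observed richness falls below nominal richness at
realistic depth exactly as in sequencing data.  Same spec and seed give
bit-identical output.  What is *not* emulated: sequencing error, chimeras,
PCR amplification bias, and compositional correlations between taxa.
Passing tests therefore demonstrate the statistical machinery under clean
multinomial sampling, not robustness to protocol artifacts.

`generate_entropy_age_dataset` draws ages log-uniformly (developmental
cohorts concentrate observations at young ages on a log scale) and adds
Gaussian noise to the model curve; defaults (n = 181, ages 0.03–80 yr,
σ = 0.5 nats) emulate a country-sized gut-microbiome cohort.

`middle_band_shapes` constructs two abundance laws that are *exactly*
identical outside a chosen rank band: the second class multiplies the band
by exp(ε·s(x)) with s a sine bulge/sag windowed to zero value and slope at
the band edges, ε set to 90% of the largest amplitude that keeps the
vector non-increasing (per-rank log-slope budget equal to the base decay),
and the band rescaled to conserve its mass.  The sorted-order corridor is
what limits ε: naive band multiplication reshuffles ranks on sorting and
leaks signal outside the band.  Defaults (decay 0.03, band ranks 41–160 of
300, ~11% peak deviation vs 8% per-rank log-normal jitter, depth 3×10⁵)
were chosen so the two families are cleanly separable (κ > 0.8) with the
signal strictly band-confined — the condition the classification analyses
are defined on.

## Study problem sizes

The robustness studies in `radnorm.experiments` use synthetic sets sized
to emulate their real counterparts while remaining quick to run: the
down-sampling study uses 50 log-normal communities (σ 1.2–2.4 spaced for
roughly uniform shape separation, richness 1–2×10⁵, depth 30 per species,
R = 1000, 100 repetitions); the R-reduction study uses 26 communities
(σ 1.0–2.6, richness 2.5–8×10³) with distances compared at the maximal
common R and at R ∈ {1000, 250, 100}.  The down-sampled copy of a
community is a single realization, which sets an irreducible floor on the
paired original-vs-down-sampled distance; communities must be rich enough
(down-sampled richness a few times R) for that floor to stay below
distances between distinct communities.

## Known limitations

- Richness information is deliberately discarded; questions about richness
  need rarefaction-style tools, not MaxRank normalization.
- If one sample's richness is far below the others, the common R collapses
  to it and the rich samples lose almost all structure; discarding extreme
  low-richness outliers is the pragmatic remedy.
- The KS p-values for discrete geometric fits are conservative (see above).
- BIOM support covers format 1.0 JSON; BIOM 2.x (HDF5) files are rejected
  with a conversion hint.
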