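# Methods

## Diversity measure

Alpha diversity is measured with Hill numbers
`^qD = (Σ pᵢ^q)^{1/(1−q)}` over relative abundances `pᵢ`, with the q→1
limit taken in closed form as `exp(−Σ pᵢ ln pᵢ)` rather than numerically.
Natural logarithms are used throughout, so q=1 is the exponential of
Shannon entropy in nats.  Zeros are excluded from the sum; vectors are
normalised internally over their positive entries, which makes every
diversity value scale-invariant and lets counts and relative abundances
be used interchangeably.  No rarefaction or coverage correction is
applied: diversities are computed from raw relative abundances, and any
depth normalisation is the caller's responsibility.  The default order
grid is q = 0, 1, 2, 3; other orders (e.g. q=4) can be passed anywhere a
`q_grid` is accepted.

## Accrual curves and model fitting

An accrual curve pools samples cumulatively in a stated order (element-
wise sum of rows — the pooled community of the first A units) and
evaluates `^qD` at each A = 1..n.  Both DAR models are estimated as
ordinary least squares on the log-linear forms

    ln D = ln c + z ln A            (PL)
    ln D = ln c + z ln A + d A      (PLEC)

rather than by nonlinear least squares on the original curves; the PL
fit uses `scipy.stats.linregress` and the PLEC fit `statsmodels.OLS`.
The reported goodness-of-fit `R` is the Pearson correlation between
observed and fitted ln D (for PLEC this equals √R² of the multiple
regression), and `p_value` is the regression F-test.

**Fit-success rule.**  A fit is successful iff the regression is
estimable — at least 3 (PL) or 4 (PLEC) points, positive variance of
ln D (relative spread > 10⁻¹²), full-rank design — and its F-test
p-value is below 0.05.  A constant curve (e.g. every accumulation unit
containing the same number of phyla) is a *failed fit*, not an error:
it returns z = 0 with NaN R/p and is counted in the `N_success`
bookkeeping.  The PLEC maximum `A_max = −z/d`,
`D_max = c·A_max^z·e^{−z}` is computed only when d < 0 and z > 0;
otherwise both are NaN while the fit itself may still be successful —
success and the existence of a finite maximum are independent flags.

Derived parameters: `g = 2 − 2^z` (pairwise diversity overlap) and
`RIP = 100·c/D_max` (%), where c comes from the PL fit of the same
resample and D_max from its PLEC fit.

## Resampling designs

*Inter-individual* (per body site): the accumulation units are the
site's samples, one per subject (subjects with repeat samples keep the
first by sample-id sort).  Because the PL intercept c is the diversity
of the first unit, the accumulation order is randomly permuted per
resample; 100 resamples by default, with per-q means and standard
errors over the successful fits.

*Intra-DT* (across sites): each of 1000 default replicates draws one
random sample per site and accumulates the sites in a fixed anatomical
order (default BM, KG, HP, TD, PT, Th, Sal, SupP, SubP, Stool — oral
cavity to gut; configurable, as only the oral→gut principle is fixed).

Aggregation: `N_success` counts resamples whose PL fit succeeded;
means/SEs of z, c, g, R, p are over those resamples; `mean_d` is over
successful PLEC fits; `D_max` and `RIP` are averaged over resamples
where the PLEC maximum exists.  `g` is averaged per-resample
(mean of g(zᵢ), not g(mean z)).  Every routine is deterministic under a
seed (one `numpy.random.Generator` consumed sequentially), and an
optional per-resample log allows all reported means to be recomputed.

## Permutation tests

Pairwise differences in z or D_max between two sample groups are tested
by pooling the groups and re-splitting them at random into pseudo-groups
of the original sizes.  The statistic of a (pseudo-)group is its
resampling-averaged parameter over `inner_reps` random accumulation
orders (default 10; a cost/stability trade-off), using all estimable
fits — conditioning the inner fits on their own significance would bias
the null.  The observed difference is the absolute difference of group
means (two-sided); the p-value uses the add-one correction
`p = (1 + #{null ≥ obs})/(n_valid + 1)`, so it is never 0.  Permutations
whose statistic is undefined are dropped; if more than half are, the
test is reported inconclusive instead of being coerced to a 0/1 call.
Group order is canonicalised before any randomness is consumed, so the
result is exactly symmetric under swapping the groups.  The pairwise
site matrix tests all C(n,2) unordered pairs per q and encodes the
calls as one digit per q ("0,000" style) with per-site percentages of
significant comparisons; no multiple-testing correction is applied.

A known property of this null-generation scheme: it has power against
pool-size differences only when the two groups' taxon pools are nested
or strongly overlapping.  When pools are largely disjoint, mixing
samples *accelerates* accrual, pseudo-group D_max is not monotone in
group composition, and the null becomes heavy-tailed — differences are
then hard to detect regardless of effect size.

## Synthetic cohorts

The generator emulates a multi-site digestive-tract survey: defaults of
242 subjects × 10 sites, a nested 5-level taxonomy
(14/30/60/120/400 taxa), per-site pools of 300 genera sharing a 60%
core across sites, lognormal abundances (σ = 1.5 between taxa, σ/2
within), and multinomial read counts at depth 10 000 — magnitudes
typical of a 16S survey at genus level.  Occupancy is core–satellite:
each pool taxon draws a presence probability π ~ Beta(a, b) once per
cohort, and each subject carries it with probability π.  This is the
minimal mechanism that yields power-law-like richness accrual with a
tunable exponent; it is a modelling choice, not a claim about any real
dataset.

Expected pooled richness has the closed form
`E[S(n)] = T·(1 − B(a, b+n)/B(a, b))`.  `calibrate_occupancy` fixes
a = 1 (then `E[S(n)] = T·n/(b+n)`) and bisects b in log space until the
log-log OLS slope of E[S(n)] over the requested area range matches the
target; the slope is monotone in b and spans (0, 1), so any target in
that interval is reachable without simulation.  The default
`occupancy_beta = (1.0, 13.99)` is this calibration for a slope of
0.294 over 1..242 subjects — the genus-level inter-individual regime.
An optional `site_pool_sizes` makes the site pools nested prefixes of
one master pool, for scenarios contrasting sites purely by pool size.

What the generator does *not* emulate: real taxon identities,
abundance–occupancy correlation, compositional covariance between taxa,
or sequencing error.  Consequently its q≥1 scaling rates decline with q
more gently than in real surveys (where dominant taxa are shared across
hosts), and passing tests demonstrate correctness of the estimation
machinery, not biological realism.

## Problem sizes and numerical choices

Test-suite runs use desk-scale sizes chosen to keep the full suite
under a minute apart from the statistical-validity checks: cohorts of
8–60 subjects, 15–100 inter-individual resamples, 50–100 intra-DT
replicates, permutation tests at n_perm = 200 with `inner_reps` 2–5
(500 tests for the type-I-error check, 10 seeded runs for power).  The
permutation inner loop evaluates the OLS coefficients in closed form
(normal equations); tests pin these to the reference fitting routines
at 10⁻¹⁰.

Degenerate inputs: all-zero samples are dropped on read with a warning;
blank lineage labels collapse into explicit `unclassified-<parent>`
bins; an empty community raises rather than returning 0 diversity;
flat curves and rank-deficient designs return failed fits.  Ties in
accumulated area cannot occur (A is the accumulation index).

## Known limitations

* Log-linear OLS weights relative errors in ln D equally along the
  curve; early accrual points therefore dominate the fit less than in
  some nonlinear-least-squares treatments, and fitted D_max is
  sensitive to d̂ near 0 (A_max = −z/d diverges) on short curves.
* The permutation scheme is a standard two-sample pool-and-resplit on a
  derived statistic; it is not an exact reproduction of any particular
  published randomization procedure.
* BIOM support covers the JSON and HDF5 dialects via the biom-format
  package; observation metadata must carry the lineage under the
  conventional `taxonomy` key for taxonomic collapsing to work.
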