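# Methods

This note records the statistical models implemented in `befgrass`, the
conventions and defaults they use, and the design decisions taken where more
than one reasonable choice existed.

## Abundance weights and diversity indices

A quadrat's community is summarized by the important value index: for
species *i*, `p_i` is the mean of its relative biomass, relative cover and
relative density within the quadrat (each component divided by its quadrat
sum). If a component sums to zero across the quadrat — all covers
unrecorded, say — that component is dropped from the average with a warning
rather than failing the quadrat; the average of the remaining relative
measures is still a valid weight vector. Cover is stored internally as a
fraction in (0, 1]; percent-scale input is converted at load time via a
dialect switch, which removes a silent ×100 error class.

Indices on the weights:

* Shannon–Wiener `H = −Σ p_i ln p_i`, natural log, as the formula is
  conventionally written. `H ∈ [0, ln S]`.
* Rao's quadratic entropy `FD_Q = Σ_i Σ_j d_ij p_i p_j`, the **full double
  sum** over ordered pairs (equivalently twice the upper-triangle sum).
  This convention keeps the algebraic identity with weighted MPD clean —
  FD-form = MPD-form × Σ_{i≠j} p_i p_j — and only rescales `FD_Q` by a
  constant, which cancels exactly in the standardized effect size.
* Weighted MPD = `Σ_{i≠j} d_ij p_i p_j / Σ_{i≠j} p_i p_j` over patristic
  distances; undefined (NaN, flagged) for single-species quadrats.

Trait space: each trait is log10-transformed, then z-scored **across the
full species pool supplied to the run**, not per quadrat — SES values are
only comparable across quadrats if all quadrats live in one common trait
space. A single trait uses the absolute z difference; a trait set uses the
Euclidean distance over z-scores divided by √(#traits), so single- and
multi-trait `FD_Q` are on comparable scales. Whether the original
FDiversity-style computation used Gower or Euclidean distance is not
derivable from its description; Euclidean-on-transformed-traits is this
package's documented choice and is switchable by supplying a custom
distance matrix. All measurement scales (biomass, richness, traits) enter
the regressions log10-transformed; base 10 is pinned by the breakpoint
back-transform convention (log-richness 1.05 ↔ ≈11.2 species/m²,
0.95 ↔ ≈9).

Species present in a community but missing from the trait table or the tree
are excluded from the affected metric for that quadrat (and from the
shuffle pool), with per-quadrat exclusion counts in the output — the
conservative default when the provenance of such species is unknown.

## Phylogeny handling

Trees are consumed as user-supplied Newick (retrieval of any particular
published megatree is deliberately out of scope). BLADJ calibration fixes
tips at age 0, takes named internal-node ages (root required), and assigns
every undated node an age by equal spacing along the path between its
nearest dated ancestor and a dated descendant reachable through undated
nodes only. Where several such descendants exist the path with the most
intervening undated nodes anchors the spacing (ties broken toward the older
descendant); once assigned, a node anchors its own descendants. For pure
chains this is exactly the classic even-spacing rule; for branching undated
regions it is a documented convention. Branch lengths become parent-age
minus child-age, so the output is ultrametric by construction; calibration
errors (child age ≥ ancestor age) name the offending pair.

Phylogenetic signal uses Blomberg's K: the ratio of the observed
(tip-variance / phylogenetically-corrected-variance) quotient to its
Brownian-motion expectation, with the phylogenetic covariance
`V_ij = (t_i + t_j − d_ij)/2` built from depths and patristic distances.
K ≈ 1 under Brownian evolution. The p-value comes from tip-label shuffles
(999 by default) with the (1 + #{K* ≥ K})/(n + 1) correction. A
constant trait is reported as undefined rather than raising. `V` is ridged
by the smallest of (0, 1e-12 … 1e-6) × mean diagonal that makes the
Cholesky succeed — ultrametric trees with very short terminal branches are
otherwise numerically singular. The choice of K (rather than Pagel's λ or
Moran-type statistics) is an explicit assumption, recorded here because the
signal statistic is configurable in principle but K is the
community-phylogenetics default.

## Taxon-shuffle null model and SES

The null preserves a quadrat's richness S and its IVI vector, and redraws S
species uniformly without replacement from the pool, assigning the fixed
weights in draw order; the metric is recomputed each iteration (default
10,000; calibration tests use 1,000 with Monte-Carlo tolerances stated in
the tests). The pool defaults to every species in the run with complete
trait and phylogeny data, matching a regional-pool framing; site-level
pools can be passed instead. SES = (observed − null mean)/null sd; a null
sd indistinguishable from zero (pool size equal to richness, constant
distances) flags the SES undefined rather than producing ±∞. Reproducibility
contract: one master seed, with per-quadrat substreams derived from
(master seed, CRC32(quadrat id ++ metric)), so results never depend on batch
order. Dispersion verdicts use the t-based 95% CI of the mean SES:
`clustered` if the CI is entirely below zero, `overdispersed` entirely
above, `neutral` otherwise.

## Model competition

Candidates per relationship: ordinary linear, quadratic, and the continuous
broken line `y = a + b₁x + (b₂ − b₁)(x − ψ)₊`.

**Segmented estimation.** Muggeo's iteration refits, at a working ψ, the
design [1, x, (x−ψ)₊, −1(x>ψ)] and updates ψ by γ̂/β̂₂ (gap coefficient over
slope difference). Two numerical safeguards matter in practice: (i) each
update is accepted through an RSS line search (step halving) because the
raw update oscillates between the two data points bracketing the optimum
when x is heavily discretized — log10 of integer richness has only ~35
distinct values; (ii) ten quantile-spaced starting values guard against
local optima, with a profile-RSS grid as a final fallback (flagged
non-converged). Candidate breakpoints must leave ≥ 5 observations strictly
on each side. On noiseless broken-line data the estimator is exact to 1e-6.

**Breakpoint uncertainty.** The default CI is Muggeo's delta method,
SE(ψ̂) = SE(γ̂)/|β̂₂| at the solution. A pairs-bootstrap percentile CI
(499 resamples, each replicate refitted with its own multistart) is
available via `ci_method="bootstrap"`. The delta CI is accurate when the
break is well identified (coverage ≈ 95% at noise sd 0.1, n = 300 in the
test suite) but anticonservative when the left segment is short and nearly
flat — at the survey-like signal (population R² 0.31) its empirical
coverage drops to ~83%, while the bootstrap CI holds ~94%. The end-to-end
recovery checks therefore exercise the bootstrap CI; both are reported.
Slope CIs come from the gap-model covariance at ψ̂ and are conditional on
the estimated breakpoint, the standard segmented-regression convention.

**Davies' test.** Signed Wald statistics for the slope-difference
coefficient are computed at K = 10 breakpoints equally spaced between the
10th and 90th x-percentiles; the two-sided p combines the maximal statistic
M with the upper-bound correction `p = 2·P(t_ν > M) + V·exp(−M²/2)/√(8π)`,
where V is the total variation of the statistic's path (evaluated on a
finer 50-point grid, since a 10-point grid understates it), capped at 1.
The approximation is asymptotic: at the survey's sample size (n = 581) the
simulated type-I error is ≈ 6% at nominal 5%, the same mild liberality the
standard R implementation shows; at small n it is larger, which is why the
calibration simulations run at n = 581.

**Selection.** AIC in the Gaussian profile form `n ln(RSS/n) + 2(k+1)`,
counting σ² as a parameter and the breakpoint as a regression parameter
(k = 2, 3, 4 for linear, quadratic, piecewise). The parsimony rule: if no
non-linear model beats the linear AIC by at least 5, linear wins; otherwise
the lowest-AIC model, with a quadratic/piecewise near-tie (within the same
margin) broken by R². A decision trace records each comparison. The
reported `Sig.` is the slope p for linear fits and the curvature p for
quadratic fits (the only parameter separating it from linear). A piecewise
row is reported as `-` (no interpretable segmented model) when Davies' test
is non-significant at 0.05 **and** the piecewise model is not
AIC-preferred; the reason is logged.

**Shape labels.** Segments and linear fits are `Increase`/`Decrease` when
the 95% slope CI excludes zero, `Unchange` otherwise; quadratics are
`U-type`/`Unimodal` by curvature sign when the vertex lies inside the
x-range, else the monotone label. Piecewise labels read
`<left> + <right> (ψ)`.

## Quantile envelopes

Straight lines minimizing the check loss `Σ ρ_τ(y − a − bx)` are fitted at
τ = 0.05, 0.50, 0.95 (configurable). The point estimate uses iteratively
reweighted least squares with an exact linear-programming fallback for
degenerate residual configurations. Standard errors are pairs-bootstrap
(999 resamples by default) — resampling cases rather than residuals because
envelope data are heteroscedastic by construction — and p-values use the
normal approximation slope/SE, two-sided; whether a bootstrap-percentile
test would have been preferable is undecidable from the method description,
and the normal approximation is the documented choice. Degenerate resamples
(constant x) are skipped and counted. Quantile crossing is reported, never
constrained: the envelope argument needs per-τ fits only. The envelope
table encodes significance at α = 0.05 as a solid/dashed line-style field.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the survey's
stated conditions, fixed once:

| knob | default | meaning |
|---|---|---|
| pool_size | 719 | regional species pool on a Yule tree (root age 1) |
| n_sites × quadrats | 118 × 5, 9 lost | → 581 quadrats |
| richness_range | 3–37 | per-quadrat S, uniform |
| max_density | 2,252/m² | lognormal abundances, clipped |
| trait_model | brownian | K ≈ 1 traits; "independent" for no signal |
| assembly | random | or filtered / limiting with a strength parameter |
| biomass law | ψ=1.05, b₁=0.04, b₂=1.16 | log10 broken line |
| biomass_sigma | solved | population R² = 0.31 over the richness range |

Traits are Brownian realizations on the tree (or i.i.d. normal),
standardized and exponentiated to realistic raw scales (SLA ~16 mm²/mg,
heights ~10 cm, seed masses ~1 mg medians). Abundance components share a
lognormal latent factor (correlation 0.7) so biomass, cover and density
covary realistically; per-quadrat covers are normalized to a total in
(0.6, 0.95). Filtered assembly draws species with probability
∝ exp(−strength·‖z − z_opt‖²) around a randomly chosen optimum; limiting
similarity grows the community by softmax-weighted farthest-point sampling
in trait space. The biomass law redraws quadrat totals on the log10 scale
and rescales species biomasses proportionally, so IVI weights are
unchanged. `sigma_for_target_r2` solves
`R² = var(f)/(var(f) + σ²)` exactly for richness uniform on the configured
range.

What the generator does **not** emulate: spatial or climatic gradients,
grassland-type structure, observation error in traits, non-uniform richness
distributions (a site-level richness effect exists but is off by default),
and any particular real megatree topology. Passing the recovery tests
therefore demonstrates the *inference chain* is correct and calibrated on
data satisfying its assumptions, not that any field dataset satisfies them.

## Problem sizes and numerical conventions

Calibration suites run at: null-model calibration — pool 200, 200 quadrats,
1,000 iterations; breakpoint recovery — 100 seeds at n = 581 with
499-resample bootstrap CIs; Davies calibration — 500 simulations at
n = 581; quantile checks — n = 5,000. Degenerate inputs are contracts, not
crashes: single-species quadrats give H = 0, FD_Q = 0 and flagged MPD;
zero-variance traits contribute zero distance with a warning; a null sd of
zero flags the SES undefined; fewer than `min_segment` points per candidate
segment is an error. Validation failures (negative abundances, duplicate
species, cover > 1, inconsistent node ages) raise itemized errors naming
the offending rows.

## Known limitations

* Davies' p is an asymptotic upper-bound approximation, mildly liberal
  (~6% at nominal 5%) even at n = 581.
* The delta-method breakpoint CI undercovers under weak identifiability;
  use the bootstrap CI when the left segment is short or nearly flat.
* Blomberg's K permutation tests on trees with near-zero terminal branches
  rely on a ridged covariance; K magnitudes on such trees are sensitive to
  the shortest branches.
* The one-breakpoint constraint is by design; data with two regime changes
  will be summarized by whichever single break minimizes RSS.
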