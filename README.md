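# befgrass

Biodiversity–ecosystem-function (BEF) inference for grassland community
surveys. The package implements the full analysis chain used to ask how
species, functional and phylogenetic diversity relate to aboveground biomass
across many sampled quadrats — the setting of large alpine-grassland surveys
where each 1 m² quadrat records the biomass, cover and density of every
vascular plant species:

1. **Abundance weights.** Each species' important value index (IVI) is the
   mean of its relative biomass, relative cover and relative density within
   its quadrat; the weights `p_i` sum to one.
2. **Diversity.** Species richness *S*; Shannon–Wiener
   `H = −Σ p_i ln p_i`; Rao's quadratic entropy
   `FD_Q = Σ_ij d_ij p_i p_j` over trait-space distances (log10-z-scored
   SLA, leaf size, plant height, seed mass — singly and combined); and the
   IVI-weighted mean pairwise phylogenetic distance
   `MPD = Σ_{i≠j} d_ij p_i p_j / Σ_{i≠j} p_i p_j` over patristic distances
   on a BLADJ-calibrated ultrametric tree.
3. **Null models.** A taxon-shuffle null preserves each quadrat's richness
   and IVI vector while redrawing species identities from the regional pool
   (default 10,000 iterations); `SES = (obs − mean_null)/sd_null`, with
   positive values indicating overdispersion and negative clustering, and a
   run-level verdict from the t-based 95% CI of the mean SES.
4. **Model competition.** Every bivariate relationship is fitted with
   linear, quadratic, and continuous one-breakpoint segmented regressions
   (Muggeo's iteration); Davies' test assesses the slope change at the
   unknown breakpoint ψ; models compete on AIC with a parsimony rule —
   linear wins unless a non-linear model improves AIC by ≥ 5 — and fits are
   labelled (`Increase`, `Unchange + Increase (ψ)`, `U-type`, …) from the
   95% CIs of their slopes.
5. **Quantile envelopes.** Straight-line quantile regression (check-loss)
   at τ = 0.05/0.50/0.95 with pairs-bootstrap standard errors traces the
   boundaries of each diversity–diversity cloud; a steep lower bound with a
   flat upper bound is the "filled triangle" signature of converging
   functional diversity at high richness.
6. **Synthetic data.** A generator with known ground truth emulates the
   survey design (118 sites × 5 quadrats with 9 lost → 581 quadrats, a
   719-species pool on a Yule tree, richness 3–37, densities up to
   ~2,250/m²) with configurable community assembly (random, environmental
   filtering, limiting similarity), Brownian or signal-free traits, and a
   broken-line richness–biomass law — so every stage of the chain can be
   validated against the truth that produced its input.

## Worked example

```python
from befgrass import SyntheticConfig, generate_dataset, RunConfig, run_analysis

cfg = SyntheticConfig(seed=42)           # survey-scale defaults, random assembly
community, traits, tree = generate_dataset(cfg)
res = run_analysis(RunConfig(n_iter=1000, n_boot=199, seed=42),
                   community=community, traits=traits, tree=tree)

bm = res["biomass_models"]
print(bm[bm.relationship == "species_richness"])
```

```
    relationship     model                      shape    r2  delta_aic  best  breakpoint  left_slope  right_slope
species_richness    linear                   Increase 0.315     41.166 False         NaN         NaN          NaN
species_richness quadratic                     U-type 0.364      0.014 False         NaN         NaN          NaN
species_richness piecewise Unchange + Increase (1.06) 0.367      0.000  True       1.056       0.046        1.312
```

The generator's biomass law had its breakpoint at log10-richness 1.05 with
segment slopes 0.04 and 1.16: the segmented fit recovers ψ̂ = 1.056 (about
11 species/m²), labels the left segment `Unchange` (its CI straddles zero)
and the right `Increase`, and the AIC rule prefers it over the linear model
by ~41 AIC units. Under this *random* assembly configuration the dispersion
summary is, correctly, neutral for every SES metric (all 95% CIs straddle
zero), and the quantile envelope shows no triangle — switching the config
to `assembly="filtered"` or `"limiting"` produces clustered (negative SES)
or overdispersed (positive SES) communities instead.

## Command line

```sh
befgrass simulate --seed 1 --outdir data/            # synthetic dataset
befgrass run --community data/community.tsv --traits data/traits.tsv \
             --tree data/tree.nwk --seed 1 --outdir results/
befgrass fitmodels --table results/diversity_ses.tsv # one relationship
befgrass signal --tree data/tree.nwk --traits data/traits.tsv --trait SLA
```

`run` writes six tables: per-quadrat diversity + SES, the dispersion
summary, the biomass-model and richness-model competition tables, the
quantile envelope, and a run log with seeds and warnings. Input format:
long-format TSV (`quadrat_id`, `site_id`, `species`, `biomass_g_m2`,
`cover`, `density_m2`), a species × trait TSV, a Newick tree, and
optionally a BLADJ node-ages file.

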