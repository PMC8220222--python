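# Methods

## Decontamination model

Field-collected underground organs of mycoheterotrophic plants are densely
colonized by their fungal partner, so a de novo assembly mixes plant and
microbial transcripts. Classification is a fixed-order decision tree over
three evidence sources:

1. taxonomy — best protein hit (max bitscore, ties broken by min evalue
   then lexicographic subject id, making the reduction a total order) inside
   a plant clade (`Streptophyta` by default, matched by exact name in the
   lineage rather than by taxon-id tree walking, so callers may supply
   lineages from any taxonomy snapshot);
2. orthology — membership in an orthogroup that also contains a protein of
   the reference-species panel, rescuing genes so conserved that their best
   hit is non-plant;
3. expression — for contigs with *no hit at all*, detection (count > 0) in
   at least `min_detect` samples (default 2 of 6; configurable because other
   designs have other sample counts).

A contig with a non-plant hit and no orthology rescue is a contaminant
regardless of expression: the expression rescue exists for hitless
fast-evolving or unannotated plant genes, not to overrule a positive
contaminant signal. "Expressed" means mapped count > 0; the threshold is
exposed since coverage-based definitions are equally defensible.

## Repertoire tests

The unit is ortholog *detection* per species (≥ 1 gene assigned;
multiplicity deliberately ignored so gene-family expansions do not masquerade
as repertoire differences). The 2×2 table pools detection events across the
species of each group, giving margins pathway_size × group_size — the only
construction computable from per-species detection counts, and symmetric in
species. Two-sidedness follows the point-probability rule (sum of all tables
with the observed margins whose probability does not exceed the observed
table's); the implementation delegates to `scipy.stats.fisher_exact` and is
tested against exhaustive exact-integer enumeration to 1e-12. Bonferroni is
applied over the pathways actually tested in a run; an explicit `n_family`
override exists for re-testing a few rows of a larger published family.

## Normalization and transform

TMM factors follow the trimmed-mean-of-M-values algorithm: reference = the
sample whose upper quartile of nonzero CPM is closest to the mean upper
quartile; per sample, M and A values against the reference over genes
nonzero in both; double trim (30 % of each M tail, 5 % of each A tail, R-style
average ranks); factor = 2^(weighted mean M) with inverse delta-method
variance weights (N−x)/(Nx) + (Nr−r)/(Nr·r); factors rescaled to geometric
mean 1. The implementation is cross-checked in the test suite against
`edgeR::calcNormFactors` (agreement ≲ 1e-12 in practice, asserted at 1e-8).

The variance-stabilizing transform is the shifted log, vst(x) = log2(x + c),
c = 0.5 CPM. Only *differences* of transformed paired samples enter the
ratio model, so any monotone log-like stabilizer is admissible; the shifted
log is chosen for transparency, and c is exposed. The pseudo-count keeps
ratios finite for the occasional zero inside an orthogroup that passed the
detection filter.

## NB GLM and dispersion estimation

Counts are NB(μ, φ) with Var = μ + φμ², log link and offsets
log(library_size × tmm_factor). One design matrix is shared by all genes, so
IRLS normal equations are solved batched (stacked p×p solves); convergence is
relative deviance change < 1e-8 or 50 iterations, and a gene that fails to
converge is reported with p = 1 plus a warning rather than aborting the run.
Dispersion uses the Cox–Reid adjusted profile likelihood
APL_g(φ) = ℓ_g(β̂(φ); φ) − ½ log det(XᵀWX):

- common φ maximizes Σ_g APL_g (bounded scalar search on log φ in
  [1e-4, 10]);
- tagwise φ_g maximizes APL_g(φ) + (prior_df / d_res)·mean_g′ APL_g′(φ) on a
  21-point log2 grid spanning common·2^±6, with parabolic refinement of the
  interior maximum. `prior_df` defaults to 10 — with n = 2 replicates per
  organ, per-gene dispersions are nearly unidentifiable and strong shrinkage
  toward the common value is essential.

Contrasts are tested by LRT against the design in which the two contrast
organs share a level (always 1 df, whatever other organs are present), χ²₁
p-values, BH adjustment. LRT was chosen over quasi-likelihood F to match a
plain log-linear NB model. The engine is verified against statsmodels' NB
GLM at fixed dispersion (coefficients to 1e-5).

Organ-specific genes: detected in every sample of one organ and zero
everywhere else — the strictest reading, since the notion is rarely pinned
down; both thresholds (`min_on_fraction`, `max_off_count`) are exposed.

## Cross-species ratio model

Orthogroup expression per species = sum of member-gene counts (sums preserve
the count nature required by TMM). Orthogroups not detected (count > 0) in
at least one sample of *every* species are removed — ratios would be
undefined there. TMM and vst are applied within species; absolute levels
never cross a species boundary. Each individual contributes one column of
log2 underground/stem ratios.

The model is cell-means on species (the trophic contrast is identical under
an intercept + indicators parameterization; cell means are clearer). With
n_s individuals for species s, residual df d = Σn_s − #species. The contrast
Δ = mean over MH species means − mean over AT species means has
se(Δ)² = s̃²·(Σ_{s∈MH} 1/(|MH|²n_s) + Σ_{s∈AT} 1/(|AT|²n_s)).

Variance moderation matches moments of log s² to a scaled-F prior
s² ~ s0²·F(d, d0): with e = log s² − ψ(d/2) + log(d/2),
excess = Var(e) − ψ′(d/2); if excess > 0, d0 = 2·ψ′⁻¹(excess) (inverse
trigamma by bracketed root-finding) and s0² = exp(mean(e) + ψ(d0/2) −
log(d0/2)); each s̃² = (d0·s0² + d·s²)/(d0 + d) and the moderated t has
d0 + d df. If excess ≤ 0 the prior df is infinite and every s̃² equals the
geometric mean of the s² (no chi-square bias correction in this degenerate
branch — with zero excess spread the observed values are the best common
estimate). d0 = 0 disables moderation and reproduces the ordinary contrast
t exactly (verified against a direct-formula oracle). No mean–variance
trend is fitted (see limitations).

Inversion classification: q ≥ α → unchanged; else inverted iff the MH and
AT group mean ratios have opposite signs (both exceeding a configurable
minimum magnitude, default 0 — no dead zone); else shifted.

## Enrichment

Hypergeometric over-representation only: p = P(X ≥ k),
X ~ Hypergeom(N, K, n), Bonferroni over terms with K ≥ 1 (BH reported
alongside). The universe is the set of ids surviving the stage's detection
filter, not the genome — enrichment is asked relative to what was testable.
Orthogroups inherit a term when ≥ 25 % of their member genes (pooled over
species; per-species denominators are not supported) carry it.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (spec, seed) via
`numpy.random.default_rng`.

- **Contig cohorts** carry evidence consistent with their truth label under
  the filter rules by construction (plant → Streptophyta hit; contaminant →
  fungal/bacterial hit, detection biased 8:1 toward underground samples;
  rescued conserved genes → non-plant hit + reference orthogroup; hitless →
  truth decided by the ≥ 2-sample rule). Perfect precision/recall on these
  cohorts therefore validates the *rules' implementation*, not the
  biological error rate of the rules on real data, where taxonomy is noisy
  and lineages incomplete.
- **Count experiments**: 4 species (2 MH, 2 AT), underground + stem, 2
  individuals each, 1–3 genes per orthogroup per species with Dirichlet
  proportions; gene counts NB with φ = 0.1 (a typical bulk-RNA-seq
  magnitude), orthogroup base means log-uniform in [5, 500], per-sample
  library factors log-uniform in [0.5, 2] so TMM is non-trivial, species
  scale factors likewise. Every null orthogroup shares one baseline
  underground/stem log2 ratio across species (sd 1.0 — organs genuinely
  differ); inverted orthogroups get ±effect in MH and ∓effect in AT with a
  random orientation per orthogroup, so inversions go both ways, as
  reprogramming does. A fraction of orthogroups is silenced in one random
  species to exercise the detection filter. Not emulated: gene-length
  effects, GC bias, phylogenetic covariance among species, organ-specific
  dispersion, mapping ambiguity between paralogs.
- **Repertoires**: per-ortholog Bernoulli detection (p = 0.9), reduced by
  `loss_fraction` in the focal group for planted-loss pathways.

## Numerical choices

- IRLS: flat-mean initialization on the offset scale, Fisher weights
  w = μ/(1 + φμ), ridge 1e-10 on XᵀWX, coefficient clip at ±100, μ floor
  1e-8, φ floor 1e-6.
- Inverse trigamma by `brentq` on [1e-8, 1e8] (trigamma is strictly
  decreasing), xtol 1e-12.
- Best-hit, trim-rank and BH tie-breaks are all deterministic (total orders
  or average ranks), so every result is reproducible bit-for-bit at a fixed
  seed.
- Zero residual variances are floored at 1e-8 of the smallest positive s²
  before taking logs in the moment matching.

## Analysis scale

The shipped drivers and test suite run the full pipeline at desk scale —
cohorts of 6,000–10,000 contigs, 1,000–2,000 orthogroups/genes, 140-pathway
screens, seeds 1–5 — sizes at which every stage's statistical behavior
(type-I control, FDR, parameter recovery) is measurable in seconds while
remaining comfortably powered.

## Known limitations

- **No mean–variance trend in the moderation.** Ratio variances rise as
  counts fall (Poisson noise through the log), and a single global prior
  under-shrinks low-count orthogroups; with many orthogroups at means ≲ 10
  the moderated test becomes anti-conservative in the far tail. A
  trend-aware prior would remove this; it is deliberately not fitted here.
- **TMM assumes the trimmed majority is ratio-stable.** If a large planted
  (or real) asymmetric shift overlaps the bulk of the M distribution — e.g.
  all inversions oriented the same way — the trimmed mean absorbs part of
  the signal and biases every null ratio anti-symmetrically between groups,
  inflating the contrast. With two-sided inversions (the default and the
  realistic case) the effect cancels. The one-sided regime remains reachable
  through the generator API for studying exactly this failure mode.
- The four-species detection filter removes photosynthesis-like orthogroups
  silent in one trophic group — by design, but it means group-specific
  losses must be studied with the repertoire module, not the ratio model.
- Fisher pooling of detection events treats species within a group as
  exchangeable draws; phylogenetic non-independence is not modeled anywhere.
- The organ-specific call is binary on detection and will miss genes with
  trace off-target expression unless `max_off_count` is raised.
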