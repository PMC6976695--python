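# Methods

This note documents the models, estimators and design choices behind
`picodepth`: what each stage computes, the tunable parameters and their
defaults, what the synthetic-data generator does and does not emulate, and
the numerical details that matter for reproducibility.

## Data model and bookkeeping

An `OtuTable` is an integer read-count matrix (OTUs × samples); one table
per template (rDNA, rRNA). Sample metadata carries the design (station,
depth, layer, ocean, template) and environment (temperature, salinity,
oxygen, nutrients, light, deep-scattering-layer flag, water-mass mix).
Layer boundaries default to surface ≤ 10 m, mesopelagic (200, 1000] m,
bathypelagic (1000, 4000] m; the DCM is a metadata label, never inferred
from depth, because its depth varies by station. Sublayers split the
mesopelagic at 500 m and the bathypelagic at 2000 m; both split points are
configurable (the survey design this package mirrors used sublayers
without stating their bounds).

**Rarefaction** draws each sample without replacement (multivariate
hypergeometric per column), so every retained column sums exactly to the
requested depth; the default depth is the minimum column sum. Samples
below the depth are dropped and logged, never padded. Unbiasedness is
checked in the tests: over ≥1,000 replicate seeds, mean subsampled counts
match `depth × count/column_sum` within four standard errors.

**OMZ definition**: oxygen strictly below a threshold, default
2 mg O₂ L⁻¹, configurable.

## Relative activity

For each station-depth with both templates, each OTU with non-zero
relative abundance in *both* gets one ratio `p(RNA)/p(DNA)`. Zeros exclude
— no pseudo-counts — because an undetected OTU gives no information about
activity, and pseudo-counts would manufacture spurious extreme ratios at
the rare tail. The exclusion rule is applied per paired sample (the only
reading that keeps every stored ratio finite); a whole-dataset pre-filter
is available as an option.

Classification uses a band around parity, default (0.5, 2.0): within
two-fold of parity is "average", above "hyperactive", below "hypoactive".
The band has no canonical value; it is a mandatory, explicit parameter
echoed into all output headers.

**Layer contrasts** pool all OTU-sample ratios of a group within each
layer (one value per OTU per pair; pooling, not per-OTU medians, because
each ratio is an independent observation of the group's state in one water
sample). Layers are compared pairwise with two-sided Mann–Whitney
rank-sum tests — the layers have different pair counts, so a paired test
is impossible — with Benjamini–Hochberg correction across the ≤6 pairwise
comparisons per group; raw and adjusted p are both reported. A layer is
flagged *significantly high* for a group when every pairwise test against
the other layers is significant after correction **and** the layer is
stochastically higher in each (common-language effect size
P(X > Y) > 1/2); symmetric rule for *significantly low*. Direction is
taken from the test's own effect size rather than comparing sample
medians because pooled count ratios are discrete — medians of two clearly
different distributions can tie exactly at 1.0 (e.g., many 1-read/1-read
OTUs) — whereas the rank-based direction is what the significance test
actually measures. Layer medians are still computed and reported.

**Layer of maximum activity** considers only OTUs with at least one ratio
in all four layers; each is assigned the argmax of its per-layer median
ratios. Exact ties are flagged ambiguous and excluded from downstream
layer sets.

## Diversity

Shannon H′ uses the natural log (the convention of the R ecology stack).
Bray–Curtis comes from `scipy`'s `pdist` and is held in a
`skbio.DistanceMatrix`.

**ANOSIM** follows Clarke (1993): mid-ranks of all pairwise
dissimilarities, `R = (r̄_between − r̄_within) / (M/2)` with
`M = n(n−1)/2`; the p-value is one-sided,
`(#{R* ≥ R} + 1)/(n_perm + 1)`, over label permutations driven by an
explicit seed (default 1,000 permutations). Implemented here rather than
delegated because seeded determinism and exact brute-force equality on
small fixtures are package contracts; the statistic is cross-checked
against scikit-bio's in the tests.

**PERMANOVA** partitions the Gower-centred matrix
`G = −½ J D² J` with sequential (Type-I) sums of squares over an ordered
term list: `SS_k = tr[(H_k − H_{k−1}) G]` with nested hat matrices,
pseudo-F per term against the residual, p by permuting sample identities
(rows/columns of G; default 999 permutations). Terms are dummy-coded
factors or numeric covariates; constant/collinear terms are dropped with
a warning. Sequential SS means term order matters — the order is the
user's model statement. In the univariate Euclidean limit the pseudo-F
equals the classical one-way ANOVA F exactly (tested). Reported R² per
term plus residual sum to 1.

Note on conventions: ANOSIM yields R, not R². Survey literature sometimes
prints ANOSIM effect sizes labelled "R²"; this package reports R and makes
no attempt to reproduce such values.

**NMDS** minimises Kruskal stress-1 by alternating isotonic regression
(pool-adjacent-violators; ties in the observed dissimilarities are treated
by the primary approach — within a tie block, disorder carries no penalty)
with SMACOF/Guttman configuration updates. The first start is the
classical (principal-coordinate) configuration, which also makes the
result equivariant under sample reordering; remaining starts (default 20)
are random. Convergence at stress change < 1e-6 or 500 iterations, with a
monotone safeguard: an update that would increase stress-1 stops the run
at the previous configuration, so the reported stress path is
non-increasing by construction. Output coordinates are centred, rotated
to principal axes and sign-fixed, making reruns reproducible up to the
rotation/reflection invariance inherent to NMDS.

## Biogeography

Per-layer (or per-sublayer) dissimilarity distributions take all pairwise
values among the stratum's samples, by default one sample per station per
stratum (the shallowest), matching the convention of comparing one sample
of each water layer among stations. Prevalence curves count OTUs by the
number of stations where they are detected (≥1 read); the fraction
present in ≥80% of stations is reported (the threshold and the
station-vs-sample interpretation are configurable). Layer-restricted OTUs
are those whose reads fall entirely in one layer, among OTUs with total
reads strictly greater than 5 (per-sample variant available). The shared
matrix counts OTUs detected in both layers of each pair.

## Zones (OMZ, DSL)

`define_zone` splits the mesopelagic samples by the oxygen rule (OMZ) or
the metadata flag (DSL). Per group, the zone contrast reports the ratio of
mean relative abundance (zone / complement; the rRNA table by default) and
the ratio of median rRNA:rDNA activity between zone pairs and complement
pairs. Mean for abundance, median for activity (robust to the ratio's
heavy tail); both statistics are switchable. Groups below 0.05% of total
mesopelagic reads are excluded; groups with data on one side only are
reported with a reason code, never as an infinite ratio. The richness
contrast is a two-sided rank-sum test of per-sample richness on rarefied
counts.

## Phylogeny

Trees are inputs (newick with branch lengths; inference is upstream and
out of scope). Validation rejects duplicate tips, negative lengths and
missing lengths; a tree whose root has more than two children is treated
as unrooted and midpoint-rooted with a warning; internal multifurcations
are accepted. Generalized UniFrac is computed with a single post-order
accumulation of per-branch descendant proportions; the root branch is
excluded; branches with no abundance on either side contribute nothing.
α = 0.5 by default (down-weighting abundant lineages); α = 1 equals
weighted-normalised UniFrac and is tested against an independent
per-branch enumeration and against scikit-bio. The distance is invariant
to rescaling all branch lengths. Layer vectors for the layer-distance
matrix are the summed rRNA relative abundances of each layer's
preferential OTUs over that layer's samples, normalised to 1 (an
unweighted presence/absence variant is a configuration choice).

## Synthetic-data generator

The generator emulates the statistical structure of a global
depth-stratified paired survey; its defaults are the study conditions the
package is tested under.

Design: 13 stations across Atlantic/Indian/Pacific, 7 depths each (3 m
surface, 80 m DCM, 300/700 m mesopelagic, 1500/2750/4000 m bathypelagic)
= 91 station-depths, two templates each; 25,000 reads per sample
(matching the rarefaction-depth scale of real surveys); 4 Pacific
stations carry an OMZ at both mesopelagic depths (8 OMZ samples), and 9
stations carry a DSL flag at 300 m. Environmental covariates are
generated consistently with layer (light only photic, temperature
decaying with depth, nutrients rising, oxygen < 2 mg/L only at OMZ
cells, water-mass mixtures only in the bathypelagic).

Generative model per sample: group depth-response archetypes (increase /
decrease with depth, mesopelagic peak, DCM peak) set expected group mass
per layer; OTU masses are log-normal within group (σ = 1.5) with
per-station log-normal drift whose σ grows with depth (0.3 / 0.4 / 0.8 /
1.3 by layer); masses are normalised to cell proportions; rDNA
proportions multiply in per-group copy factors (MALV-I ×10, MALV-II ×8);
rRNA proportions multiply in per-(group, layer) activity factors; OMZ
samples multiply designated groups (Ciliophora ×4, Dinoflagellata ×3,
MALV-III ×2); reads are multinomial. Default activity factors plant the
depth-activity structure: heterotrophs ×3 in the mesopelagic and ×0.3 in
the bathypelagic, phototrophs ×2 at the DCM, mixotrophs ×2 in the dark
ocean. The mixotroph term is not decoration: rRNA:rDNA ratios are closed
(relative abundances), so a uniform activity collapse is invisible —
somebody must absorb the bathypelagic rRNA pool for everyone else's
hypoactivity to register, and dark-ocean mixotrophy is the biologically
sensible absorber.

Scale: 600 OTUs per group (9,600 total) at 25,000 reads per sample puts
typical OTUs near the detection boundary, the regime real surveys occupy
(OTU counts of the same order as per-sample read counts). This is what
makes prevalence curves decline, layer-restricted OTUs exist, and
between-layer sharing structured; a much smaller roster saturates
detection and erases those patterns. The effect sizes above are
calibration choices for testability — the source surveys report the
qualitative shapes, not magnitudes — and are configuration, not code.

What the generator does **not** emulate: sequence-level artefacts (PCR
bias, chimeras), overdispersion beyond multinomial (a deliberate default,
keeping oracles closed-form; real amplicon counts are overdispersed),
taxon-specific copy-number variation within groups, seasonal or
geographic covariance beyond the station drift, and any DSL effect
(deliberately null). Passing tests therefore demonstrate that the
analysis recovers planted structure under idealised sampling noise, not
that it is robust to every artefact of real amplicon data.

Read sampling is multinomial rather than Dirichlet-multinomial by
default; the per-station log-normal drift already injects
between-replicate variance at the community level.

## Numerical and degenerate-input conventions

All randomness flows through `numpy.random.default_rng` with explicit
seeds; reruns are byte-identical (tested on the full pipeline). Relative
abundance columns must sum to 1 within 1e-9; gUniFrac input vectors
within 1e-6. Permutation p-values are never below `1/(n_perm+1)`.
Rank-sum tests on identical arrays short-circuit to p = 1. Ties in
layer-of-maximum-activity medians mark the OTU ambiguous rather than
picking arbitrarily. Empty zones, strata with fewer than two samples,
groups with fewer than two layers of data, and unpaired samples are
skipped with log messages, not silently dropped.

## Known limitations

* rRNA:rDNA ratios are *relative* activity only; rDNA copy number varies
  across taxa, so ratios are comparable within a group across layers, not
  across groups. No growth-rate inference is attempted.
* Sequential-SS PERMANOVA makes explained-variance percentages depend on
  term order; marginal (Type-III) tests are not implemented.
* The compositional closure of both templates means community-wide
  activity shifts are unidentifiable; only differential structure is.
* Desk-scale simulations (9,600 OTUs) are an order of magnitude smaller
  than real surveys; absolute values of detection-dependent quantities
  (restricted-OTU fractions, UniFrac magnitudes) should be read as
  qualitative analogues, not predictions.
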