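# Methods

This note records the model, the defaults, and the design choices made
where the design was genuinely open.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study design assumed

Two data types from a repeated-dehydration experiment on maize
seedlings:

- **Transcriptome**: FPKM-normalised expression at stages W (watered),
  S1 (first 90-min dehydration) and S3 (third dehydration), two
  biological replicates each (six samples).
- **Physiology**: per-plant measurements at W, S1, R1 (rehydration) and
  S2 (second dehydration) — gas exchange, PAM chlorophyll-a
  fluorescence, relative water content, foliar ABA and chlorophyll.

Selected genes respond alike in S2 and S3, so the two repeated-stress
stages are declared equivalent (`StageDesign.equivalence_map`); the
transcriptome's S3 response is reported as the repeated-stress (S2)
response, and S2 physiology pairs with S3 transcriptome samples during
integration.  R1 physiology has no transcriptome counterpart and is
excluded from correlations — a declared convention, since the original
design leaves the pairing open.

## Differential expression and memory patterns

The triple significance rule per contrast: BH-adjusted q ≤ 0.05,
|log₂FC| ≥ 1 (pseudocount 1 on FPKM means, so fold changes stay bounded
for zero-FPKM genes), and an expression floor — in at least one of the
two contrasted stage-mean profiles the gene strictly exceeds that
profile's 25th percentile (linear interpolation between order
statistics; "sample" is read as the stage-level profile, replicates
averaged first).

The original DE statistics came from an upstream RNA-seq pipeline whose
settings are not fully specified; this package therefore (a) ingests
external per-gene (log2fc, q) tables unchanged, and (b) provides an
internal test path: a two-sided t on log₂(FPKM+1) replicates.  With two
replicates per stage a raw per-gene variance estimate has so few degrees
of freedom that true 2-log₂FC effects are missed at an ~8–9% rate, so the
internal path shrinks the per-gene pooled variance toward an
empirical-Bayes prior shared across genes (scaled inverse-chi-square
prior fitted by moments of log s², the standard moderated-t device for
small-n expression designs) before forming the statistic.
`moderate_var=False` gives the plain Welch t.  Internal q-values are a
stand-in and will not numerically match values from a count-model
pipeline.

An optional third gate (`require_stable_repeat`) additionally demands no
significant S2–S3 difference when both repeated stresses are present;
off by default.

## Co-expression network

- Correlation on log₂(FPKM+1): variance stabilisation for heavy-tailed
  FPKM; the network is unsigned (d = 1 − |r|) by default, with a
  topological-overlap option (adjacency |r|^β, default soft power 6).
- **Cut height.** With n = 6 samples the null distribution of the
  Pearson correlation between unrelated genes has density ∝ (1 − r²):
  P(|r| > 0.75) ≈ 9% per pair, so thousands of background genes form
  large chance clusters at moderate cut heights.  The default module
  criterion is therefore d ≤ 0.05 (|r| ≥ 0.95, chance ≈ 0.2% per pair);
  at this height spurious 30-gene clusters were never observed across
  seeds while planted modules (within-module d ≈ 0.01–0.08 at the
  default noise) survive intact.  `cut_height` is a config key.
- **Dynamic tree cut.** Deterministic tree-structured variant: maximal
  average-linkage branches whose merges all sit at or below the cut are
  module candidates; a candidate splits recursively at its top merge
  when the merge height exceeds both children's internal heights by a
  significant gap (≥ 50% of the merge height) and both children meet
  the size floor (minimum module size 30).  The PAM-like reassignment
  stage of the hybrid algorithm is intentionally omitted — a documented
  simplification that keeps the cut deterministic.  Linkage ties are
  resolved by the deterministic nearest-neighbour chain over the input
  gene order.
- Mirror-image profiles (x and −x) are indistinguishable in an unsigned
  network; the synthetic generator's default profiles avoid mirror
  pairs for this reason.
- Eigengenes are unit-norm first right singular vectors of the
  standardised (per-gene mean 0, sd 1, ddof 1) module matrix, oriented
  to correlate non-negatively with the module's mean standardised
  profile; explained variance is s₁²/Σs².  Meta-modules: average
  linkage on 1 − r between eigengenes, cut at 0.2; singleton groups are
  solo modules.

## Physiology

Fluorescence yields follow the Genty-style definitions (φPSII,
Fv′/Fm′, qP) with the Oxborough–Baker Fo′ estimate when Fo′ is
unmeasured; the identity φPSII = qP × Fv′/Fm′ holds algebraically and is
enforced to 1e−12 in tests.  ETR uses PSII fraction 0.5 and leaf
absorptance 0.85 (both config keys).  The qE/φqE pair is derived from a
post-relaxation maximal fluorescence (relaxed Fm′):
qE = Fm/Fm′ − Fm/Fm′ᵣ and φqE = Fs/Fm′ − Fs/Fm′ᵣ; without a relaxation
measurement all NPQ is attributed to qE and the output is flagged.  The
exact published qE expressions are not printed in the source literature
summary available here, so the relaxation-based definitions are a
documented stand-in.  A_G = P_N + R_d with R_d a config input;
φCO₂ = A_G/(PPFD × absorptance).

Memory calls per parameter use the same sign scheme as genes, from
two-sided two-sample t tests at α = 0.05.  Welch's t is the default
(variances differ visibly between watered and stressed stages); a
pooled-variance Student's t flag mirrors the original description
verbatim.  Chlorophyll, analysed in the original study with a
mixed-effects model (experiment date as random intercept), is here
classified with the same t-test scheme as every other parameter — a
deliberate simplification.  No multiple-comparison correction is applied
across stage contrasts, matching the displayed raw pairwise letters.

## Integration

Transcriptome replicates and physiology plants are different
individuals, so pairing replicates one-to-one would be arbitrary; each
parameter's stage mean is instead replicated to every transcriptome
sample of the matching stage (n = 6 paired points for the default
design).  A `stage_means_only` flag collapses to n = 3.  Raw per-cell p
values are reported (matching the displayed correlation grids); BH
adjustment across the grid is available but off by default.  Constant
trait vectors yield undefined cells, never r = 0.

## Enrichment

One-sided over-representation only (hypergeometric upper tail), the
convention of agricultural GO web services; terms with fewer than 5
reference mappings are not tested (the "minimum mapping entries"
criterion applied to the reference count K).  FDR is computed within
each module's term list — matching per-list web runs — with a global
option.  Annotations are used exactly as provided: GO-graph ancestor
propagation is out of scope and must be done upstream if desired.

## Synthetic data

The generator emulates the study conditions: 2000 genes, five planted
50-gene modules, two replicates per stage, Gaussian noise of sd 0.1 on
the log₂(FPKM+1) scale (lognormal-type replicate noise after
back-transformation, which keeps FPKM non-negative), gene loadings
N(1, 0.15) clipped to [0.5, 1.5], background genes flat at
log₂-levels U(1, 5).  Default module profiles place effects at twice the
|log₂FC| ≥ 1 threshold and are validated against their declared memory
patterns before sampling; pairwise profile |r| stays ≤ 0.87 with no
mirror pairs so an unsigned network can separate them.  One GO term per
module is planted at odds 8 over a 5% annotation baseline, plus 20 null
terms.  Physiology defaults encode the qualitative pattern calls of the
original experiment (g_s and E [−/−]; RWC and C_i [−/=]; ABA [+/=];
P_N, φPSII, ETR, qP, Fv′/Fm′, φCO₂ [=/−]; qE, φqE, qE/ETR, φPSII/φCO₂,
ETR/A_G [=/+]; chlorophyll [−/−]), with "=" legs planted at exactly
equal means so the zero-noise limit is well defined; plant-to-plant sd
defaults to 8% of the watered mean with 10 plants per stage.  A raw
fluorescence mode inverts the closed-form identities to emit Fs, Fm′,
Fo, Fm and relaxed Fm′ whose derivation recovers the planted targets to
round-off.  All randomness flows from one integer seed through numpy's
PCG64 generator; outputs are bit-identical across runs.

What the generator does **not** emulate: count-level (negative-binomial)
sequencing noise, gene-length and library-size artefacts, correlated
background structure, batch effects, or instrument drift.  Passing the
planted-recovery suites therefore shows the pipeline's operations are
correct and coherent at the study's design scale — not that the
original genome-scale module memberships would be reproduced, which
would require the original data and the unstated upstream settings.

## Problem sizes and numerics

The acceptance runs use the default conditions above (2000 genes; the
exhaustive Fisher-oracle check enumerates all tables with N ≤ 20 plus
300 random tables with N ≤ 200).  Percentile and linkage tie-breaks are
documented in their docstrings; percentages are rounded half away from
zero to match the printed style while exact fractions are retained in
machine output.  Degenerate inputs (zero-variance genes, constant
traits, zero-variance t tests, single-gene modules) have defined
behaviour and dedicated tests.

## Known limitations

- Internal DE q-values are not a count-model reimplementation.
- The dynamic tree cut is the deterministic tree variant; module counts
  on real data will differ from WGCNA's hybrid cut.
- Unsigned networks conflate mirrored profiles.
- GO annotations are taken flat (no DAG propagation).
- The chlorophyll mixed-effects analysis is simplified to t tests.
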