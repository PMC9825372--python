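# Methods

This note documents the models, parameter choices, numerical decisions,
and known limitations of `primeseq`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate and data conventions

All genomic coordinates are 0-based half-open internally (BED
convention); GTF input is converted at the I/O boundary. One transcript
model per gene (the longest when a GTF carries several): the analysis is
gene-level throughout, so isoform choice would only add ambiguity. Sample
metadata lives in a separate tab-separated design table keyed by
`sample_id` with closed factor vocabularies (exercise ELE/SED, learning
none/3min/10min, hemisphere L/R/both, isolation simultaneous/separate,
assay RNA/CUTRUN, antibody H4K8ac/H3K27me3/IgG/NA).

## Differential expression

**Model.** NB2 GLM with log link: counts K_gj ~ NB(s_j · μ_gj, α_g),
Var = μ + α μ². Size factors are median-of-ratios (reference = per-gene
geometric mean over samples, using genes with no zero count; a
`pseudo_reference` fallback uses positive-part geometric means for sparse
matrices). Dispersions are gene-wise method-of-moments on normalized
counts after removing group means, `α = max(1e-8, (var − mean)/mean²)`.
There is **no shrinkage toward a fitted trend** and no outlier
refitting — a deliberate deviation from shrinkage-based reference
packages: the estimator is simple, unbiased in the regimes the tests
probe, and fully oracle-checkable. The cost is noisier per-gene α at
n = 2–3, which inflates neither the Wald type-I error (measured: in
[0.03, 0.07] at nominal 0.05, n = 50/group) nor the LRT null calibration
(KS-uniform in ≥ 18/20 seeds), both recomputed by the acceptance script.

**Fitting.** IRLS vectorized across genes sharing a design matrix
(batched normal equations, weights μ/(1 + αμ)), convergence when the max
coefficient change drops below 1e-8, 100-iteration cap; non-converged or
all-zero genes carry NaN statistics and are excluded from the BH batch
rather than assigned p = 1, so they do not deflate the correction.
Linear predictors are clipped to ±30 on the natural-log scale to keep
exp() finite during early iterations.

**Tests.** Wald: z = β̂/SE from the observed-information covariance,
two-sided normal tail. LRT: 2(ℓ_full − ℓ_reduced) against χ² with df =
parameter difference; term lists use treatment coding with SED / none /
L / simultaneous as reference levels. The three reduced models used to
attribute genes to design terms are drop-one-term reductions of
`hemisphere + exercise + hemisphere:exercise` (dropping the exercise main
effect, the hemisphere main effect, or the interaction respectively).
Two-way ANOVA: OLS on log2(normalized + 1), classic sequential (type-I)
F tests in formula order, run per gene via shared projection matrices;
constant genes report NaN (zero residual variance). The log2(x+1)
transform stands in for a variance-stabilizing transform; the concordance
statistics applied downstream are rank-based and insensitive to the
choice of monotone transform.

**DEG criterion.** |log2FC| > log2(1.3) ≈ 0.3785 and raw p < 0.05, both
strict. Raw p (not padj) gates the call; padj (Benjamini–Hochberg via
statsmodels, NaNs excluded and reinserted) is reported alongside and can
be selected with `use="padj"`. Supplying 0.3875 as the cutoff triggers a
warning: that figure is a transposition of log2(1.3) and inconsistent
with the ">30% change" definition.

**A note on normalization invariance.** Multiplying *all* samples'
counts by c (with dispersions rescaled by 1/c, since α is in count
units) leaves fold-change estimates unchanged to solver tolerance — the
offsets absorb it exactly. Scaling a *single* sample is absorbed by its
size factor only asymptotically: the NB score equation weights samples
by their fitted means, so per-gene estimates shift by O(1/n). The test
suite asserts the exact all-sample form and bounds the single-sample
perturbation.

## Peak calling

The calling unit is the signal block: a maximal run of strictly positive
depth (blocks separated by any zero-depth gap are never merged by
default; `max_gap` exists but defaults to 0, matching the
sparse-enrichment philosophy). Score = AUC = Σ depth × length.

*Numeric mode*: AUC threshold is the empirical (1 − fraction)-quantile
with "higher" (ceiling) interpolation, so the kept fraction never
exceeds the request except through ties; ties at the threshold are all
kept (no seed-dependent peak lists). Stringent mode adds the analogous
max-depth gate; relaxed gates on AUC alone. The stringent double gate
under a numeric threshold is this package's own definition, not a
re-implementation of any upstream tool's internals.

*Control mode*: candidate thresholds are the union of observed AUCs; the
chosen threshold maximizes frac(target ≥ t) − frac(control ≥ t), with
the smallest t on (float-tolerant) ties and a warning when the
difference curve is entirely flat. Empirical FDR = #control ≥ t /
#target ≥ t; samples above 0.1 are excluded by the QC filter, which
reports each exclusion. The "top 1% with FDR < 0.1" phrasing common in
this field is interpreted as two independent controls — numeric 1%
calling plus per-sample control-based FDR QC — rather than a per-peak
FDR; the per-peak reading is not implemented.

The integrated pipeline defaults to control mode with relaxed gating:
the IgG threshold already supplies the specificity that the stringent
depth gate contributes in numeric mode.

## Peak annotation

Categories are evaluated in the fixed priority order Promoter → 5′UTR →
3′UTR → Exon → Intron → Downstream → DistalIntergenic; the first
applicable wins, making annotation a total function (every peak gets
exactly one category and one gene). The promoter window is the closed
interval TSS ± 3000 bp regardless of strand extent conventions;
downstream is 3000 bp past the 3′ end in gene orientation; overlap means
≥ 1 bp intersection in half-open arithmetic. The assigned gene is the
one supplying the winning feature; ties break by smallest |midpoint
distance to TSS|, then lexicographic gene id. Distal-intergenic peaks
are assigned the nearest TSS. Since minimal annotations carry no CDS,
the 5′/3′ UTRs are proxied by the first/last 10% of the first/last exon
in transcript orientation — an explicit approximation that lets the full
category vocabulary be exercised; supply true UTR features for real
annotations where this matters. The fast path uses per-category interval
trees and is property-tested equal to a quadratic brute-force scan.

## Priming integration

Gene-level mark dynamics per antibody: new = present in ELE only, lost =
present in SED only, shared = both, where "present" means ≥ 1 annotated
peak of that antibody/condition in any category ("new/lost" status is
gene-level, not region-level; a region-level mode would be a natural
extension). Classification (per direction, all DEG sets relative to the
no-exercise/no-learning baseline):

    cGAMES = deg(ELE+3min) ∩ deg(SED+10min)
    cGAME  = deg(ELE+3min) \ [deg(ELE alone) ∪ deg(SED+3min) ∪ deg(SED+10min)]
    cGAMS  = deg(SED+10min) \ [deg(ELE alone) ∪ deg(SED+3min) ∪ deg(ELE+3min)]

cGAME excludes genes significant under exercise alone (the strict
reading of "not changed in any other group"); `exclude_ele_alone=False`
gives the laxer definition. cGAMES is the intersection reading of
"changed in the threshold-learning groups"; a union-with-exclusions
reading would be a different class and is not implemented. Genes may be
classified independently per direction. Priming fractions score
up-classes against new H4K8ac ∪ lost H3K27me3 and down-classes against
new H3K27me3 ∪ lost H4K8ac, reporting each component and the union;
display percentages round half away from zero (58/145 → 40%,
76/256 → 30%); empty classes report NaN with count 0. Z-scores are row
standardizations of per-gene log2FC across the three learning-relevant
groups (exercise alone excluded by default, configurable); zero-SD rows
are excluded and counted; concordance is the fraction of primed genes
whose ELE+3min and SED+10min z-scores share a sign.

## Concordance module

Tracks are binned (100 bp default) with exact signal conservation
(Σ bin values = track integral, asserted in tests), normalized to
counts-per-million of the chromosome total — the simplest read-depth
normalization, and rank-preserving, so Spearman is unaffected by the
constant. Bins with zero signal in *both* tracks are excluded by default
(they contribute pure ties and degenerate the rank statistic; a flag
retains them). Spearman uses average ranks for ties and the large-sample
t approximation for p; p-values below 2.2e-16 display as "<2.2e-16".
The concordance rule is ρ > 0.5 and p < 2.2e-16. The gene-length-bias
comparison between two DE results (difference of length–log2FC Spearman
correlations with a seeded gene-wise sign-flip permutation p) is an
added statistic of this package, labeled as such in its output.

## Synthetic data: what it emulates, and what it does not

The generator produces the full paired study: a genome of
non-overlapping gene models (2–10 exons, ≥ 10 kb inter-gene gaps), NB
counts over the five behavioral groups, and 10-bp-tile Poisson coverage
run-length-encoded to bedGraph.

**Study conditions (defaults, chosen once):**

- Group sizes 3/3/3/2/2 (baseline, exercise alone, exercise+3 min,
  sedentary+3 min, sedentary+10 min): exercised-group n = 3 vs sedentary
  n = 2 exercises the unbalanced-design path.
- Baseline means log-normal, median 150 (σ = 1 ln-units); planted-DEG
  genes floored at μ = 100, reflecting that behaviorally responsive
  panels sit in the robustly expressed range.
- Dispersions log-normal, median 0.01 (σ = 0.5): isogenic animals and a
  purified neuronal population put biological dispersion at the clean
  end of bulk RNA-seq.
- Planted |log2FC| uniform on [log2(1.3) + 0.2, 2.0]: the +0.2 margin
  separates power testing from threshold-boundary behavior, which is
  tested separately; library-size factors log-normal (σ = 0.15).
- Class sizes: 200/150/100 up and 80/80/60 down (cGAMES/cGAME/cGAMS),
  plus exercise-alone and subthreshold-learning DEGs, on a 1500-gene
  panel — a deliberately class-enriched, scaled-down panel (not a
  transcriptome): it keeps 20-seed end-to-end experiments inside a few
  minutes while leaving ~500 null genes to measure false classification.
- Priming plants: new H4K8ac at 40% of cGAMES-up and 30% of cGAME-up
  genes (promoter-centered peaks, widths 400–1200 bp), smaller lost-mark
  and repressive-mark fractions, H4K8ac shared peaks at 45% of all genes
  (active promoters) and H3K27me3 at 15% (broad repressive domains).
- Coverage: background Poisson 0.002 per 10-bp tile; within a peak the
  tile rate becomes λ_bg × fold (default fold 1750, i.e. ~3.5 expected
  fragments per tile) — antibody-directed cleavage concentrates
  fragments at true sites, and the block-level peak:background ratio
  must be realistic for threshold-against-control calling to be
  well-posed: when target and IgG backgrounds are identical, the
  threshold-scan objective is flat across the background AUC range and
  only the peak fraction tilts it upward, so peaks must be a
  non-negligible fraction of blocks (as in real sparse-enrichment data).
  With zero background the fold is read as the absolute per-tile rate.
  `noise_free=True` replaces all sampling with deterministic expected
  values (and the pipeline is then run with numeric fraction-1.0
  calling, every block being a planted peak), enabling exact end-to-end
  recovery checks.

**Not emulated:** read-level artifacts (fragment lengths, duplicates,
mappability), batch effects beyond the hemisphere/isolation factors,
correlated background structure between conditions, chromatin-state
autocorrelation, and transcriptome-scale gene counts. Passing the
recovery tests therefore demonstrates the correctness and calibration of
the inference chain under its stated model, not robustness to upstream
artifacts real data would add.

## Degenerate inputs and tie-breaks (summary)

Empty block lists: numeric calling returns an empty peak set with a
warning; control mode requires nonempty inputs (the pipeline maps a
signal-free track to an empty peak set instead of an error). Empty
classes: NaN fractions, zero counts. All-tie Spearman inputs: NaN ρ.
Constant ANOVA responses: NaN. Annotation ties: smallest |TSS distance|
then lexicographic gene id. Numeric-calling ties: all kept.
Control-threshold ties: smallest threshold.

## Known limitations

- No dispersion shrinkage or outlier handling; per-gene α is noisy at
  n = 2–3 (calibration is still within the tested bands).
- Gene-level annotation only; no isoform or CpG/enhancer categories.
- UTR proxies are heuristics absent CDS annotation.
- The per-sample (not per-peak) reading of control-based FDR QC.
- Spike-in calibration of coverage tracks is out of scope; tracks are
  compared after CPM normalization only.
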