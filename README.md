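# primeseq

Paired translatome–epigenome analysis for exercise/learning studies:
negative-binomial differential expression of TRAP-seq counts,
sparse-enrichment CUT&RUN peak calling against an IgG control,
priority-ordered peak-to-gene annotation, and an integration step that asks
which genes early-life exercise (ELE) has epigenetically *primed* for
expression during later learning.

## Who this is for

Labs pairing a translatome readout (TRAP-seq, or any gene-level count
matrix) with histone-modification CUT&RUN tracks from the same animals,
across a behavioral design of exercise (ELE vs sedentary) × learning
stimulus (none / subthreshold 3 min / threshold 10 min object-location
training), who want the full inference chain — DEGs, peaks, peak→gene
assignment, and the priming classification — as tested, scriptable Python
rather than a one-off collection of R sessions.

## The model and the statistic

**Differential expression.** Counts for gene *g*, sample *j* follow
NB(mean = *s<sub>j</sub>µ<sub>gj</sub>*, dispersion *α<sub>g</sub>*) with
median-of-ratios size factors *s<sub>j</sub>*, a log-link GLM fit by IRLS,
and gene-wise method-of-moments dispersions (no shrinkage — a documented
deviation from shrinkage-based packages). Tests: Wald *z* on a two-level
contrast, likelihood-ratio between nested designs (e.g. full
`hemisphere + exercise + hemisphere:exercise` against reduced models to
attribute genes to terms), and per-gene two-way ANOVA on
log2(normalized + 1). A gene is a DEG when |log2FC| > log2(1.3) ≈ 0.3785
(a >30% change) and raw *p* < 0.05, both strict.

**Peak calling.** Coverage is segmented into maximal positive-depth blocks
scored by AUC (depth × length). Numeric mode keeps the top fraction
(default 1%, stringent mode double-gates on max depth); control mode picks
the AUC threshold maximizing the target-minus-IgG fraction of surviving
blocks and reports an empirical FDR (#control ≥ t / #target ≥ t); samples
with FDR > 0.1 are excluded.

**Annotation.** Each peak gets the first applicable category in the fixed
priority order Promoter (TSS ± 3000 bp), 5′UTR, 3′UTR, Exon, Intron,
Downstream (3000 bp), DistalIntergenic, and the gene supplying that
feature (nearest TSS on ties).

**Priming classification.** With per-group DEG sets relative to the
no-exercise/no-learning baseline, per direction:

- `cGAMES` = DEG(ELE+3min) ∩ DEG(SED+10min) — changed in both
  threshold-learning groups;
- `cGAME` = DEG(ELE+3min) minus all other groups — exercise-enabled
  learning genes only;
- `cGAMS` = DEG(SED+10min) minus all other groups.

Each class is scored for ELE-induced mark changes: for up-genes, new
H4K8ac (permissive) or lost H3K27me3 (repressive mark removed); for
down-genes the converse. A per-gene *z*-score of fold changes across the
three learning-relevant groups quantifies whether primed genes move in the
same direction in exercised-3-min and sedentary-10-min animals.

## Worked example

Every stage has a synthetic twin with planted ground truth, so the whole
pipeline runs end to end without external data:

```python
from primeseq.simulate import make_fixture_study
from primeseq.priming import run_study

study = make_fixture_study(seed=1)          # genome, counts, coverage, truth
report = run_study(study.genome, study.counts, study.tracks, study.igg)

for grp, degs in sorted(report.deg_by_group.items()):
    print(f"{grp}: {len(degs.up)} up / {len(degs.down)} down DEGs")
for (ab, cond), ps in sorted(report.peaksets.items()):
    print(f"{ab} {cond}: {len(ps)} peaks (empirical FDR {ps.empirical_fdr:.3f})")
print(report.priming.rows[["direction", "class", "total", "n_primed",
                           "percent_primed"]].to_string(index=False))
print(f"z-score sign concordance of primed genes: {report.priming.concordance:.2f}")
```

prints

```
ELE_3min: 350 up / 191 down DEGs
ELE_none: 77 up / 71 down DEGs
SED_10min: 302 up / 166 down DEGs
SED_3min: 56 up / 60 down DEGs
H3K27me3 ELE: 804 peaks (empirical FDR 0.030)
H3K27me3 SED: 902 peaks (empirical FDR 0.021)
H4K8ac ELE: 2758 peaks (empirical FDR 0.009)
H4K8ac SED: 2250 peaks (empirical FDR 0.008)
direction  class  total  n_primed  percent_primed
       up  cGAME    153        52              34
       up cGAMES    193        90              47
       up  cGAMS    104        17              16
     down  cGAME     94        12              13
     down cGAMES     89        12              13
     down  cGAMS     74         2               3
z-score sign concordance of primed genes: 0.63
```

The fixture plants 200 cGAMES / 150 cGAME / 100 cGAMS up-genes (80/80/60
down) with 40% of cGAMES-up and 30% of cGAME-up genes given a new H4K8ac
peak in the exercised condition; the run above recovers the classes with
micro-F1 ≈ 0.94 and the planted new-H4K8ac fractions within a few percent
(the `n_primed` column additionally counts genes with lost H3K27me3, so it
sits above the new-H4K8ac component alone). The threshold-learning groups'
DEG counts dwarf the subthreshold (3 min sedentary) group, as designed.

A `primeseq` console script exposes the same stages
(`simulate`, `de`, `callpeaks`, `annotate`, `compare`, `integrate`/`run`);
see `primeseq --help`.

## Concordance utilities

`primeseq.compare` bins coverage tracks (100 bp default), normalizes to
counts-per-million, and reports Spearman's ρ with the rule "concordant
when ρ > 0.5 and p < 2.2e-16", plus gene-length-bias summaries of DE
results with a seeded permutation comparison between two methods.

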