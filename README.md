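# t3enh

Classification of thyroid-hormone (T3) responsive enhancers from
multi-factor ChIP-seq, Hi-C and RNA-seq count data.

## The problem

Hormone-dependent enhancer activation is classically described by a
bimodal switch: without ligand the thyroid hormone receptor (TR)
tethers the NCoR corepressor complex (NCOR1-HDAC3) to chromatin and
keeps nearby histones hypoacetylated; with T3 the corepressor leaves,
histone acetyltransferases (CBP/p300, SRC1) arrive, and H3K9/H3K27
become hyperacetylated. Genome-wide data complicate this picture in two
ways: many TR binding sites (TRBSs) carry no HDAC3 at all and only
acquire TR, HATs, MED1 and DNase accessibility together with the
hormone; and a sizeable fraction of hyperacetylated regions carries no
TRBS yet still requires functional TR, plausibly through co-regulation
inside super-enhancers (SEs), topologically associating domains (TADs)
or direct chromatin loops.

`t3enh` implements the full analysis that distinguishes these modes:

1. **Hyperacetylated region calling** — Poisson window scanning of
   binned tag tracks, replicate-concordant peaks, and a
   negative-binomial differential test per mark with the decision rule
   FDR < 0.01 and log2FC > 1; regions significant for *both* H3K27Ac
   and H3K9Ac form the high-confidence hyperacetylated set.
2. **TRBS classification** — TR-bound hyperacetylated regions ranked by
   HDAC3 tag density in the hypothyroid state and split into tertiles:
   the top third are poised **type 1A** sites (HDAC3/NCOR1-occupied,
   constitutive TR/CBP), the bottom third hormone-established
   **type 1B** sites (everything recruited with T3).
3. **TR-independent hyperacetylation** — explained by SE co-occupancy
   (ROSE-style stitching at 12.5 kb plus a rank-signal slope-one
   cutoff), TAD sharing, and Hi-C contacts quantified at 5 kb
   resolution with a 10 kb window against an opposite-direction
   mirrored background; enrichments use Fisher exact tests against 600
   randomly drawn acetylated regions.
4. **Gene linkage** — differential expression (NB test), RPKM, linkage
   of genes to hyperacetylated regions within 100 kb of the TSS, and
   fold enrichment of corepressor-dependent induction against ten sets
   of 1000 random genes.

Because such studies hinge on tissue data that cannot ship with code,
the package includes a first-class synthetic data generator that plants
the entire architecture — region classes, NB counts per ChIP target and
condition, SE clusters, TADs, distance-decaying Hi-C with loops, and
coupled gene expression — with a truth table, so every stage is scored
for recovery.

## The statistics

Counts follow `K_ij ~ NB(mean = s_j * q_i, dispersion alpha_i)` with
per-sample size factors `s_j` (median-of-ratios by default, library
depth per 1e7 tags for ChIP tracks in the pipeline). Dispersion is
estimated per region by method of moments and clamped to
`[trend, 2 * trend]`, where the trend is the bin-mean along abundance;
the Wald statistic on `log2((m_trt + 0.5) / (m_ref + 0.5))` gives
two-sided p-values, adjusted by Benjamini-Hochberg per contrast and
mark. Fisher's exact test is computed with exact integer arithmetic
(two-sided: sum of hypergeometric probabilities not exceeding the
observed table's). The signed-rank test drops zero differences,
midranks ties, enumerates the exact null below n = 25 and uses a
tie-corrected normal approximation above. The SE cutoff is
`argmin_i (y_i - x_i)` on the normalized signal-vs-rank curve — the
point where the curve leaves slope one.

## Worked example

```python
import t3enh

report = t3enh.run_all(t3enh.SimConfig(seed=11))
```

The report is a plain JSON-serializable dict; the headline numbers for
seed 11 print as:

```
high-confidence hyperacetylated regions: 497 (recall 0.96, precision 1.00)
regions with a TRBS: 384 (77% of hyperacetylated)
HDAC3 density, type 1A vs 1B (hypothyroid): 104.5 vs 4.3 (signed-rank p = 9.6e-23)
super-enhancers: 134 called, 100% of planted clusters recovered
planted loops detected: 90%; contact vs mirrored background median 82 vs 15 (signed-rank p = 1.1e-12)
T3-induced genes: 225, 100% within 100 kb of a hyperacetylated region
NCOR1-disruption fold enrichment: type 1A-linked 2.61, type 1B-linked 2.09
```

Reading: of 2000 synthetic acetylated regions, 497 come out
hyperacetylated at both marks (520 were planted); TR-bound sites split
cleanly into HDAC3-high (poised) and HDAC3-low (established) tertiles;
TR-free hyperacetylated regions sit in SEs, TADs and loops shared with
TR-bound regions far above random expectation; and genes whose
expression depends on the TR-NCoR interaction concentrate near poised
(type 1A) rather than established (type 1B) sites — the signature the
analysis is designed to expose.

The same stages are available from the shell:

```bash
t3enh simulate --seed 11 --out sim/
t3enh diff --counts sim/counts_H3K27Ac.tsv --sample-sheet sim/sample_sheet.tsv \
      --mark H3K27Ac --contrast hypo:hyper --fdr 0.01 --lfc 1 --out k27.tsv
t3enh run-all --seed 11 --report report.json
```

## Layout

- `t3enh.stats` — size factors, NB Wald test, BH, Fisher exact,
  signed-rank, z-scores
- `t3enh.simulate` — synthetic genome generator and recovery scoring
- `t3enh.regions` — region calling, concordance, differential marks,
  high-confidence intersection
- `t3enh.classify` — TRBS annotation, HDAC3 tertiles, occupancy
- `t3enh.superenhancers` — stitching, rank cutoff, co-occupancy nulls
- `t3enh.hic` — contact matrices, mirrored background, loop detection,
  TAD confinement
- `t3enh.genes` — RPKM, differential expression, 100 kb linkage,
  random-gene enrichment
- `t3enh.pipeline` / `t3enh.cli` — orchestration and the `t3enh`
  command

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
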