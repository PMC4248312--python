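# occushift

Dynamic transcription-factor occupancy analysis across hematopoietic
differentiation, packaged as a tested, reusable pipeline.

Master regulators such as TAL1 bind different genomic sites at different
stages of blood-cell differentiation, and those shifts in occupancy are
coupled to the induction and repression of lineage genes. Given
per-cell-type ChIP-seq peak calls and signal tracks, this package

1. builds a **merged occupied-segment (OS) atlas** — the union of all
   peak calls with overlapping segments merged, each merged segment
   annotated with the set of cell types that bind it;
2. attaches normalized signal (mean per-base coverage, scaled to
   counts-per-million per track), **quantile-normalizes** the OS ×
   cell-type matrix and clusters it (k-means, k = 16 by default), and
   summarizes cell-type relatedness as an average-linkage dendrogram on
   the Pearson dissimilarity 1 − r;
3. scans 1-kb OS-centered windows with PWMs at an exact p-value
   threshold (FIMO-style dynamic programming over discretized log-odds
   scores, p = 10⁻³ by default) and scores **central motif enrichment**

   log₂ OR = log₂[(a/c)/(b/d)],

   where a, b are the mean motif counts in the central ±50 bp and in the
   window flanks per OS, and c, d the same quantities on comparably
   sized random genomic segments;
4. partitions the G1E/ER4 occupancy universe by the **response of TAL1
   to GATA1 restoration** — dissociation, retention or recruitment,
   each split into direct (GATA1 co-occupied) and indirect — groups
   a–f, plus GATA switch / GATA2-loss classes;
5. assigns presumptive **target genes** per OS, either all genes whose
   TSS shares the OS's enhancer-promoter unit (EPU) or the nearest TSS;
6. declares induced / repressed genes from an expression table
   (active in both conditions, log₂ FPKM > 3, FDR ≤ 0.05), computes
   per-OS and per-group response percentages, and calibrates enrichment
   against a **1000-fold group-label-shuffling permutation null**:
   log₂(true % / shuffled %);
7. assigns each OS a chromatin state (nine-state segmentations) and
   categorizes progenitor-only OSs by their active/inactive **fate**
   across the erythroid maturation series.

A first-class synthetic-data generator (`occushift.simulate`) emits a
complete miniature fixture — genome, peaks with controlled sharing,
motifs planted with tunable centrality, coverage, EPU/TSS annotation,
state tilings and an expression table coupled to the planted response
groups — with a JSON manifest of the ground truth, so every stage is
testable end to end.

## Worked example

```sh
occushift demo --outdir demo_out --seed 1
```

simulates the default fixture (2 × 500 kb genome, 590 planted occupied
segments across six cell types, 300 genes in 40 EPUs) and runs all
stages. `demo_out/report.json` contains, among others (seed 1):

| quantity | value | meaning |
|---|---|---|
| atlas OS count | 590 | every planted sharing event recovered as one merged OS |
| single-cell-type OSs | 78.0 % | most occupancy is cell-type-restricted, as planted |
| GATA1 overlap | 64.8 % | fraction of the G1E/ER4 TAL1 universe co-occupied by GATA1 |
| GATA motif central log₂ OR | 1.28 | strongest central enrichment of the five scanned motifs |
| group d induced log₂(true/shuffled) | 0.21 (p = 0.038) | retention with GATA1 co-occupancy is induction-enriched |
| group a repressed log₂(true/shuffled) | 0.17 | TAL1 dissociation is repression-enriched |
| fate: inactive in all 3 erythroid types | 8.3 % of 120 HPC7-only OSs | chromatin-fate summary of progenitor-only sites |

The per-stage TSV/JSON/Newick outputs land in `demo_out/results/`, and
`provenance.json` records a content hash of every output; rerunning with
the same seed reproduces identical hashes.

The same stages run individually on real data from a YAML config:

```sh
occushift atlas --config config.yaml
occushift run --config config.yaml --stages atlas,cluster,motifs
```

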