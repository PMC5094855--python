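# sgrnakit

A toolkit for designing CRISPRi/CRISPRa sgRNA libraries and quantifying
pooled growth screens:

- **`annotations`** — hybrid TSS annotation: CAGE peaks (BED, `p1@gene` /
  `p2@gene` labels) refine transcript-model TSS coordinates through a strict
  matching hierarchy (matched peaks within 30 kb → unmatched primary peaks
  within 500 bp → robust/permissive peaks within 200 bp → transcript model),
  with primary/secondary ranges merged into a single "P1P2" range when less
  than 1 kb apart.
- **`guide_features`** — enumerates 19-nt + NGG candidate sgRNAs within
  mode-specific windows around TSS-range edges ([−25, +500] bp for CRISPRi,
  [−550, −25] bp for CRISPRa, measured at the PAM 3'G, strand-aware) and
  computes signed TSS distances, per-position sequence one-hots and
  dinucleotides, composition/homopolymer descriptors, guide secondary
  structure, and per-track chromatin means over the 22-bp target site.
- **`training_data`** — builds activity-score training sets from screen
  phenotype tables: hit genes by `|z × log10 p| ≥ 20`, per-gene sgRNA
  phenotypes normalized to the mean of the top-3 guides by absolute value.
- **`activity_model`** — linearizes features (fixed-width binning with
  sparse-edge collapse; RBF-SVR curves for TSS-distance features),
  z-standardizes with training-set statistics, and fits elastic-net
  regression with cross-validated grid search over the l1/l2 ratio and
  strength. Splits are always gene-wise. Models serialize to JSON.
- **`offtarget`** — exhaustive genome scan for NGG-adjacent sites scored by
  position-weighted mismatch penalties (perfect match = 0), tiered
  stringency T0–T4/FAIL from TSS-proximal (< 31) and genome-wide (< 21)
  alignment counts. A vectorized index (`OfftargetIndex`) provides the same
  semantics at speed.
- **`library_design`** — per-TSS selection (up to 2 empirical guides with
  activity ≥ 0.75 first, then predicted-score ranking with a +0.2 empirical
  bonus, 3-bp shift exclusion, restriction-site filtering, iterative tier
  relaxation to 10 guides), composition-matched non-targeting controls, and
  84-bp cloning oligos (18-nt adapter + BstXI arm + 20-nt insert + BlpI arm
  + 18-nt adapter).
- **`screen_scoring`** — counts → depth-normalized, control-centered γ per
  cell doubling (sgRNAs with < 50 reads in both samples excluded), gene
  scores (top-3 |γ| mean, Mann-Whitney vs negative controls, lowest-p TSS),
  negative-control pseudo-genes, hit calling with empirical FDR, and
  ROC/precision-recall evaluation against gold-standard gene sets.
- **`synthetic_fixtures`** — seeded toy genomes, annotations, chromatin
  tracks, activity datasets, and negative-binomial screen counts with
  planted truth, emitting exactly the file formats the pipeline consumes.

## Command line

```sh
# seeded toy reference (FASTA, transcript TSV, CAGE BED, bedGraph tracks)
sgrnakit simulate-reference --seed 3 --n-genes 20 --outdir ref/

# hybrid TSS annotation
sgrnakit annotate --cage ref/cage_peaks.bed --transcripts ref/transcripts.tsv \
    --out tss.tsv

# 84-bp cloning oligo for one protospacer
sgrnakit oligo --protospacer ACATCATCATCATCAATCA

# screen quantification: counts TSV -> gene-score TSV
sgrnakit score-screen --counts counts.tsv --gene-map gmap.tsv \
    --doublings rep1=10 --out genes.tsv
```

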