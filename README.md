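# cki — the Clinical Kinase Index

`cki` ranks candidate drug-target genes (built for the human kinome, but
agnostic to the gene panel) within a tumor cohort by integrating four
independent lines of clinical evidence from standard cohort data — a bulk
RNA-seq count matrix with matched normals, a per-patient clinical table, a
MAF-style somatic mutation table — plus static target annotations. It is
aimed at target-prioritization work: given a cohort, which understudied
genes look as clinically relevant as the established, approved targets?

## The score

For gene *g* in a cohort, four evidence components are evaluated:

* **DGE** ∈ {0, 1} — significantly overexpressed in tumor vs normal:
  log₂FC > 1 and Benjamini–Hochberg FDR < 0.01, Welch's t on log₂-CPM.
* **Survival** ∈ {0, 1} — upper-quartile expressors have significantly
  *worse* survival than lower-quartile expressors: two-group log-rank
  p < 0.05 on Kaplan–Meier curves, with the high arm required to have the
  lower restricted mean survival.
* **Hotspot** ∈ {0, 1} — mutations cluster at specific residues: a
  positional-clustering score (fraction of the gene's mutations captured by
  binomially seeded residue clusters) that is an upper-tail outlier against
  the cross-gene background, with ≥ 5 mutations required.
* **Clinical** — one sub-score in [0, 1] per available clinical parameter
  (T, N, M stage, histological grade, pathologic and clinical stage): the
  fraction of stage-level pairs where expression is significantly *higher*
  at the more advanced level (Welch's t, p < 0.05).

The index is

```
CKI(g) = 100 × raw / max,   raw = DGE + Survival + Hotspot + Σ clinical sub-scores
                            max = (# evaluable binary components) + (# available clinical parameters)
```

so `max` adapts to each cohort's data availability (e.g. a cohort with
fewer than 3 normal samples cannot evaluate DGE and scores out of a smaller
maximum). Genes are competition-ranked by CKI within the cohort; cohorts
are compared by Spearman rank correlation and top-quartile overlap of their
CKI lists, and scores can be stratified by target development level (TDL),
IDG understudied status, MOA-target status, or kinase group.

A dependency-screen benchmark is included: cell-line loss-of-function
scores are dichotomized at the conventional cutoff (dependent iff < −1) and
the CKI is evaluated as a predictor of dependency (Kruskal–Wallis, Spearman,
ROC AUC) per cell line and at tissue level.

Because no real cohort ships with the package, a synthetic cohort generator
(`cki.simulate_cohort`) produces complete bundles — negative-binomial
counts, censored survival, TNM labels, residue-level mutations, dependency
scores, annotations — with planted effects recorded in a truth manifest, so
every stage of the pipeline is testable end to end.

## Worked example

Simulate a cohort in which 15% of 120 genes carry *all* planted effects
(overexpression, prognostic expression, stage trend, mutation hotspot,
cell-line dependency), then score it:

```bash
$ cat sim.yaml
n_genes: 120
n_tumor: 150
n_normal: 50
composite_fraction: 0.15
cohort: DEMO

$ cki simulate --config sim.yaml --out bundle --seed 42
wrote cohort DEMO (120 genes) to bundle

$ cat run.yaml
seed: 42
cohorts:
  DEMO:
    bundle: bundle

$ cki score --config run.yaml --out scored
DEMO: 120 genes scored; top G0108 CKI=42.59

$ head -6 scored/scorecards_DEMO.tsv | cut -f1-5,12-15
# seed=42
# config_hash=5bfa74660fdf
gene    cohort  dge     survival        hotspot raw     max     cki_percent     rank
G0108   DEMO    1       1       1       3.8333  9       42.59   1
G0019   DEMO    1       1       1       3.6667  9       40.74   2
G0089   DEMO    1       1       1       3.6667  9       40.74   2
```

The top-ranked genes carry all three binary components plus fractional
clinical credit (raw 3.83 out of a maximum of 9: three binaries plus six
clinical parameters), giving CKI ≈ 42.6 — planted genes; null genes score
near 0. `cki benchmark --config run.yaml --out bench` then compares the CKI
against the bundle's dependency matrix; on this cohort the 18 dependent
genes average CKI 32.5 versus 0.69 for the rest (Kruskal–Wallis
p = 7.4e−15, tissue-level AUC = 1.0).

The same pipeline is available as a library:

```python
import cki
bundle, manifest = cki.simulate_cohort(cki.SimulationConfig(
    n_genes=120, n_tumor=150, n_normal=50, composite_fraction=0.15, seed=42))
cards, summary = cki.score_cohort(bundle)
cards[0].gene, round(cards[0].cki_percent, 2)   # ('G0108', 42.59)
```

For real data, place the cohort's files in a directory
(`counts.tsv`, `samples.tsv`, `clinical.tsv`, `mutations.maf`,
`annotations.tsv`, optionally `dependency.tsv` + `cell_lines.tsv`; formats
documented in `cki/io_formats.py`) and point the run config's `bundle:` at
it.

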