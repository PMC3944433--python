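# zfcoscan

Predicting transcription-factor co-occupancy from a zinc-finger protein
sequence and a set of ChIP binding regions.

## The problem

Chromatin regulators such as the *Drosophila* SWI/SNF ATPase Brahma (Brm)
bind hundreds of genomic sites, and a frequent question is whether a
sequence-specific transcription factor — here the C2H2 zinc-finger protein
Earmuff (Erm) — co-occupies those sites. When no ChIP data exist for the
factor itself, its binding can still be predicted from sequence:

1. **Recognition-code PWMs.** Each C2H2 zinc finger (pattern
   `C-x(2,4)-C-x(12)-H-x(3,5)-H`) reads 3–4 bp of DNA through the residues
   at positions −1, 2, 3 and 6 of its recognition helix. An empirical
   recognition code maps those residues to per-base preferences, giving one
   4-column position weight matrix (PWM) per finger.
2. **Preference enrichment.** Windows of ±200 bp around each peak are tested
   for enrichment of each finger's preference (both strands, one-sided
   binomial or shuffle null).
3. **De novo motif.** Windows carrying enriched preferences are handed to a
   seeded ZOOPS (zero-or-one occurrence per sequence) expectation-
   maximization, with z-score k-mer seeding and BIC width selection, to
   learn a full-length motif (`-2·LL + (3W+1)·ln n`).
4. **Co-occupancy calls.** Windows are scored by their best log-odds hit
   (bits, both strands, pseudocount `0.25·q_b`); an empirical null yields
   per-window p-values `(1 + #null ≥ s)/(1 + n_null)` and Benjamini–Hochberg
   calls at a target FDR (default `1e-4`; a direct empirical-FDR threshold is
   available).
5. **Validation.** The motif's AUC for discriminating peak windows from
   background windows is benchmarked against random Dirichlet(1) PWMs of the
   same width (which sit at AUC 0.5) and against a negative-control motif.
6. **Annotation.** Called sites map to their nearest gene.

Because the original ChIP regions and genome build are not deposited, the
package ships a seedable synthetic-data generator that reproduces the
statistical structure of the analysis — Markov background windows, a planted
14-bp motif concentrated near window centers, and a six-finger fixture
protein whose predicted preferences are `GTAG` (finger 1) and `RAAA`
(finger 4) — so the full pipeline runs and is tested without downloads.

## Worked example

Run the full pipeline on the default synthetic dataset (270 peak windows of
401 bp, planted motif in 90% of them, 270 background windows):

```bash
zfcoscan run --seed 7 --outdir out/
python -m json.tool out/report.json
```

Key fields of the resulting `report.json` (abridged):

```
"n_windows":        270
"n_called":         96
"alpha":            0.0001
"fdr_method":       "empirical-BH"
"threshold_bits":   18.05
"auc":              0.936
"random_auc_mean":  0.499
"random_auc_sd":    0.0259
"control_auc":      0.549
"control_within_null": true
"truth_precision":  1.0
"truth_recall":     0.392
```

Reading this: the de novo motif (a width-14 PWM whose consensus
`GTAGCACGTGRAAA` recovers the planted motif; see `out/motif.meme` and
`out/discovery.yaml`) separates peak from background windows with AUC 0.936,
~17 standard deviations above the random-motif null (0.499 ± 0.026), while a
column-shuffled control motif stays inside the null band (0.549). At
FDR < 1e-4 against 50,000 background-model null windows, 96 of 270 windows
are called; every call is a truly planted window (precision 1.0), and the
partial recall reflects the deliberately moderate planted signal
(~1.2 bits/column). `out/distance_histogram.tsv` tabulates motif-to-peak-
center distances for the called sites and `out/gene_table.tsv` maps them to
nearest genes (`site_id  CG_number  gene_name  distance`).

Per-stage subcommands (`simulate`, `fingers`, `windows`, `enrich`,
`discover`, `classify`, `annotate`) run the same stages individually, e.g.

```bash
zfcoscan fingers out/synthetic/protein.fasta
# finger 1 [6-26] NEKR -> GTAG
# ...
# finger 4 [84-104] QKNG -> RAAA
```

Real inputs are supplied via a YAML config with `synthetic: false` and paths
to a protein FASTA, genome FASTA, peaks BED, optional gene BED and an
optional recognition-table TSV (`position  residue  pA  pC  pG  pT`).

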