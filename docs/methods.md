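# Methods

## Zinc-finger recognition model

C2H2 repeats are located with the PROSITE-style pattern
`C-x(2,4)-C-x(12)-H-x(3,5)-H`, scanned N→C with leftmost, non-overlapping
matches. Taking the first histidine as helix position 7, the specificity
residues (helix −1, 2, 3, 6) sit at fixed offsets 5, 8, 9, 12 of the twelve
residues between the second cysteine and the first histidine.

Each finger yields a width-4 PWM under the canonical antiparallel docking
geometry: helix positions 6, 3, −1 read the 3-nt core 5'→3' on the top
strand, and position 2 contacts the fourth base on the complementary strand;
that column is stored complemented into top-strand coordinates. The
residue→base lookup is a *recognition code table* shipped as plain-text
package data (`position  residue  pA  pC  pG  pT`) and swappable per run.
The bundled table is a deliberately simple code (Arg/His→G, Asn/Gln/Thr→A,
Glu/Asp→C, Lys/Ser→T at probability 0.85; Gly→A/G equally; all other
residues uniform), applied identically at all four contact positions. It is
sufficient to drive the pipeline and to express the expected finger
preferences of the bundled six-finger fixture protein (finger 1 → `GTAG`,
finger 4 → `RAAA`); real analyses should substitute a published code.
Residues missing from a table fall back to a uniform column with a warning
(or a hard error when fallback is disabled).

IUPAC consensus: a column emits its top base alone when its probability
exceeds the degeneracy threshold (default 0.6); otherwise the minimal IUPAC
code covering every base with probability ≥ threshold × maximum. Ties break
toward the alphabetically first base.

## Scanning

Coordinates are BED-style 0-based half-open; a peak's window is
`[center − flank, center + flank + 1)` (default flank 200 bp → 401-bp
windows), clipped at chromosome ends. Scores are log-odds in bits,
`Σ_j log2(p_j(b)/q(b))`, with the PWM regularized by a pseudocount of
`0.25·q_b` per cell. The minus strand applies the PWM to the reverse
complement, reported in top-strand coordinates. Ambiguous bases contribute
the background-expected column log-odds (≈ 0) rather than −∞, so clipped or
masked windows remain scorable; on the minus strand that expectation uses
complemented marginals. Ties break toward the smaller offset, then the plus
strand.

The background model is an order-k Markov chain (order 0 trained from the
windows themselves when nothing else is supplied); its stationary single-base
marginals are the log-odds reference.

Finger-preference enrichment counts windows with ≥ 1 exact IUPAC match on
either strand. The closed-form path treats offsets as independent:
`P(window matches) = 1 − (1 − p₀)^(2(L−W+1))` with `p₀` the product of
per-column allowed-base marginals, then a one-sided binomial tail; the
resampling path re-draws whole window sets from the background model.
"Enriched" is operationalized as fold > 1 with one-sided p < 0.05 — a
pragmatic stand-in, since no published test statistic exists for this step.

## Motif discovery (seeded ZOOPS EM)

The de novo stage is a zero-or-one-occurrence-per-sequence mixture: a window
either is pure background or contains exactly one motif instance at a
uniformly chosen offset and strand. Free parameters are the PWM and the
occurrence prior λ. Seeds are k-mers (k = 6–8) ranked by the z-score of the
number of windows containing them versus the background expectation, with
lexicographic tie-breaks.

EM details: responsibilities use likelihood ratios motif/background per
(offset, strand); the M-step re-estimates λ (clipped to `[1e-6, 1−1e-6]`)
and the PWM with a Dirichlet pseudocount of `pseudocount·q_b` (default 1.0)
per column. Because the M-step is thus a MAP update, the *penalized*
objective (data log-likelihood + pseudocount prior term) is the quantity EM
provably ascends; `EMTrace.log_likelihoods` records it, and the raw data
log-likelihood is kept alongside for model comparison. Convergence: relative
objective change < 1e-6, max 200 iterations. Seed initialization places the
seed consensus centered in the target width with weight 0.7 plus a uniform
remainder; λ starts at 0.5.

Width selection fits the widest candidate from the raw seeds, then re-fits
each narrower width from the highest-information contiguous sub-window of
the wide fit — this keeps all widths phase-aligned on the same signal, so
BIC (`−2·LL + (3W+1)·ln n`, raw LL) compares widths rather than accidental
seed placements. Ties go to the smaller width.

A caution from null calibration: on pure background data the ZOOPS MLE
saturates λ near 1 (any weak motif has a best placement in every window), so
λ is **not** a signal-presence indicator. Null behavior shows up instead as
a low-information motif with chance-level discrimination; validation should
always use the random-motif AUC null below.

## Site calling and validation

Peak windows are scored by their best hit to the discovered motif. The
empirical null is 50,000 background-model windows in synthetic mode, or
dinucleotide-preserving (Altschul–Erickson) shuffles of the peak windows for
real inputs. Per-window empirical p-values `(1 + #null ≥ s)/(1 + n_null)`
feed Benjamini–Hochberg at α (default 1e-4, π₀ = 1, conservative); a direct
plug-in empirical FDR (`eFDR(s) = n_obs·FPR(s)/#{obs ≥ s}`, monotonized as a
q-value) is available by flag. Note the structural limit of empirical nulls:
p-values are floored at `1/(1 + n_null)`, so BH can only reject at very
small α when many windows outscore essentially the whole null sample — the
default `n_null = 50,000` was chosen so α = 1e-4 is attainable at all with
270 windows (the advisory `n_null ≥ 1/α` is not sufficient for BH).

AUC framing (stated in every report): positives are the peak windows,
negatives are matched background windows (generator backgrounds in synthetic
mode, dinucleotide shuffles otherwise), score is the best log-odds hit. AUC
is the exact rank statistic `P(pos > neg) + ½·P(tie)`. The null reference is
the AUC sample of n random PWMs (columns ~ symmetric Dirichlet(1), same
width); a negative-control motif (by default a column-shuffled copy of the
discovered motif) is flagged `control_within_null` when its AUC lies inside
the null's central 95% interval. Random motifs sit at AUC 0.5 by
construction, anchoring the scale.

Called sites map to the nearest gene by center-to-feature distance (0 when
inside), ties toward the smaller gene start then the lexicographic id; sites
beyond `max_gene_distance` (default 10 kb) stay unassigned. The mapping is
many-to-one by design.

## Synthetic data

The generator emulates the analysis inputs, not any real genome: order-2
Markov background (AT-rich composition 0.29/0.21/0.21/0.29 with mild CpG and
TpA depletion, a generic metazoan-like texture), 270 peak windows of 401 bp
and 270 background windows; a width-14 planted motif with consensus
`GTAGCACGTGRAAA` (containing the fixture finger preferences GTAG and RAAA),
dominant-base probability 0.86 per column (~1.2 bits/column on average, the
degenerate R column 0.45/0.45) planted in 90% of peak windows; placement is
a truncated discrete Gaussian around the window center (sd 50 bp); strands
are equiprobable; at most one instance per window, matching the ZOOPS
assumption. A truth table records every planted offset/strand/instance. The
emitted "genome" concatenates windows with 100-bp N spacers so coordinate
clipping paths are exercised, and re-extracting windows from genome + BED
reproduces the window FASTA byte-for-byte.

What passing tests do and do not show: the generator has no probe-level
ChIP noise, no peak-calling uncertainty, no repeat structure and a motif of
one fixed information content, so recovery and calling results here
demonstrate correctness of the machinery under its own assumptions, not
performance on real chromatin data. In particular, at this deliberately
moderate signal strength the planted and null best-score distributions
overlap: empirical-BH at α = 1e-4 calls only windows that beat essentially
all null scores, giving precision ≈ 1 with partial, seed-dependent recall
(0–0.4 across the default seeds). Stronger planted motifs or larger α move
recall up; the defaults were fixed once, before the test thresholds, and are
not tuned per run.

## Determinism and problem sizes

All randomness flows from one integer seed; per-stage seeds derive as
`(seed·1000 + stage_counter) mod 2³¹` and are recorded, with SHA-256 digests
of every output, in the run manifest — identical config + seed reproduces
identical bytes. Default problem sizes (270 + 270 windows, 50,000 null
windows, 200 random motifs, widths {10, 12, 14, 16}, ≤ 200 EM iterations)
complete a full run in well under a minute on one core; they are the study
conditions, chosen once, not runtime knobs.
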