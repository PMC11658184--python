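# Methods

## The measurement model

Aminoacylation protects the 3′ terminal nucleotide of a tRNA from periodate
oxidation. After periodate treatment and β-elimination, an uncharged
molecule is shorter by exactly one nucleotide; a charged molecule is not.
Sequencing then reads charging state off the 3′ end: a read whose alignment
reaches the reference terminus is "CCA", one nucleotide short is "CC", and
two or more short is "missing ≥ 2". All headline statistics are built on
these three counts:

- `CCA% = 100·n_CCA/(n_CCA + n_CC)` — reads missing ≥ 2 nucleotides are
  excluded because they reflect degradation, not the single-base periodate
  signature;
- `non-CC/CCA% = 100·n_missing≥2/n_total` of all reads;
- charging index = per-gene CCA% ratio periodate/control;
- retention ratio = per-gene CCA% ratio pre-deacylated/periodate.

Tail classification is purely coordinate-based. A substituted or deleted
base inside positions 74–76 flags the call (`tail_mismatch`) but does not
change the category: base modifications cause reverse-transcriptase
misincorporations, and letting base identity into the tail call would
conflate modification with degradation. Whether such flagged reads should
also be excluded from CCA% denominators is exposed as a toggle; by default
they are kept.

CCA% is undefined (NaN, never 0) when a gene has fewer than `min_reads`
(default 100) reads or no CCA/CC reads at all; undefined values propagate
through ratios rather than being clamped.

### Assumptions

- A charged molecule always carries an intact CCA (the amino acid requires
  the terminal A).
- Periodate attacks any free 3′ end, so molecules already ending CC lose
  further bases at the same efficiency.
- The in-vivo CC-ended pool and extraction damage are indistinguishable at
  the read level; both are modeled by one parameter (below) and
  distinguished only by treatment contrasts.
- Raw read abundances are not abundance estimates: tRNA-seq library
  construction is heavily biased, so only relative comparisons across
  treatments/libraries of the same gene are interpreted.

## Alignment

A single fit-aligner replaces the usual local-prepass + global-mapper
combination. The read must be fully consumed except soft clips; the
aligned span may start and end anywhere on the reference. Scoring: match
0, mismatch −5, gap open −5, gap extend −3 (a length-L gap costs
−5 − 3L), free 5′ soft clip up to 5 bases (reverse-transcriptase
terminal-transferase additions), free 3′ clip up to 5 bases only past the
reference 3′ terminus (non-templated tails on CCA-less references),
otherwise −5 per clipped base. A read maps when its best score reaches
−0.7 − 0.7·length; equal best scores on two or more distinct reference
sequences flag the read ambiguous (references are deduplicated at load, so
gene-level and sequence-level ambiguity coincide).

Two numerical design points matter:

- **Minimum aligned span.** At least 10 reference-consuming columns are
  required, and the constraint lives *inside* the dynamic program (a layer
  dimension tracks the capped column count). Enforcing it after the fact
  is wrong: with free end clips, a degenerate one-column "alignment"
  hugging the reference terminus scores 0 and would dominate every read
  containing a real error.
- **Tie-breaking.** Co-optimal alignments are resolved deterministically:
  fewer clipped bases, then smaller reference start, then lexicographically
  smallest operations. Mapping is therefore independent of reference
  order. One consequence: a single-base deletion inside a repeated-base
  run is attributed to one column of the run (the traceback prefers
  continuing matches, pushing gaps 5′-ward); per-site misincorporation
  rates adjacent to homopolymers inherit that ambiguity, as with any
  aligner.

Exact and single-substitution reads bypass the full dynamic program
through two provably score-optimal fast paths (a perfect hit scores the
global maximum 0; when no perfect hit exists anywhere, a one-mismatch
ungapped hit at −5 cannot be beaten because any gap costs −8). The
fallback DP is exercised directly by deletion- and multi-error reads and
is checked against an independent exhaustive oracle in the tests.

Pair merging follows the standard overlap-consensus rule (≥ 30 nt ungapped
overlap, ≤ 4 mismatches, disagreements resolved by quality then toward
read 1), and adapter trimming allows one mismatch per 10 adapter bases,
removing the adapter and everything 3′ of it.

## Sprinzl coordinates

Structural segments from the annotation sidecar are mapped to canonical
labels: acceptor stem 1–7/66–72, connectors 8–9 and 26, D-stem 10–13 and
22–25, D-loop 14–21, anticodon arm 27–43, variable region 44–48, T-arm
49–65, discriminator 73, CCA 74–76. Variability is label-driven: a 7-nt
D-loop skips 17; 9–11-nt loops insert 17a/20a/20b; a 4-nt variable region
skips 47; variable regions longer than 5 nt keep 44/45/48 and label the
middle e1…eN. Supported envelopes are D-loop 7–11 nt and variable region
4–23 nt — anything else is rejected loudly rather than mislabeled
(D-armless animal mitochondrial tRNAs are out of scope). Labels are
unique, monotone in the canonical order, and round-trip through position
indices; these are tested as properties over the whole supported envelope.

## The simulator

The generator draws each molecule through the physical chain: charging
(Bernoulli θ per gene), in-vivo CCA integrity of uncharged molecules,
treatment chemistry, reverse transcription, size selection. Defaults are
the package's standing model of the assay:

| parameter | default | meaning |
|---|---|---|
| θ | 0.55 | charging fraction (periodate-library CCA% sits in the mid-50s) |
| cca_intact_uncharged | 0.8 | uncharged molecules with intact CCA (control CCA% below 100) |
| periodate_eff *e* | 0.98 | terminal-nucleotide removal efficiency (uncharged spike-in retains ~2% CCA) |
| deacyl_eff *q* | 0.9 | deacylation efficiency in the pre-deacylated treatment |
| deacyl_resistance | 0.0 | per-gene multiplier making deacylation fail (Ile/Thr/Val-like behavior) |
| extra_degradation *d* | 0.10 control / 0.35 periodate | probability of off-target 3′ loss |
| extra_degradation_geom *p* | 0.5 | loss length is 1 + Geometric(p) (mean 2 nt) |
| terminal_transferase_prob *t* | 0.3 | chance of 1–3 random 5′ extension bases |
| size_min | 35 | library size-selection floor |

The off-target degradation term is deliberately applied to charged and
uncharged molecules alike and can remove more than one nucleotide — this
reproduces the observation that periodate-treated libraries contain many
reads short by several 3′ bases, and that even control libraries are not
at 100 % CCA. tRFs are generated as independent molecule species (a 5′
fragment spans the gene start to its breakpoint, a 3′ fragment the
breakpoint to the mature end), both ligatable. Hard-stop and
misincorporating modification sites are specified by Sprinzl label with
stop/deletion/substitution probabilities; reverse transcription scans
3′→5′, stopping immediately 3′ of a triggered site.

One RNG stream per library, seeded from (seed, library index); identical
configuration and seed give byte-identical FASTQ and manifest. The truth
manifest records per-gene molecule fates (one fate per molecule with
precedence tRF > extra-degraded > terminal-removed > RT-truncated >
charged-protected > intact-uncharged, so fates always sum to the molecule
count) and the realized CCA/CC/missing counts before size selection.

### What the simulator does not model

Ligation and PCR bias, realistic quality scores, sequence-dependent
degradation, RT fall-off away from modified sites, and the capture-hairpin
sequence itself (an optional constant adapter only). Passing recovery
tests therefore demonstrates that the analysis inverts the modeled
chemistry correctly — not that real libraries are free of the biases the
model omits; on real data the charging index remains a proxy, and
absolute abundances should not be interpreted.

## Calibration scenarios and problem sizes

The canned scenarios (`trnacharge.scenarios`) pick sizes so sampling error
is small relative to the effect measured: charging recovery uses 50 genes
× 2000 reads (binomial SE of θ̂ ≈ 0.011, so a mean absolute error bound of
0.03 has comfortable margin); the spike-in experiment uses 300k/100k reads
because the quantity of interest (periodate failure ≈ 1.99 % CCA) must be
separated from its own sampling noise; misincorporation calibration uses
10 000 reads (SE ≈ 0.004 on a 0.75 rate). The spike-in check is stated at
the population level: the closed-form chemistry value is asserted against
the 2 % bound and the pipeline's estimate is required to match the closed
form within three binomial standard errors — a raw finite-sample draw
straddles a bound this tight at any practical depth. The calibration gene
is synthesized with distinct bases flanking the modified site so
single-base deletions have a unique optimal placement (see tie-breaking
above).

## Statistics

Classical fixed-effects one-way ANOVA, two-sided t-tests (Welch by default
for unpaired samples — equal variances are not assumed; paired where the
design pairs values), and Pearson correlation with an optional log
transform for quantities spanning orders of magnitude. Degenerate inputs
(zero within-group variance, zero-variance differences) raise a documented
error rather than returning NaN. **No multiple-testing correction is
applied anywhere**: raw P values are reported, and users comparing many
families should correct externally. Family-level CCA summaries are
computed both as unweighted means of member-gene values (default, matching
figure-style family averages) and as pooled counts; the two differ exactly
by read-count weighting.

## Known limitations

- CCA% is a charging *proxy*; no correction for periodate or deacylation
  efficiency is applied to produce absolute aminoacylation fractions.
- 5′-tRF detection is blind below the ~35 nt size floor; each gene's
  maximum detectable breakpoint distance is reported alongside calls
  rather than treating short fragments as absent. 3′-tRFs are not called
  as a class — they are visible only as 5′-truncation signal, which also
  means 5′-truncated reads conflate hard-stop modifications with genuine
  3′ fragments.
- Misincorporation rates adjacent to homopolymer runs inherit gap-placement
  ambiguity (above).
- The mapper is a functional equivalent of a BLAST-trim + Bowtie2 workflow,
  not a bit-for-bit reimplementation; scores follow the documented scheme,
  with quality-scaled mismatch penalties collapsed to their ceiling since
  the decisions are dominated by the linear score threshold.
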