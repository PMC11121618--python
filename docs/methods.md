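# Methods

## Motif model

A putative G-quadruplex motif is four guanine runs separated by three
loops of 1–10 nt.  Two classes are scanned, each with a G-strand and a
mirror C-strand form so that quadruplex potential on either strand of the
duplex is detected:

| class  | run length | minimal footprint |
|--------|-----------|-------------------|
| weak   | exactly 2 | 11 nt             |
| strong | 3–4       | 15 nt             |

The loop element is the regex `\D{1,10}` — "non-digit", which on a
nucleotide string matches **any** character, including G, C and N.  We
reproduce this semantics exactly rather than restricting loops to
non-run bases, because the classification counts depend on it: for
example an uninterrupted run of ≥16 G's satisfies the strong pattern
(three of the G's serve as single-character loops), and N's may appear in
loops though never inside a run.  A `strict_loops` mode (loops exclude
the run base) is provided for sensitivity analysis only; no headline
output uses it.

Scanning uses the standard non-overlapping leftmost-earliest regex scan.
Window classification needs only match existence, so overlap policy
cannot change any reported number.  Categories are mutually exclusive
with STRONG > WEAK > NONE precedence, which makes the "weak + strong"
combined count a disjoint union.  Soft-masked (lowercase) reference
sequence is uppercased before scanning, i.e. repeats are *not* excluded.

The scanner is certified against an independent brute-force enumerator
that explicitly iterates every run/loop decomposition; presence/absence
agreement is fuzz-tested on random 141-mers (10,000 per strength in the
acceptance suite) and the enumerator is memoised so degenerate poly-G
inputs stay tractable.

## Windows and haplotypes

Internal coordinates are 0-based half-open; VCF positions are converted
on ingest and BED intervals taken as-is.  For an SNV at 1-based position
p with flank 70 the window is `[p−71, p+70)` — 141 nt, the mutated base
included, since the site's own base can participate in a G-run.  Indel
windows span the `len(REF)` anchor bases plus 70 nt each side, keeping
the contract symmetric around the affected span.  Windows crossing
contig ends are clipped and flagged rather than discarded, so
denominators are never silently changed.

Germline edits carried by the sample are spliced into each window before
classification.  Edits are applied right-to-left in reference
coordinates so no rescaling is needed within a batch; a later batch
(e.g. the somatic mutation in the gain/loss analysis) is offset by the
net indel length of previously applied edits to its left.  Overlapping
edits and REF mismatches are hard errors; edits not fully inside the
window are skipped and recorded.  Germline edits are applied whenever
the sample carries the variant, regardless of zygosity — a deliberate
simplification recorded here because heterozygous carriers in reality
have one unedited haplotype.  Germline calls are first depth-filtered
(DP > 10 and alternate-allele depth > 5, both strict; unscorable calls
are dropped and tallied).

The enrichment count uses the reference-plus-germline haplotype; the
somatic allele itself is only used in the separate gain/loss analysis.

## Null model and tests

Controls are windows of the same nominal length anchored uniformly over
the union of the sample's capture-panel bases (interval chosen with
probability proportional to its length, then a uniform base), sampled
with replacement — at 2000 draws from megabase panels collisions are
negligible.  Each panel gets its own control set, classified on reference
sequence only (controls are patient-agnostic); every sample is tested
against the control of its panel.

Per sample and per context (STRONG, WEAK_PLUS_STRONG) we compute the 2×2
table, both proportions with Wilson score intervals (via
`statsmodels.stats.proportion.proportion_confint`), the Pearson χ² test of
independence (`scipy.stats.chi2_contingency`, Yates correction off by
default, available as a flag), and the pooled two-proportion z-test
(`statsmodels.stats.proportion.proportions_ztest`).  On a 2×2 table
without continuity correction z² = χ² exactly; the test suite asserts
this identity exhaustively on small tables.

**Labelling rule.**  Enrichment is a directional hypothesis: a sample is
labelled only when its proportion exceeds the control's.  With two-sided
p-values a `p < α` + direction gate would have type-I rate α/2, so the
label compares the one-sided (greater-than) p-value to α — for the z-test
directly, and for χ² by halving its p-value when the direction is
positive (valid via the z²=χ² identity).  Two-sided statistics are still
reported per sample.  The G4_STRONG label requires both tests to pass on
the strong context; otherwise the combined weak-plus-strong context is
judged by the same rule for the G4_WEAK_PLUS_STRONG label.  No
multiple-testing correction is applied across samples by default (each
patient is reported individually); a Benjamini–Hochberg option exists
behind the `bh_correction` flag.

Degenerate tables (pooled proportion 0 or 1) return z = 0, p = 1 with a
flag and are never labelled enriched.

For the group summary, samples labelled G4_STRONG form one group and all
others — including the combined weak-plus-strong label — are pooled as
"without G4 strong enrichment" before mutation-count means are taken.

## Spectra and downstream tables

Substitutions are classified into the 12 strand-specific types (C>A is
not merged with G>T) because G4 context is inherently strand-asymmetric.
Per (enrichment group, G4 stratum) cell the package reports counts,
proportions, and the binomial SD of each proportion, `sqrt(p(1−p)/n)`.
Non-SNV variants are excluded from spectra and counted.  Consequence
labels are consumed verbatim from the input annotation (VEP-style text);
missing labels fall into an "unannotated" bucket.  Group-exclusive
germline SNPs are identified by (chrom, pos, ref, alt) key — presence in
every group sample, absence in every other sample — and then filtered to
population allele frequency strictly below 0.1 (the AF source is
whichever INFO field the input VCF carries, configurable); variants
without an AF are reported separately rather than silently kept or
dropped.

## Synthetic study generator

The generator emulates the study design the analysis was built for: an
exome-like genome (default two 100 kb contigs, GC 0.45, a tiled panel
covering 60% of each contig), 30 strong and 30 weak motifs planted per
contig inside panel intervals (runs of 3–4 G or C with random 1–10 nt A/T
loops; A/T loops guarantee the planted weak motifs cannot accidentally
contain a strong one), 11 samples whose somatic counts mirror the
published cohort the package ships as its example, planted enrichment
0.6 for the three strong-labelled samples, and 15 group-exclusive
germline SNPs of which 8 are rare (AF < 0.1).  Enriched somatic sites
are placed so their window fully contains a uniformly chosen planted
strong motif; background sites stay ≥ 200 nt from every planted motif so
truth labels are unambiguous.  Background G4 matches arising by chance in
the random sequence are permitted and measured, not suppressed — at these
defaults roughly 6% of random panel windows classify STRONG, so the null
is realistically non-empty.  DP is drawn uniformly from 5–30 and the
alt-allele depth binomially at 0.5, so the depth filter has real work to
do.  One config seed drives independent per-stage substreams; identical
config + seed gives byte-identical files.

What the generator does **not** emulate: signature-structured mutation
spectra, read-level noise, copy-number events, mapping artefacts, linkage
between germline SNPs, or panel GC bias.  Passing tests therefore
demonstrate the correctness and calibration of the *procedure*, not the
biological claims on any real cohort.

## Calibration experiment

`signal_recovery_rates` generates one synthetic genome, then simulates
independent tumors at planted enrichment fractions f and tests each
against a freshly drawn 2000-window control.  At f = 0 the background
exclusion is set to 0 so null somatic sites are drawn from exactly the
control distribution; the G4_STRONG label rate over 500 replicates then
estimates the procedure's type-I error and is checked against the 95%
binomial band around α = 0.05 (this is what motivated the one-sided
labelling rule above).  At f = 0.6 with 100 mutations per tumor,
detection exceeds 90% over 50 replicates, and the detection rate is
monotone in f.  Problem sizes (100 somatic sites, 2000 controls, 500/50
replicates) were chosen to mirror the study scale while keeping the whole
experiment under a minute on one CPU.

## Numerical and degenerate-input choices

* Wilson bounds are clamped to [0, 1] and pinned to exactly 0 (k = 0) and
  1 (k = n) at the boundaries.
* Empty spectrum cells report NaN proportions and are flagged, never
  imputed.
* A zero marginal in the 2×2 table raises in the standalone χ² function;
  inside sample evaluation it is treated as the degenerate no-signal case
  (stat 0, p 1).
* Report TSVs serialize floats at 6 significant digits; the JSON manifest
  contains no timestamps, so reruns are byte-identical.
* Multiallelic VCF records are split per alt allele; no left-normalization
  is performed beyond that.

## Known limitations

* The motif model is purely pattern-based: no thermodynamic scoring
  (G4Hunter-style), no loop-length-weighted stability, no RNA G4s.
* Heterozygous germline edits are applied unconditionally (see above).
* The exclusivity search treats presence/absence only; zygosity and
  phasing are ignored.
* With a single panel per sample and 2000 controls, very small tumors
  (< ~30 windows) have little power; the label is then conservative.
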