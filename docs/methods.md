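# Methods

`coldchrom` implements the computational core of a cold-stress chromatin
study design: single-end DNase-seq for open chromatin in three samples
(room-temperature tubers, cold-stored tubers, leaves; two biological
replicates each), paired-end ChIP-seq for four histone marks plus
input, and dual-order sequential ChIP-seq (re-ChIP) for bivalent
H3K4me3–H3K27me3 domains, tied together by an expression table and
two differential-expression caller outputs. All genome-scale inputs can
be generated by the package's synthetic module, which plants a known
truth so every stage is testable end to end.

## DHS calling

Cut-site tracks store one genomic base per mapped DNase I cut. The
per-bp accessibility density is a sum of Gaussian kernels, one per cut,
with sd equal to the bandwidth *h* (default 300 bp):

    f(x) = Σ_i φ((x − x_i)/h) / h

evaluated at every base by discrete convolution of the cut histogram
with an exact Gaussian kernel truncated at 7 sd (tail mass < 1e-11, so
the profile agrees with the brute-force sum to well below 1e-9). The
profile integrates to the cut count up to boundary truncation.

**Empirical FDR threshold.** The published analysis controls DHS calls
at FDR < 0.05 but does not print the mechanism, so the package states
its own: cut positions are re-placed uniformly over the effective
genome in `n_null` Monte-Carlo simulations (default 20) and the
threshold is the smallest density *t* at which

    E[null bases with f ≥ t] / (observed bases with f ≥ t) ≤ fdr.

This is the random-background philosophy of kernel-density hotspot
callers, made seed-reproducible. If no *t* qualifies (the observed
track is indistinguishable from its null), the threshold is +∞ and no
DHSs are called — which is also why pure-null tracks yield a called-base
fraction far below the nominal FDR rather than near it: the criterion
compares whole tail masses, and a null-like tail never dominates its
own null expectation. DHSs are maximal runs of bases at or above
threshold; runs shorter than `min_length` (default 50 bp) are dropped
and runs closer than `merge_gap` (default 0) merged. The summit is the
base with the most cuts in the run, leftmost on ties.

**Consensus and specificity.** A replicate-consensus DHS is any
replicate-1 DHS with ≥ 1 bp overlap in replicate 2; its interval is the
union of the overlapping intervals (a flag keeps replicate-1
coordinates instead) and its summit comes from the replicate with the
larger summit count (replicate 1 on ties). A condition-specific DHS has
zero base-pair overlap with the other condition's consensus set. Both
operations are checked against an O(n·m) brute-force overlap oracle in
the tests. Top regions for motif input are ranked by read density
(ties: summit count, then coordinate) and exported as 100 bp windows
centered on summits.

## Feature assignment

A DHS is assigned to a genomic feature by its summit alone. Windows:
upstream1k/downstream1k are the 1-kb windows 5′/3′ of the TSS/TTS in
transcription orientation; the refined label set splits off TSS200 and
TTS200 (the 200 bp nearest the TSS/TTS) and adds a 1–5 kb
`intergenic_1to5k` band. The precedence when windows of different genes
overlap — exon > intron > upstream > downstream, ties broken by TSS
distance then gene id — is the package's own choice (the source design
does not state one); genic evidence wins because genic DHSs carry the
biological signal of interest. Coordinates are 0-based half-open
internally; for a minus-strand gene the TSS is stored as the exclusive
end boundary, so all windows are half-open intervals.

## Metagene profiles and sensitivity

Genes are aligned TSS→TTS and split into 100 body bins (integer
boundaries, widths differing by ≤ 1 bp) plus 100 bins per 1-kb flank;
genes shorter than 100 bp are excluded with a warning. Signal is
events per bp per million mapped events (`count/length/(library/1e6)`);
DNase events are the cut bases, ChIP events are fragment midpoints.
Gene-body sensitivity is the same normalization over [TSS, TTS), and
condition comparisons report per-gene `log2((s_A+ε)/(s_B+ε))` with
ε = 0.01 to keep silenced genes finite, alongside both a paired
signed-rank and an unpaired rank-sum p (the source analysis does not
say which was used, so both are reported). Expression quartiles are
taken over genes with FPKM > 1 in the sample, ties falling in the lower
quartile.

## ChIP quantification and bivalent calling

Single-mark levels are triple-normalized: to interval length, to depth,
and to the input track (`s = norm(track)/max(norm(input), ε)`).
Bivalent levels replace input with the matching first-antibody
no-antibody control: K4-K27 is normalized to K4-noAb, K27-K4 to
K27-noAb; mismatched pairings are an error. A gene is called bivalent
when it is active (FPKM > 1 in both conditions) and its bivalent level
rose from RT to cold in **both** antibody orders. The rule is a strict
inequality with no minimum effect size, mirroring the stated design; an
optional `min_fold` parameter (default 1.0) allows stringency.

Under fixed sequencing depth the dual-order rule is better powered than
it looks: when a condition adds strong bivalent signal to some gene
bodies, the background share of the library shrinks, so genes *without*
bivalent chromatin see their normalized sequential-ChIP score drop
systematically in that condition. Their cold-vs-RT comparison is
therefore not a coin flip, and the false-positive rate among K4-only
genes stays below 5% even at 0.2 carry-over in the controls (verified
in the tests).

Mark classes (K4-only / K27-only / both / neither) threshold each
mark's input-normalized gene-body signal at 1.5× input — the package's
own documented choice.

## Reporting statistics

Association tables count, per feature category, the genes of each class
(up/down/constitutive) harboring ≥ 1 condition-specific DHS whose
summit resolves to that gene; percentages are reported at one decimal.
Class contrasts use the pooled two-proportion z test with two-tailed
normal probability (pooled variance is the package's choice; degenerate
tables return z = 0, p = 1). The rank-sum test enumerates all rank
assignments exactly for pooled sizes ≤ 12 and otherwise uses the
normal approximation with tie and continuity correction. Window
density correlations count events in non-overlapping windows (100 bp
for replicate coverage, 1 Mb suggested for density-vs-gene-density
correlations) and report Pearson r.

DE labels are consumed, not computed: a gene is differentially
expressed when both caller tables list it with the same direction at
FDR < 0.01; direction conflicts are dropped and logged. Active genes
have FPKM > 1 in both compared samples (strict); constitutively
silenced genes have FPKM = 0 in all samples. Random intergenic controls
are drawn uniformly over all placements ≥ 2 kb from any gene, matching
a template length list one-to-one.

## The synthetic generator

Defaults are the study conditions: 2 chromosomes × 1 Mb, 300 genes
(1–4 kb, ≥ 2 kb apart, 1–3 exons), 25% silenced / 20% up / 20% down /
35% constitutive, 30% of active genes bivalent, DNase depth 4×10⁵ cuts
per sample (2×10⁵ per Mb), ChIP depth 2×10⁵ fragments per channel,
carry-over 0.1. These sizes keep a full pipeline run under ~2 minutes
on one CPU while leaving ≥ 200 active genes for the rank-based
comparisons; they are the package's chosen desk-scale stand-in for the
original libraries, whose intensity distributions are not published.

DNase reads split their mass background/promoter/gene-body as
0.65/0.35/0 at RT and in leaves and 0.45/0.35/0.20 in cold. Promoter
hotspots are Gaussian bumps (sd 75 bp) centered 100 bp upstream of the
TSS — the scale at which real sensitivity peaks just upstream of genes —
weighted by the gene's expression quartile; cold gene-body bumps sit on
2 internal nucleosomes of the planted genes (all upregulated genes, all
bivalent genes, and 60% of the remaining active genes), bivalent genes
at twice the weight. ChIP channels draw ~150 bp fragments (midpoint
jitter sd 20 bp) from one fixed 180-bp nucleosome grid shared by all
channels, with per-nucleosome weights 1.0 (background) plus a mark
weight: K4me3 +3.0 on active bodies; K27me3 +2.0 on silenced bodies at
RT and, in cold, +1.8 silenced / +1.0 active / +2.5 bivalent (the
planted "active genes gain, silenced genes lose" direction); sequential
channels add carry-over × first-mark weight plus +6.0 on bivalent
bodies in cold only; noAb controls carry only the carry-over term.
These weights were fixed by a signal-to-noise budget (body of ~14
nucleosomes, a few hundred fragments per channel per body) so each
planted contrast clears its decision boundary by ≥ 2 sd.

What the generator does **not** emulate: sequence content (no FASTA or
aligner; tracks are position-level), mappability structure, copy-number
or GC biases, fragment-length chromatin dependence, isoform diversity,
and nucleosome-phasing oscillations in the DNase signal. Passing
recovery tests therefore demonstrates the correctness of the pipeline's
logic under the planted model, not robustness to every artifact of real
libraries.

## Numerical choices and edge cases

* ε = 0.01 floor on every signal denominator and pseudo-signal in
  ratios.
* Events on bin boundaries belong to the left (half-open) bin.
* Summit ties: leftmost base.
* Genes < 100 bp: excluded from metagene work, logged.
* Degenerate z-test tables (pooled proportion 0 or 1): z = 0, p = 1.
* Indistinguishable-from-null tracks: threshold +∞, zero DHSs.
* Sub-seeding: each simulated (sample, replicate, channel) derives its
  generator from `SeedSequence([seed, crc32(label)])`, so outputs are
  byte-identical for a fixed configuration and independent across
  channels.

## Known limitations

The FDR mechanism is a stated stand-in validated only by its own
calibration property; published genome-scale counts depend on the
original sequencing data and are not reproducible at desk scale, so the
package reproduces the printed ratio arithmetic and the directional/
recovery properties instead. The feature-precedence rule and the
consensus-interval union are documented choices where the source was
silent; alternatives are exposed as flags where they matter.
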