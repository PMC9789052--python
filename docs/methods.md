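# Methods

## Scope and model

`ntescan` implements a two-arm analysis for N-terminally extended proteoforms
(NTEs) initiated at non-AUG codons upstream of an annotated AUG start.

The **theoretical (primary) extension** of a transcript is found by walking
upstream from the annotated start in steps of three nucleotides until the
first in-frame stop codon (`stop_bounded`) or the 5'-most complete in-frame
codon of the transcript (`edge_bounded`); a leftover of one or two 5' bases
is never part of a codon. Transcripts whose annotated CDS is not a multiple
of three, carries truncation tags, or does not begin with ATG are excluded
from extraction (the ATG gate is switchable: annotated non-AUG models are
the product of reannotation, not its input). Analyses operate on the
**window** of at most 50 codons abutting the start; extensions shorter than
20 codons are discarded, and windows whose genomic footprint overlaps any
foreign coding exon on the same strand by at least one base are excluded.
The same-strand reading of the overlap rule is the default (a flag widens it
to both strands). One representative transcript per gene is kept — the
longest extension, ties by smallest transcript id — purely to make gene-level
sets deterministic.

All internal coordinates are 0-based half-open; GTF and FASTA-header
(1-based inclusive), BED (0-based half-open) and VCF (1-based) conventions
are converted only at I/O boundaries. Codons containing N match neither
start nor stop codons.

## Footprint detector

Profiles are P-site-assigned counts per transcript position in two channels
(elongating, initiating), summed over samples. For a candidate start c the
scored region is [c, cds_start). With F0/F1/F2 the per-frame read sums,
`occupied` the codons holding any read and `wins` the codons whose frame-0
position strictly exceeds both other frames (ties never win):

* `p_read = P(X >= F0)`, X ~ Binomial(F0+F1+F2, 1/3);
* `p_codon = P(W >= wins)`, W ~ Binomial(occupied, p0), where p0 is the mean
  over occupied codons of the exact trinomial probability that frame 0 holds
  a strict maximum given that codon's read total (enumerated exactly for
  totals <= 30, 1/3 beyond — the tie mass is negligible there). The
  codon-level statistic is robust to single-position pileups that can
  inflate the read-level one.

The two p-values are combined as `p_comb = min(1, 2 * min(p_read, p_codon))`,
a Bonferroni-adjusted minimum that is a valid p-value under arbitrary
dependence. The two statistics share the frame-0 counts and are strongly
positively dependent; a chi-square (Fisher) combination, which assumes
independence, measured a false-positive rate of 0.06–0.07 at the nominal
0.05 on noise-only simulations — at or above the calibration bound this
package holds itself to — while the adjusted minimum measures ~0.03 with no
practical loss of power at the planted effect sizes (detection there is
limited by the gates, not the combiner). Fisher remains available via
`RiboConfig(combiner="fisher")`.

Auxiliary scores: `sigma = (mu_down + eps)/(mu_up + eps)` with mu_down the
in-frame reads/codon over the scored region and mu_up the same over the up
to 15 in-frame codons upstream of the candidate but inside the extension
(0 if none), eps = 0.1; `iota` is the initiating-channel read count within
one codon of the candidate over the transcript-wide mean initiating reads
per codon (+ eps). Initiation data is intrinsically noisy (a single position
per initiation site), so iota is reported but not used in ranking by default
(config switch).

Gates: at least 10 in-frame reads in the scored region and non-zero codon
coverage; zero-read transcripts are never called. Per transcript the call is
the candidate with smallest p_comb, ties by larger sigma, then the 5'-most
position. The transcriptome-wide rank orders calls by p_comb ascending, ties
by mean density mu descending, then transcript id. Candidate codons are AUG
plus the nine near-cognates; AUG-called predictions are tagged and excluded
from non-AUG set building rather than discarded. All constants
(eps, the 15-codon upstream span, the read gate) are config-exposed.

P-site offsetting is out of scope: profiles arrive already P-site-assigned.

## Coding-evolution scorer

Windows are scored from a reference-anchored MAF. Columns are addressed by
reference base, so reference-insertion columns in other species drop out by
construction; bases covered by no block leave the non-reference species
missing at that codon; blocks are stitched across exons in transcript order
and complemented on the minus strand. The reference row must reproduce the
window sequence exactly (`ref_mismatch` otherwise).

The built-in scorer compares each species codon q to the reference codon r
pairwise over a star topology, ignoring phylogeny and branch lengths — a
deliberately simple, clearly-labelled stand-in (`scorer_id =
builtin_subst_v1`) that makes the pipeline testable end to end; per-codon
tracks from full phylogenetic codon models are read via
`read_external_scores` and classified identically. For a difference at k
positions, the expected synonymous/nonsynonymous single-step counts are
averaged over mutation orderings (Nei–Gojobori path counting; orderings
through stop-codon intermediates are excluded, with a fallback to all
orderings when every path is blocked). With f_s(r) the fraction of the nine
single-nucleotide neighbours of r that are synonymous (stop neighbours count
as nonsynonymous), each synonymous step contributes
`log(1 / (f_s + omega(1-f_s)))` and each nonsynonymous step
`log(omega / (f_s + omega(1-f_s)))` — the log-likelihood ratio of a
purifying model (nonsynonymous steps down-weighted by omega) against a
neutral one. Identical codons contribute 0; a species codon that is an
in-frame stop contributes the stop penalty (default −10); gap or missing
codons contribute nothing — alignment absence is not evidence. Defaults:
omega = 0.1 (strong purifying selection, relaxed N-termini still fall well
below 1), minimum 3 species (else the track is flagged `low_species`).
A window joins the conserved class iff its total is strictly positive.

## Gene sets and statistics

* Footprint sets: genes of the top-500 (and top-5000 for the extended set)
  ranked non-AUG calls.
* Control set (no upstream translation): rules applied in order, each
  transcript attributed to its first failure — (1) non-truncated CDS;
  (2) no coding-exon overlap of the extension; (3) extension >= 20 codons;
  (4) gene and transcript absent from the entire predicted set;
  (5) covered-position fraction in the extension <= 0.0005; (6) CDS in-frame
  reads per codon >= 1; (7) covered-position fraction in the CDS >= 0.3.
  One transcript per gene, the highest CDS coverage.
* Overlap tests: upper-tail hypergeometric over a configurable gene universe
  (default: all genes passing the complete-CDS gate; analyses that print an
  overlap p-value should also print their universe), BH-adjusted across the
  test family.
* Rank sweep: reference-set gains per 500-rank bin against a uniform-
  placement expectation (an explicit modelling choice), compared two-sided
  by Mann–Whitney (exact for <= 30 bins per side; the method used is
  recorded).
* Rank vs coverage: Spearman correlation of log10 mean CDS footprint density
  against rank; fewer than five pairs or constant input raise rather than
  returning an undefined coefficient.
* KS comparisons are exact for samples up to 30 per side, asymptotic
  otherwise, with the method recorded.

## Start-codon context

TIS efficiency is an exact 8-mer lookup — four upstream bases, the start
codon, one downstream base — on the scale where CACCAUGG scores 100; the
printed optimum is 8 nt, so the 8-mer is the table key (a config option
accepts a wider −4..+4 table). Missing contexts are reported missing, never
imputed. Context matrices count nucleotides per position over −4..+4 with
purine-at−3 and G-at+4 summarised separately. The structure scan slides a
22-nt window at 1-nt steps over −10..+100 around the start; the built-in
energy is minus the maximum number of nested base pairs (Nussinov dynamic
programme, minimum hairpin loop 3, G·U allowed) — a pair-maximisation
stand-in, not a thermodynamic model; external folding engines plug in via
`energy_fn` and every profile carries its `energy_model_id` so models are
never silently mixed.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
sequencing reality. Transcripts are composed as [pad][bounding stop]
[extension][CDS][3' UTR] with controllable extension length (default 20–120
codons), CDS length (100–300 codons), splicing (30% of genes, 2–3 exons),
strand, and edge-bounded fraction (15%). True-NTE genes carry a planted
near-cognate start (palette weighted CUG > GUG > ACG > ...) inside the
analysis window with at least 10 translated codons, and a strong Kozak-like
context (purine −3, G +4) with probability 0.8. Decoy classes plant
coding-exon overlaps (a second same-strand gene whose CDS invades the
victim's window while its own extension stays clear of any CDS), short
extensions, zero-coverage genes, and control-set rule violations including
reads placed exactly at the 1-read/codon and 0.3-breadth boundaries.

Reads are drawn per codon (Poisson at the configured depth, default 10 per
codon) and split across frames with frame-0 probability 0.8 in translated
regions, uniformly elsewhere; untranslated extension background runs at
depth/step_multiplier (default step 5); the initiating channel places a
20-read peak at true starts. A noise-only mode draws equal-frame reads
everywhere for calibration work. Alignments evolve each window codon
independently along a star tree of 10 species at 0.3 mutation events per
codon per branch, accepting nonsynonymous changes with probability omega
(0.1 coding, 1.0 neutral) and rejecting stop-creating changes in the coding
regime; this exercises the pairwise-to-reference scorer and is not a
phylogeny emulator. Everything is deterministic under (seed, config); every
emitted file carries the seed and a config hash, and the ground truth
records every planted feature.

What passing tests therefore show: the implementation agrees with its
specification and oracles, is calibrated under its own null, and separates
its own planted signal classes. What they do not show: performance on real
libraries with P-site offset error, nucleotide bias, multimapping,
incomplete annotation, alignment error or genuine phylogenetic structure —
none of which the generator models.

## Problem sizes and numerical choices

Default experiment sizes — 1,000-transcript extraction oracles, 500×500
interval-intersection oracles, 2,000-transcript calibration cohorts at depth
5, 500-gene detection cohorts (50 planted extensions), 200 windows per
selection regime — keep every check exact or well-powered while the whole
suite runs in well under a minute of compute; they are the package's
standing study conditions, fixed before any thresholds were measured.
P-values are floored at 1e-300 before combination; binomial/hypergeometric
tails come from scipy; BH adjustment from statsmodels. Ties in calling and
ranking break deterministically (sigma, then position; density, then
transcript id) so reruns are byte-identical. Degenerate inputs raise typed
errors (`range`, `no_structure`, `ref_mismatch`, `corrupt_profile`,
`universe_violation`, `insufficient_n`, `degenerate`) rather than returning
sentinel values.

## Known limitations

The built-in conservation scorer ignores phylogeny, branch lengths, codon
frequencies and alignment uncertainty; it is a screening statistic, not a
substitute for full phylogenetic codon models. The detector assumes
P-site-assigned, aggregation-ready profiles and models no offset error. The
structure energy is combinatorial, not thermodynamic. The generator's star
tree and per-codon independence understate real evolutionary correlation;
its read model has no sequence bias. Gene-level collapse and the uniform
null of the rank sweep are explicit, documented choices where the design was
genuinely open.
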