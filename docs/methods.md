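# Methods

## Reference model

The package works in 1-based inclusive rCRS coordinates (NC_012920,
16,569 bp). The genome is circular, but only one annotated feature crosses
the origin — the control region (D-loop), stored as the wrapping interval
16024..576 — so circularity is handled by an explicit wrap on that single
feature rather than by general modular arithmetic. The bundled region map is
the standard rCRS annotation (13 protein-coding genes, 22 tRNAs, 2 rRNAs,
control region, and the short non-coding spacers between genes); the
L-strand replication origin is deliberately not a map entry because it
overlaps two tRNAs and is never used as a tabulation category, which keeps
the map's multi-mapped positions exactly the known gene overlaps
(MT-ATP8/MT-ATP6 8527–8572, MT-ND4L/MT-ND4 10760–10766, and the 1–3 bp
junctions MT-TI/MT-TQ, MT-TC/MT-TY, MT-ATP6/MT-CO3). The map is an input
file, so a different annotation (or a non-human reference of the same
format) can be substituted.

Translation uses the vertebrate mitochondrial code taken from Biopython's
table 2. Six genes end in an incomplete codon completed to UAA by
polyadenylation of the transcript; the package applies that convention
uniformly: partial terminal codons are padded with A before translation, in
substitution annotation and in truncation scanning alike. A substitution
inside such a codon therefore annotates as a stop-loss (reported as
missense with `aa_ref = "stop"`), not as an error.

## Variant calling

Input is one Sanger-style consensus sequence per tissue, IUPAC ambiguity
codes allowed. Conceptually the caller performs a global affine-gap
alignment against the linearized reference (match +1, mismatch −1, gap open
−4, gap extend −1); because a full 16.6 kb × 16.6 kb dynamic program takes
seconds and the sequences are expected to be >99% identical, the
implementation first chains unique 21-mers shared by sample and reference
(longest colinear subset via patience LIS) and runs the affine-gap aligner
only on the short windows between anchor blocks. If anchoring covers less
than half the genome the full global alignment is used instead; a test
verifies the two paths call identically on planted-variant genomes.
Alignment identity below 90%, length outside 90–110% of the reference, or
non-IUPAC characters raise typed errors.

Each alignment difference becomes one variant: substitutions carry single
ref/alt bases; insertions are anchored on the reference base they follow
(`302 A-AC` = C inserted after 302); deletions are anchored on their first
deleted base. Indels are left-normalized within repeat runs, which makes
placement deterministic whatever the aligner's internal tie-break and
reproduces the conventional D310 notation. An ambiguity code whose two-base
set is {reference, alternate} is called as a heteroplasmic substitution
(the Sanger double peak); `N` in either sequence is a no-call; any other
ambiguity pattern is rejected as input error, since a Sanger consensus
cannot exhibit two non-reference alleles at a homoplasmic site. No
allele-fraction quantitation is attempted — the assay provides none.

Somatic classification compares tumor and normal call sets on
(position, ref, alt, kind), ignoring the heteroplasmy flag, so an allele
seen heteroplasmic in one tissue and homoplasmic in the other counts as
inherited. Variants only in the normal tissue are kept as a third class
rather than discarded.

## Consequence annotation

Substitutions in coding genes are resolved through the in-frame codon on
the coding strand (reverse complement for MT-ND6). Indels with net length
change not divisible by 3 are frameshifts; the mutated gene sequence alone
(no read-through into downstream genes) is translated codon-by-codon and
the frameshift is truncating iff a stop appears before the reference gene's
terminal codon. In-frame coding indels get a dedicated `inframe_indel`
effect — the effect vocabulary needs a non-frameshift outcome for them —
and are never flagged truncating. Variants in gene overlaps are annotated
against every containing gene; the first-listed gene (map order) is primary
and is the one tabulations count, a convention chosen because published
variant tables list one gene per variant (no variant of the validation
catalogue falls in an overlap, so the choice is unexercised by real data).

The annotator never trusts a stated reference allele: it is checked against
the rCRS and disagreements are flagged (`ref_mismatch`) while the
consequence is still computed from the true reference codon and the stated
alternate. The bundled 46-variant catalogue keeps two published rows that
are internally inconsistent — position 3877 lists ref T where the rCRS has
G (the stated alternate still reproduces the published Ala-Pro), and 8369
lists alt G whose computed effect is Pro-Ala where the publication printed
Pro-Ser (only C>T yields Ser) — and the acceptance test asserts these are
flagged, not forced.

## Conservation and pathogenicity

Site conservation is the fraction of rows in a vertebrate multiple
alignment (human included; 17 expected) whose aligned base equals the human
base; gaps never match. Published per-site values are reproducible only
with the original study's alignment, which is uncited; the package
therefore treats the alignment as an input and ships a synthetic generator
(`synthetic_species_alignment`) whose per-species divergence rises from 2%
to 35% across the species list — internally consistent for testing, not
comparable to published scores.

The pathogenicity consensus is a strict majority over a fixed panel of six
predictor programs: deleterious count > 3 → putative pathogenic. The panel
size stays 6 even when verdicts are missing (missing counts against),
making the rule deterministic. The frequency filter classes a variant as
rare below 0.5% population frequency, common at or above, unreported if
absent from the supplied table.

## Haplogroups

Full Phylotree nomenclature is out of scope. Assignment uses a flat table
of defining substitution motifs for 11 coarse East-Asian haplogroups (D, G,
M7, M8, M12 under macro-haplogroup M — sharing a 4-site M core motif — and
A, N9, R9, R11, B, H2 under N). The haplogroup with the highest fraction of
its defining sites present among a case's inherited variants wins; ties
break by absolute match count, then alphabetically; matching nothing yields
"unclassified". The bundled motif table is a constructed, synthetic
simplification (filename and docstring say so): positions are plausible
diagnostic sites whose reference alleles are validated against the rCRS at
load, sufficient for simulation and recovery testing, not for
lineage-accurate typing of real genomes. Distribution bias is tested by
Pearson chi-square — goodness of fit against a uniform null for a single
cohort, or a 2×k subset-vs-complement contingency test without continuity
correction. The original study's SPSS-computed P-values are not
reproducible from its printed marginals with standard tests; the package
reports its own statistics and makes no attempt to match.

## Copy number

Relative content is 2^−(Ct_mt − Ct_nuc) with base exactly 2 (100%
amplification efficiency; the assay description gives no efficiency
correction). Replicate Cts are combined by arithmetic mean before
exponentiation. An optional calibrator rescales the cohort by one constant
(e.g. to a chosen non-tumor mean); the ratio of group means and the
fraction of reduced pairs are invariant to it. The paired summary reports
group means with SEM, ratio of means, fraction of pairs with tumor below
normal, and a two-sided paired t-test.

## Synthetic cohort generator

The generator emits the stated world of the motivating study: 86 cases;
somatic variants in 40.7% of tumors, 1–3 each, placed 30% in the control
region, 20% in MT-ND5 and the remainder uniformly elsewhere; 89.8% of
substitutions transitions; 15% of somatic variants indels (the 7/46 in the
validation catalogue); somatic heteroplasmy rate 1/46; a non-tumor-only
heteroplasmic variant in ~5/86 of cases; haplogroups drawn at the study's
11-group frequencies; Poisson(10) private germline substitutions per case
(typical Asian mtDNA divergence from the rCRS is a few dozen sites; 10
keeps cohorts light while leaving motifs in the minority of calls); one
small germline indel in ~16/86 of cases, restricted to non-protein-coding
sequence as observed; IHC positivity 81.4% with a size-association odds
ratio of 3.65 (the value the published 2×2 cells imply); covariates at the
published demographics (age 55.3 ± 11, 80.2% male, grade I/II/III/IV =
10/61/14/1). Private variants avoid all diagnostic motif positions so that
clean-data haplogroup recovery is exact by construction. Randomness is
split into one child stream per facet (sequence, copy number, IHC,
covariates) spawned from the master seed, so adding a facet never perturbs
the others; output is byte-deterministic given the seed.

**Content model.** The published copy-number numbers are mutually
inconsistent under any per-pair ratio model: a ratio distribution with mean
0.49 mathematically forces more than 88% of pairs below 1, not the reported
69%, and the published SEMs imply far too little dispersion for 69%. The
generator therefore targets exactly the two parameters the analysis
recovers — the tumor/non-tumor **ratio of group means** (0.49) and the
**fraction of reduced pairs** (0.69) — with independent lognormal contents
per tissue sharing a log-scale SD σ and differing in log-mean by
ln(ratio); σ is solved from the reduced fraction
(σ = ln(1/ratio)/(√2 · Φ⁻¹(F)) ≈ 1.02). Consequences, documented rather
than hidden: published-scale SEMs are not reproduced, and a target pair
that is jointly infeasible (ratio < 1 with F ≤ 0.5) raises a config error.
A further consequence is statistical: the per-cohort ratio-of-means
estimator carries an O(CV²/n) upward bias (~+0.02 at n = 86 at this
dispersion), so the recovery test pools replicate group means and uses a
delta-method standard error instead of averaging biased per-cohort ratios.

**What a green recovery test does and does not establish.** It establishes
that calling, classification, haplogrouping and the statistical summaries
recover planted truth from cleanly generated files at the study's sample
size. It does not establish performance on real chromatograms: the
generator models no base-calling error, no alignment-breaking poly-C length
noise beyond planted indels, no NUMT contamination, and heteroplasmy only
as a binary IUPAC code.

## Numerical and degenerate-input choices

Alignment segment ties resolve to one deterministic alignment and indel
left-normalization makes the final placement canonical regardless. The
empty call set, the empty IHC table and a single-category haplogroup vector
are all explicit, typed outcomes (all-zero table, `undefined` flag,
degenerate-table error) rather than exceptions or NaNs leaking through.
2×2 odds ratios use the Haldane +0.5 correction only when a cell is zero.
All thresholds that embody a convention are parameters with the documented
defaults: rare-frequency 0.005, positivity rule product/≥1, age cutoff 60,
size cutoff 5 cm.

## Known limitations

Real-genome haplogroup calls are only as good as the synthetic motif table;
no chromatogram parsing; no read-level or fractional heteroplasmy; no
efficiency-corrected qPCR; conservation depends entirely on the supplied
alignment. The published cohort's raw sequences are not deposited anywhere,
so cohort-level published results are validated only through the printed
46-variant catalogue and through parameter recovery on synthetic data.
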