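# Methods

This note documents the models, conventions and numerical choices
behind each stage of the pipeline, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Orthologue pairing

Identity is defined on an end-to-end global alignment with match +1,
mismatch −1 and linear gap penalty −2, as matching columns divided by
total alignment columns; gap columns count as mismatches and `N` never
matches anything, including another `N`. Clustering tools used in
transcriptome studies do not publish a single canonical identity
formula, so this definition is fixed here and exposed as the unit the
thresholds apply to.

Redundancy collapsing merges transcripts at identity **strictly
greater** than the threshold (default 0.95) by single linkage and
keeps the longest member per class (ties: lexicographically smallest
id). The operation is idempotent. Cross-taxon pairing accepts
identity **≥** the threshold (default 0.90) and reduces candidates to
a one-to-one matching by greedy best-hit: identity first, then
alignment length, then ids — fully deterministic.

An optional k-mer prefilter skips alignments that provably cannot
reach the threshold, using two sound bounds: identity ≤
min(len)/max(len), and a shared 8-mer count lower bound implied by the
number of matching columns. It changes runtime, never results.

Complexity is quadratic in the number of transcripts per taxon
(all-vs-all global alignments); the package targets desk-scale and
simulated inputs, not full 70k-unigene transcriptomes.

## Reading frames and codon alignments

Transcripts are unannotated, so the coding region is taken as the
longest stop-free codon run over all six frames (minimum 50 codons by
default; shorter sequences are flagged non-coding and dropped). Ties
break deterministically: forward strand, lower offset, earlier start.
This replaces homology-based frame assignment and will mis-frame
sequences whose true ORF is shorter than a chance stop-free run in
another frame — rare at the default minimum, and immaterial for
simulated data where the generating frame is stop-free over the whole
gene.

Pairs are aligned at the protein level (global, BLOSUM62, gap open
−10, extend −0.5) and back-translated to codon columns. Columns with
a gap, an `N`, or a stop codon are excluded from counting.

## NG86 counting and correction

Sites: at each codon position the synonymous fraction is the share of
single-nucleotide changes **among those not creating a stop codon**
that preserve the amino acid; each position therefore contributes
exactly one site and S + N = 3 × counted codons. Site totals are
averaged over the two sequences. (Biopython's NG86 instead counts
stop-creating changes as nonsynonymous; its dS runs a few percent
higher. The convention here keeps the estimator in exact
correspondence with the simulator, which never proposes stop-creating
changes, and with the enumeration oracle used in the tests.)

Differences: codon pairs differing at d positions are resolved by
enumerating all d! orderings of the single changes, discarding
orderings that pass through a stop codon, and averaging the
synonymous/nonsynonymous step counts over the remainder. For sense
endpoints at least one stop-free ordering always exists: the three
stop codons of the standard code cannot cover every pathway (they are
never pairwise ≥2 substitutions apart in the required pattern), so the
estimator never needs a fallback.

Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) converts p_s and p_n
to rates; p ≥ 3/4 is undefined and such pairs are flagged `saturated`
and excluded downstream. ω = Ka/Ks is reported as a number when
Ks > 0, as the flag "> 1" when Ks = 0 < Ka, and "undefined" when both
are zero.

Known bias: equal-weight pathway averaging assumes synonymous and
nonsynonymous changes are equally likely along a pathway. When ω is
far from 1 and divergence is moderate, multi-hit codons are
misattributed slightly; at Ks = 0.05 and ω = 2 the pooled ω estimate
runs ≈3–4 % low. This is intrinsic to NG86 and visible only beyond
the replication used in the validation suite. A
maximum-likelihood-style estimator could be added behind the same
`RateEstimate` interface.

## Ks peaks

The species-pair distance is the mode of the per-orthologue Ks
distribution, computed as a fixed-width histogram (default width 0.01)
over [0, cap) with cap 2.0; values at or beyond the cap (saturated
tails) are dropped first. The peak is the left edge of the modal bin,
ties resolve to the lower bin, and a first-bin mode is held as 0.0
internally and displayed as "< 0.01". A histogram mode matches the
0.01 reporting grid of the packaged conifer matrix and is exactly
testable, unlike a kernel or mixture fit; with enough data and
narrower bins it converges on the distribution mode.

## Tree and clock

Neighbour joining follows the classical Saitou–Nei Q-criterion with
two determinism rules: Q ties resolve to the lowest node-index pair
(the conifer peak matrix has many tied entries), and negative branch
lengths are clamped to zero with a logged warning. On additive
matrices the algorithm reproduces the generating tree and its
distances exactly, which the tests exploit as an oracle.

Rooting places the root at the midpoint of the outgroup's pendant
edge; re-rooting on the same outgroup is a no-op.

Each split is dated from its branch-average Ks — the arithmetic mean
of all cross-clade pairwise peak values, reported to 3 decimals — via
age = Ks / rate with rate 0.68 × 10⁻⁹ synonymous substitutions per
site per year. Dividing the *pairwise* Ks by the one-lineage rate is
the calibration convention the packaged conifer ages follow
(0.146 → 214.7 Mya); the textbook per-lineage form Ks/(2·rate) is
available via `per_lineage=True`. Ages are rounded to 0.1 Mya;
coarser display rounding is left to the caller.

## Selection screen

A pair is positively selected iff ω > 1 strictly, including the
Ks = 0 < Ka convention; Ka = Ks = 0 is never selected. No
significance test is applied — with single-pair counts there is no
replication to test against, and the screen is explicitly a raw-ratio
filter; treat its output as candidates, not inferences. Annotation
is a left join on either member's id from a user-supplied map
(id → accession, label); conflicting labels from the two members are
both kept and flagged.

## Markers

SSRs are maximal perfect tandem repeats of primitive 1–6 nt motifs at
minimum repeat counts 12 (mono), 6 (di), 5 (tri, tetra), 4 (penta,
hexa). A run is reported once under its smallest repeating unit;
cyclic-rotation duplicates and runs contained in a longer reported run
are suppressed; `N` breaks a run; partial trailing units are not
counted, so coordinates always satisfy end − start = unit × repeats.
Compound/interrupted SSRs are not modelled. Coordinates are 0-based
half-open in memory and 1-based inclusive in TSV reports. Motifs are
reported as found on the given strand, with an optional
cyclic-rotation canonical form for grouping.

SNP typing is the standard purine/pyrimidine rule; of the 12 ordered
distinct base pairs, 4 are transitions and 8 transversions.

## Synthetic data generator

Sequences start as uniform draws over the 61 sense codons and evolve
by single-nucleotide events: the event count on a branch is Poisson
with mean 3L × ks × max(1, ω); each event picks a uniform position
and a uniform **non-stop** alternative base, and is accepted with
probability 1/max(1, ω) if synonymous, ω/max(1, ω) otherwise. This
makes the expected accepted density exactly ks per synonymous site and
ω·ks per nonsynonymous site, in the same site currency the NG86
estimator counts — the truth parameters are directly comparable to the
estimates (verified: at ks 0.05, ω 2, realized densities are 0.0501
and 0.0998 over 1000 replicates). Pair simulation splits the total
divergence evenly over two branches from the ancestor; clade
simulation evolves each gene independently along a user tree with
branch lengths in Ks units, plus optional random-codon decoy sequences
for pairing-specificity tests.

Not emulated: indels, codon-usage bias, among-site rate variation,
transition/transversion bias, shared polymorphism, assembly and
sequencing error. Passing round-trip tests therefore demonstrates
correctness of the inference chain under its own model assumptions,
not robustness to real-data artefacts such as frameshifts or chimeric
transcripts.

## Validation problem sizes

The validation suite runs at desk scale by design: parameter recovery
uses 200 replicates of 500-codon pairs per setting (3 Monte-Carlo
standard errors as the acceptance band, with ω pooled as the ratio of
replicate means and a jackknife standard error — the per-replicate
ratio is undefined when a replicate's Ks is 0 and is upward-biased by
Jensen's inequality); NG86 is checked exhaustively over all 61 × 61
sense-codon pairs; NJ additivity over random trees of up to 10 taxa;
SSR scanning against an independent regex-based oracle on 10 kb
sequences; and end-to-end pipeline runs use 4 taxa × ~14 genes of
120 codons, enough to recover the generating topology and peaks while
keeping all-vs-all alignment costs small.
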