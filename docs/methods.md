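# Methods

## Study design emulated by the generator

`memomir.simulate` emulates a three-group drought-memory experiment on wheat
seedlings: control (CG), direct drought (DD) and drought memory (DM; primed
with mild drought before a severe one), sampled at 0, 1, 6 and 12 h after
stress onset with three biological replicates — 33 small-RNA libraries —
plus one pooled degradome library per group. The generator plants:

* a baseline DE set (DM_0h vs CG_0h) of 198 miRNAs, 123 up / 75 down;
* DM- and DD-responsive unions over 1/6/12 h of 243 and 228 miRNAs with a
  57-miRNA overlap, 9 of which are additionally DE between DM and DD
  ("rescue"), giving 186 + 9 = 195 candidates;
* 64 candidates with degradome-validated cleavage sites on 445 distinct
  transcripts, 19 of them also baseline-DE;
* null miRNAs belonging to no set (86 in the `cs-memory-v1` preset of 500
  miRNAs).

Each union member is active at exactly one post-stress timepoint, drawn
uniformly from the seeded generator; the per-timepoint split is not itself a
design quantity. Shared non-rescue members receive *identical* effects in DM
and DD (so they are never DM-vs-DD significant); rescue members are
down-regulated at different depths in the two groups, making them DE in all
three contrast families.

## Acceptance noise mode and library balancing

In `noise_mode="acceptance"` counts are fully deterministic. Because DE is
computed on per-million-normalized counts, null miRNAs stay exactly flat only
if every library is scaled by the same factor, i.e. if all 33 library totals
are equal. The generator therefore balances each group × timepoint library
class to a constant total: planted effects are mostly 4-fold down-regulations
(count β/4 against base β), and one class-exclusive up-regulated "absorber"
member per class takes the integer residual (its fold is ≥ the nominal 4).
The 75 baseline-down members receive enlarged bases so the 0 h class has
enough down-capacity for the 123 fixed up-regulations. With exactly equal
totals, the zero-variance degenerate t-test conventions (below) recover every
planted set exactly and call no null — which is what makes the planted
cardinalities reproducible; Gaussian noise on nulls would scatter ~5% false
positives per contrast and destroy them.

`noise_mode="realistic"` draws gamma–Poisson (negative binomial) counts
around the same means with coefficient of variation `cv` (default 0.05);
recovery is then approximate and the planted counts are recalled only up to
type-I/II error.

What the generator does **not** emulate: real wheat sequence content,
miRNA family structure, isomiR abundance gradients, ligation biases,
sequencing errors (qualities are uniform Q40 except planted low-quality
reads), or degradome background with overdispersed pileups. Passing the
preset therefore demonstrates the correctness of the inference chain's
logic and arithmetic, not its robustness to biological noise.

## Reads and preprocessing

Read layout is insert + 3′ adapter (TruSeq-small-RNA-like,
`TGGAATTCTCGGGTGCCAAGG`) + 12-nt UMI, padded with A to 60 nt. 60 nt (not a
shorter read) is the default because a 25-nt insert plus the 21-nt adapter
and 12-nt UMI needs 58 cycles. Rejection rules: raw length outside 30–80 nt,
mean Phred < 20 (the concrete reading of "low-quality"), missing adapter, or
an empty insert. Adapter search is leftmost-first with one mismatch allowed
in the first eight adapter bases and exact agreement for the rest.

PCR duplicates are molecules identical in (insert, UMI); the duplication
ratio is defined as 1 − unique/total (the generator injects duplicates at
rate 0.2 of final reads). Contaminant filtering is exact full-length
substring matching against decoy rRNA/tRNA/snRNA/snoRNA/repeat/mRNA records
— deterministic and adequate for desk-scale decoys, not a replacement for
alignment against Rfam/Repbase — plus a low-complexity rule (one base >
80%) and the 18–25 nt gate for the miRNA tag set.

## Catalogue

Classification cascade (ACGT101-style compatibility convention; the gp2a/2b
split is operationalized as hairpin success at the genomic locus):
wheat-mature match (≤ 2 substitutions and/or ≤ 2-nt end shifts) mapping
within its precursor → gp1a; precursor-only mapping → gp1b; non-wheat mature
match with a folding genomic window → gp2a, with a non-folding window →
gp2b, without a genomic locus → gp3; no mature match but a folding genomic
window → gp4 (novel); otherwise unassigned.

Folding is Nussinov maximum base-pairing (AU/GC/GU, minimum loop 3) with a
diagonal-vectorized DP and an outer-pair-first traceback, so a perfect
inverted repeat folds to its rod stem deterministically. A window hosts a
miRNA hairpin when the mature sits entirely on one arm (no internal pairs,
all partners on one side), ≥ 60% of mature bases are paired, the hairpin
loop is ≥ 3 nt and ≥ 45% of window bases are paired. Maximum pairing is
dependency-free and deterministic; it overestimates pairing relative to
free-energy folding, which is why the non-folding decoy windows are built
with poly-A flanks rather than random flanks.

Variant naming follows the `_L±k`/`_R±k`/`_nss<pos><ref><obs>` suffix
grammar (e.g. `_L-2` for a 2-nt 5′ trim, `_1ss21GA` for G→A at tag position
21). Trims and substitutions are invertible from the suffix; 5′/3′
extensions consume precursor context, so `apply_variant` takes an optional
context argument.

## Expression and DE

Counts are scaled per library to 1e6 (per-million over miRNA-mapped
molecules; the "modified" aspect of the original global normalization is
unspecified upstream, so plain per-million scaling is used and flagged).
Expression bins: low ≤ 10 < medium ≤ dataset mean < high, with the x = 10
boundary assigned to low.

DE is a two-sided pooled-variance Student's t (not Welch), with degenerate
conventions chosen for deterministic inputs: both groups zero-variance and
equal means → p = 1; zero-variance and unequal means → p = 0. One-way ANOVA
inherits the same conventions. log2 fold changes use a +1 pseudocount.
No multiple-testing correction is applied by default, matching the plain
p < 0.05 threshold of the emulated analysis; `alpha` is configurable.

## Memory selection

`candidates = (DM-union \ DD-union) ∪ (DM-union ∩ DD-union ∩ DM-vs-DD-union)`,
with all three unions taken over the 1/6/12 h timepoints (0 h feeds the
baseline contrast only). The DM-vs-DD union over the three post-stress
timepoints is a design choice made for symmetry with the other unions; a
rescue miRNA needs significance at any one timepoint.

## Degradome validation

Degradome tags map to every transcript position where their first 20 nt
match exactly; multi-mapping tags count once per locus. T-plot categories
follow the 0–4 scheme with the maximum-based rules taking precedence over
the mean comparison (a uniform multi-peak profile is category 1, not 3), and
the mean over covered positions only (an all-positions option is exposed
upstream of the category threshold via the profile itself). The cleavage
position is the transcript base paired to miRNA nucleotide 10; coordinates
are 1-based and closed. Duplex scoring: match 0 / G:U 0.5 / mismatch 1,
doubled opposite miRNA positions 2–13, ungapped, cutoff 4.0 — a
compatibility default for the classic plant-target scheme. Validation keeps
sites with category ≤ 2 ("categories < 3"; `category_max=3` reproduces the
alternative "categories 0–3" reading) and more than one read.
`validate_targets` enumerates covered positions with count > 1 first and
scores only the implied windows; this is equivalent to filtering the sliding
`find_candidate_sites` scan and is cross-checked against it in the tests.

## Enrichment

Hypergeometric upper tail P(X ≥ k) per term, population = genes with ≥ 1
annotation in the supplied map (standard ORA practice; a custom population
may be passed), significant at p < 0.05, no correction by default. The
association export contains miRNA→gene edges for validated candidate hits
and gene→term edges for significant terms.

## Problem sizes and numerics

The `cs-memory-v1` preset uses 500 miRNAs × 33 libraries at base count 12
(≈ 0.5 M reads total) and 500 transcripts of 300 nt — deliberately
desk-scale: sequencing depth is a free parameter of the design being
emulated, and these sizes keep a full pipeline run below ten seconds while
exercising every rule. Genome windows are ≤ 300 nt (the folding DP is
O(n³)). All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical (config, seed) gives byte-identical
FASTA/FASTQ output. The preset seed is the fixed documented constant
20220525.

## Known limitations

* Exact-substring contaminant matching and exact transcript mapping do not
  model mismatches or indels in real reads.
* Nussinov maximum pairing is not an energy model; borderline hairpins that
  RNAfold would reject can pass, and vice versa.
* UMI deduplication is exact-match; directional-network UMI error correction
  is out of scope.
* The DE machinery has no dispersion modelling (no negative-binomial
  shrinkage); it reproduces the t-test/ANOVA analysis it emulates.
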