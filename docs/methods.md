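# Methods

This note documents the models, conventions and numerical choices behind
`repgut`, and what the synthetic-data tests do and do not demonstrate
about real sequencing data.

## Germline reference

The packaged reference is synthetic: nine heavy-chain V alleles over
four families (names `TVH1-1*01` … `TVH4-2*01`, plus a second allele
`TVH3-1*02`), four J alleles and two constant segments (IGA, IGG),
generated deterministically from a fixed seed. It is not IMGT data and
carries no licensing constraints. Families are ~75% divergent and
sibling genes (and the second allele) differ at nine codons, so segment
assignment stays unambiguous even at 20+ hypermutations; real IGHV genes
are far more similar, and allele-level call accuracy on real data is
therefore not claimed. Every V is in frame from its first base and ends
with the conserved Cys104 codon (`cys104_offset = len − 3`); every J
begins with 6 nt of CDR_H3 tail followed by a W-G-x-G framework-4 motif
(`fr4_motif_offset = 6`). Anchor invariants are validated on load.

Coordinates are 0-based half-open internally; serialized alignment
positions (`v_subject_start`) are 1-based because the subject-start
quality filter (reject when start > 9) is stated as a BLAST-style
position.

## Alignment model

Two routes coexist:

* `align_local` is an exact affine local aligner (match +1, mismatch −2,
  gap open −5, gap extend −2, i.e. a length-L gap costs 5 + 2L) built on
  `Bio.Align.PairwiseAligner`, with deterministic tie-breaking (lowest
  query start, then subject start). The test suite checks it against an
  independent naive Gotoh dynamic program on random instances.
* Bulk assignment (`assign_vj`, `call_isotype`) places each *full*
  germline segment at its best ungapped offset in the read, clipping
  only at read boundaries (vectorized over all offsets). This is exact
  under the pipeline's substitution-only sequence model — the network
  stage itself admits only non-indel differences, and indel
  hypermutation is a declared non-goal — and roughly an order of
  magnitude faster than the gapped DP. A 5'-truncated read naturally
  yields `v_subject_start > 1`, which is what the subject-start filter
  keys on. Reads containing indels relative to their germline would be
  scored pessimistically by this route; they are outside the model.

E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with λ solved
numerically for the +1/−2 scheme at uniform base composition
(λ ≈ 1.34) and K fixed at 0.46, the conventional value for this
nucleotide scheme. Since any fixed (λ, K) is a monotone calibration of
the score, the E ≤ 10⁻³ filter behaves identically under any
re-calibration; only the printed magnitudes would shift. The bit-score
floor for accepting a segment call is 20 bits — shuffled (non-Ig) input
falls far below it.

## CDR_H3 convention

CDR_H3 runs from the codon *after* the V-anchored Cys104 to the codon
*before* the J-anchored Trp of W-G-x-G (IMGT junction minus anchors).
The motif must survive in the read itself: a substitution destroying the
Trp or either Gly triggers `cdr3_motif_fail`, as does a junction whose
length is not a multiple of 3 (frame shift). Productivity is absence of
stop codons in the V-region frame from the first complete aligned V
codon through the end of the aligned J.

## Mutation counting

`vh_mutation_count` is the number of mismatched aligned positions over
the V alignment, excluding positions where the read base is N (ambiguity
from sequencing should not inflate SHM); the frequency is 100 × count /
aligned V length. On error-free simulator output the count equals the
planted truth exactly, which is what the clean-limit acceptance test
asserts.

## Merging

The merger re-implements the computation the pipeline needs from a
paired-end merger: admissible placements need ≥ 10 overlapping
nucleotides and overlap mismatch rate ≤ 0.25; among admissible
placements the one maximizing matches wins (ties: lower mismatch rate,
then smaller offset). Overlap bases are voted by quality (tie → 5'
read), merged quality is the per-base max, trimming is terminal-only at
Q20, and products shorter than 300 nt are dropped. Parity with any
specific merging tool's statistical test is not claimed; the contract is
the exact round trip on error-free pairs and the stated thresholds.

## Dereplication and clonal families

Dereplication is greedy incremental clustering in decreasing
(duplicate_count, length) order: a record joins the first existing seed
with ≥ 99% global identity, else opens a cluster. Identity is matches /
alignment-columns of an edlib global alignment; a k-mer signature and a
length screen prune candidate comparisons without changing results (the
test oracle is a screen-free re-implementation with an independent
Levenshtein distance).

The clonal rule — same V gene, same J gene (allele suffix `*NN`
stripped, since SHM routinely obscures alleles), equal CDR_H3 amino-acid
length, CDR_H3 identity ≥ 0.8 — is read as normalized *similarity* with
single-linkage closure inside each (V, J, length) bucket: a distance
≥ 0.8 would merge near-unrelated junctions, contradicting the rule's
purpose. Family ids are content hashes of sorted member ids, so the
partition is order-invariant.

Networks connect unique sequences at Hamming distance exactly 1
(equal length, one substitution), built with a one-position-wildcard
index in expected O(n·L); the brute-force all-pairs oracle remains the
test authority. The clone-size tail exponent is estimated by the
discrete zeta MLE.

## Group statistics

Two-sided Fisher exact tests use the probability-mass rule (sum of
hypergeometric probabilities no greater than the observed table's, with
the conventional 1 + 10⁻⁷ tie slack), delegated to scipy and verified
against an exact-rational enumeration oracle for all margins ≤ 12.
Welch's t uses the Satterthwaite degrees of freedom. The volcano
significance flag is the *unadjusted* p < 0.05, as such figures
conventionally draw it; Benjamini–Hochberg-adjusted p-values are
reported alongside rather than replacing it. CDR3 charge is
(#R + #K) − (#D + #E) with histidine excluded (pH 7 convention); CDR3
length classes are ≤ 10 / 11–17 / ≥ 18 aa. Heavy–light pairing features
appear only when a paired single-cell table is supplied; bulk records
contribute heavy-chain features. The panel enumerates every observed
(feature, level) pair and reports its own parameter count.

## Sharing rule

A mucosal monoclonal matches a bulk sequence iff V gene and J gene are
identical, CDR_H3 lengths are equal, and CDR_H3 amino-acid identity is
≥ 0.90. Length equality is required because homology between
different-length junctions is undefined without an indel model, and
clonal relatives share junction length. Isotype is deliberately not part
of the rule (shared clones appear under both IgA and IgG). Raising the
identity threshold can only shrink the match set (tested property).

## Reactivity metrics

ELISA: AUC is the trapezoid integral of OD405 against
log10(concentration) with negative ODs clamped to 0; the cumulative AUC
is log10(ΣAUC + 1), the +1 keeping a zero-binding antibody at exactly 0.
Microarray: per-array robust Z = (MFI − median)/(1.4826·MAD) after
averaging duplicate spots; σᵢ = (Z_test,i − Z_ref,i)/√2 is the signed
perpendicular deviation from the test-vs-reference diagonal; PI is the
fraction of proteins with σᵢ > 2; an antibody is polyreactive iff
PI > 0.21 (strictly). The PI functional form is a reconstruction that
preserves the published threshold semantics (PI ∈ [0,1], cutoff 0.21);
numerical parity with the vendor's scoring software is not claimed, and
a MAD of zero is reported as a degenerate array rather than scored.

## Synthetic repertoire generator

The generator emulates the study conditions: two groups × two
compartments, clonal lineages with a random in-frame junction insert of
9–60 nt, IgA/IgG mix per compartment (gut P(IgA) = 36/58 from the
reported 36% IgA vs 22% IgG memory split; blood 0.55, a chosen
IgA-leaning default), per-(group, compartment, isotype) mean V_H
mutation loads set to the published violin-plot means (gut IgA
20.5/21.4, gut IgG 22.0/21.9, blood IgA 18.4/19.8, blood IgG 19.8/18.9),
gut→blood clone seeding probabilities 0.049 (eART) and 0.333 (lART),
per-clone polyreactivity probabilities 0.188 and 0.313, and power-law
duplicate counts with exponent 2.5 (a modelling choice; no clone-size
law is published).

SHM is substitution-only: per clone a shared load ~ Poisson(0.6·μ) and
per member a private load ~ Poisson(0.4·μ) are drawn without positional
overlap, uniformly over the V region excluding the anchor Cys codon.
For blood members of shared gut clones the private mean is adjusted so
the blood stratum keeps its configured mean. Substitutions that would
create an in-frame stop codon are resampled — selection keeps expressed
receptors productive, and it lets the clean-limit tests compare against
the complete truth table rather than a stop-censored subset. Paired
reads split each template around a configurable overlap (default
150 nt, 300 nt reads); sequencing errors are uniform substitutions at
`read_error_rate` (default 0.001) with visibly lower Phred qualities on
erroneous bases.

What passing tests show: the pipeline's operations are exact under the
generator's model (no indels, uniform errors, well-separated germline
segments, anchor codons intact). What they do not show: robustness to
indel SHM or sequencing indels, chimeras, primer artefacts, highly
similar germline alleles, or biased SHM hotspot targeting — all outside
the generator by design.

## Problem sizes

The clean-limit end-to-end check runs 200 clones per group-compartment
(~4,400 sequences); SHM-mean recovery runs 2,000 clones per
group-compartment (~10k sequences each, ~40k total, so every
group-compartment-isotype stratum holds ≥ 3,700 sequences and the
standard error of a mean near 20 is ≈ 0.07, far inside the 5% band);
sharing recovery pools 100 sampled mAbs per group over 50 simulation
seeds; statistical calibration uses 1,000 null replicates at n = 500
per group for Fisher (large margins, where the exact test's discreteness
is negligible) and n = 30 per group for Welch.

A note on partition identity: with ~800 simulated lineages, two distinct
clones occasionally share a V/J/length bucket and a ≥ 0.8-identical
junction by chance; the clonal rule then merges them, exactly as it
would on real data. The clean-limit identity check therefore holds at
its fixed simulation seed, while across arbitrary seeds the adjusted
Rand index against truth can dip marginally below 1 (≈ 0.998) — an
ambiguity of the rule, not an implementation error.

## Known limitations

Real IgBlast/CD-HIT/PEAR output parity is not attempted — the stated
computations are re-implemented and their contracts tested against
oracles instead. D segments are not assigned (the clonal rule needs only
V, J and CDR_H3; D-family features are read from supplied single-cell
tables). Light chains enter only pre-annotated. The E-value's K is a
fixed calibration constant, so absolute E magnitudes differ from BLAST's
while the filter's behaviour does not.
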