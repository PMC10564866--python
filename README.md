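# repgut

Analysis of class-switched B-cell receptor (BCR) heavy-chain repertoires
from paired gut mucosa and peripheral blood samples, built for studies
comparing two donor groups (here labelled eART and lART, individuals
starting antiretroviral therapy early versus late in HIV-1 infection).
The package implements the full bulk-sequencing workflow — paired-end
amplicon merging, germline V/J assignment, CDR_H3 extraction, somatic
hypermutation (SHM) counting, quality filtering, dereplication, clonal
family inference, single-nucleotide mutation networks, repertoire
feature statistics, gut↔blood clone-sharing detection and antibody
polyreactivity metrics — together with a synthetic repertoire generator
that provides exact ground truth for every stage.

## The core computations

* **Merging.** Reverse-complement the 3' read, place it at the overlap
  offset maximizing matches (≥ 10 overlapping nucleotides, mismatch rate
  ≤ 0.25), vote disagreeing bases by Phred quality, trim terminal bases
  below Q20 and drop products shorter than 300 nt.
* **Annotation.** Each germline segment is aligned to the read (match
  +1, mismatch −2; a length-L gap costs 5 + 2L in the general local
  aligner), with BLAST-style Karlin–Altschul E-values
  E = K·m·n·e^(−λS). Reads failing any of four filters are removed:
  in-frame stop codon, V-gene E-value > 10⁻³, no W-G-x-G
  framework-4 motif bounding CDR_H3, or V alignment starting past
  germline position 9. CDR_H3 spans the codons between the conserved
  V-gene Cys104 and the J-gene Trp of W-G-x-G (anchors excluded); SHM is
  the number of mismatched aligned V positions (read N's excluded),
  reported as a count and as percent of the aligned V.
* **Clonotyping.** Reads are dereplicated at 99% global identity
  (greedy, CD-HIT style). Clonal families group sequences with the same
  V gene, same J gene, equal CDR_H3 length and CDR_H3 amino-acid
  identity ≥ 0.8 (single linkage). Mutation networks connect unique
  sequences differing by exactly one non-indel nucleotide.
* **Statistics.** Categorical repertoire parameters (V family, J gene,
  V–J pairing, isotype, CDR3 charge/length classes, …) are compared
  between groups with the two-sided 2×2 Fisher exact test; continuous
  parameters (CDR_H3 length, mutation counts) with Welch's t test;
  correlation panels with Pearson r and Benjamini–Hochberg FDR control.
* **Sharing.** A mucosal monoclonal antibody is called "found in blood"
  when a bulk blood sequence carries the identical V and J genes, an
  equal-length CDR_H3 and ≥ 90% CDR_H3 amino-acid identity.
* **Reactivity.** ELISA curves are summarized by the trapezoid AUC of
  OD405 over log10(concentration) and the panel-level cumulative AUC
  log10(ΣAUC + 1); microarray profiles by robust per-array Z-scores,
  the diagonal deviation σ = (Z_test − Z_ref)/√2, and the polyreactivity
  index PI (fraction of proteins with σ > 2), with antibodies classified
  polyreactive when PI > 0.21 (strict).

## Worked example

```python
from repgut import SimulationConfig, MergeParams, QCParams
from repgut.synthetic_repertoire import simulate_repertoire, emit_paired_reads
from repgut.read_processing import merge_pairs, apply_qc
from repgut.annotation import annotate
from repgut.clonal_analysis import dereplicate_99, infer_clonal_families

rep = simulate_repertoire(SimulationConfig(seed=11, n_clones=50, read_error_rate=0.0))
r1, r2 = emit_paired_reads(rep)
merged, report = merge_pairs(r1, r2, MergeParams())
print(report)
annotated = annotate(merged, rep.reference)
passing, rejected, qc_report = apply_qc(annotated, QCParams())
families = infer_clonal_families(dereplicate_99(passing))
print(len(families), "clonal families from", len(passing), "sequences")
print("mean V_H mutations:",
      round(sum(r.vh_mutation_count for r in passing) / len(passing), 2))
```

Output:

```
{'input': 1071, 'merged': 1071, 'discarded_overlap': 0, 'discarded_length': 0}
200 clonal families from 1071 sequences
mean V_H mutations: 19.58
```

All 1071 error-free read pairs merge, the 200 simulated clonal lineages
are recovered exactly, and the mean V_H mutation load reflects the
configured group-specific SHM means (≈ 18–22 substitutions).

The same stages are exposed on the command line:

```bash
repgut simulate --seed 11 --n-clones 50 --outdir sim/
repgut merge --r1 sim/R1.fastq --r2 sim/R2.fastq --out merged.fasta
repgut annotate --in merged.fasta --out rearr.tsv
repgut run --config run.yaml          # full pipeline with a manifest
```

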