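# porefix

Correction-based functional annotation of noisy nanopore metagenomic reads.

Nanopore long reads carry enough information to annotate unassembled soil
and sediment metagenomes, but their indel-rich errors (~5% per base) break
reading frames, so gene callers and homology search lose most signal.
`porefix` implements the correction-first alternative to assembly as a
tested Python library plus CLI:

1. **Quality masking** — bases with Phred quality < 5 are replaced by `N`
   so they cannot mislead downstream alignment.
2. **Pileup polishing** — accurate short reads placed on the long read vote
   per position; a majority-vote consensus (depth ≥ 4, fraction ≥ 0.7)
   fixes substitutions and indels where coverage allows.
3. **Frameshift-aware DNA-to-protein alignment** — a Smith–Waterman-style
   dynamic program over (read position, protein position) in which a codon
   column may consume 2, 3 or 4 nucleotides. A 2-nt column (`\`, forward
   shift) marks a base missing from the read; a 4-nt column (`/`, reverse
   shift) marks a spurious inserted base; each costs a frameshift penalty
   *f* (default 15, BLOSUM62, affine gaps 11/1):

   ```
   M(i,j) = max( 0,
                 best(i-3, j-1) + s(aa(dna[i-3..i]), p_j),
                 best(i-2, j-1) + s(aa(dna[i-3..i]), p_j) - f,   # '\'
                 best(i-4, j-1) + s(aa(dna[i-3..i]), p_j) - f )  # '/'
   ```

4. **Frameshift correction** — each `\` inserts a copy of the previous
   nucleotide; each `/` deletes the current nucleotide. Overlapping
   alignments are resolved greedily by score, so each read region is
   corrected by at most one reference protein.
5. **Annotation** — six-frame open-ended ORF calling (≥ 30 aa, `N` codons
   translate to `X` and do not terminate), then best-hit assignment of KEGG
   Orthology (KO) labels by protein–protein alignment against a KO-labelled
   database, evaluated as multiset precision/recall against a gold standard.

The package also implements the two quantitative formulas used alongside
such surveys: **RPKM** transcriptional activity,
`RPKM_g = reads_g / ((len_g/1000) · (total/10⁶))`, and the **static-chamber
gas flux** `R_gas = (ΔC/Δt) · P·V / (R·T·A)` (slope in ppm/h, P in atm, V in
L, R = 0.0821 L·atm·K⁻¹·mol⁻¹, T in K, A in m² or kg), whose sign separates
soil emission from consumption.

A synthetic-data module generates coding-dense mock genomes with KO-labelled
proteins, error-injected nanopore-like reads with exact truth records, short
reads with true placements, and linear gas series — everything needed to
benchmark the pipeline with known ground truth.

## Worked example

```bash
porefix mock --out-dir demo --n-genes 8 --n-reads 12 --read-len 600 --seed 3
porefix run --reads demo/reads.fastq --proteins demo/proteins.faa \
            --gold demo/gold_ko.tsv --out-dir demo/out --seed 1
cat demo/out/evaluation.json
```

prints (seed 3/1, 12 reads at 5% error):

```json
{
  "n_tp": 25,
  "n_fp": 3,
  "n_fn": 1,
  "micro_precision": 0.8928571428571429,
  "micro_recall": 0.9615384615384616,
  "macro_precision": 0.9166666666666665,
  "macro_recall": 0.9583333333333334
}
```

— of the 26 gene copies overlapping the 12 reads, 25 are assigned their
correct KO after masking and frameshift correction, with three spurious or
duplicate calls and one missed gene. `demo/out/correction_stats.json`
reports the 79 frameshift events the aligner found (13.4 per kilobase of
aligned read at this error setting), and `demo/out/edits.tsv` lists every
base-level repair.

In the library the same flow is:

```python
from porefix import (MockGenomeSpec, ErrorModel, ScoringScheme, gen_reference,
                     gen_mock_reads, correct_reads, annotate_reads)

ref = gen_reference(MockGenomeSpec(n_genes=8, seed=3))
reads, truths = gen_mock_reads(ref, 12, 600, ErrorModel(total_rate=0.05), seed=4)
corrected, stats = correct_reads(reads, ref.proteins, ScoringScheme())
results = annotate_reads(corrected, ref.proteins)
```

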