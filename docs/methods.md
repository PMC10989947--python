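# Methods

## The correction-based annotation model

Unassembled nanopore reads of a diverse metagenome cannot be annotated
directly: at a ~5% per-base error rate dominated by indels, reading frames
break every few dozen codons. `porefix` treats annotation as a
correction-first problem with three repair stages followed by
alignment-based gene assignment.

**Quality masking.** Bases with Phred quality strictly below `q_min = 5`
(error probability > ~68%) are replaced by `N`. Masking is idempotent and
keeps the quality string, so no information is destroyed. Downstream, any
codon containing `N` translates to `X`, which scores 0 against every
residue: masked positions are neutral rather than misleading.

**Pileup polishing.** Short accurate reads placed on a long read vote per
long-read position. The stage is a transparent majority-vote consensus, not
a reimplementation of a full polisher: at columns with depth ≥ `min_depth`
(default 4), the read base is replaced when a different base reaches the
consensus fraction `tau` (default 0.7), deleted when the deletion fraction
reaches `tau`, and the most common inserted string anchored after a column
is inserted when it reaches `tau`. Positions below `min_depth` are
untouched; "polished fraction" of a read is the fraction of positions with
depth ≥ `min_depth`. Consensus may restore a base over an `N` mask.
Substituted bases keep their quality; inserted bases get quality
`min(depth, 40)` — a pragmatic convention, not a calibrated probability.

**Frameshift-aware alignment.** A local dynamic program over (nucleotide
prefix i, protein prefix j) with three states (match, read-codon gap,
amino-acid gap). A match column normally consumes 3 nt; consuming 2 nt is a
forward shift (`\`, one base missing from the read) and consuming 4 nt is a
reverse shift (`/`, one spurious base), each at penalty `f` (default 15).
Gap runs are affine: a k-long gap costs `gap_open + (k-1)*gap_extend`
(defaults 11/1), matching common translated-search practice; the
substitution matrix is BLOSUM62 with the `X` row and column set to 0.
Alignments below `min_score` (default 60) are discarded.

*Translation of shifted columns.* Both shifted columns translate the last
three nucleotides ending at the column boundary, `dna[i-3:i]`. For a 2-nt
column this borrows the base preceding the column — exactly the codon
produced when the repair inserts a duplicate of that base. For a 4-nt
column it drops the first consumed base — the codon produced when the
repair deletes it. Aligner and corrector therefore agree by construction
about what every shifted codon means.

*Determinism.* Ties break by higher score, then fewer shift events, then
ascending protein id, then ascending read start; the traceback prefers the
plain 3-nt interpretation over shifted ones at equal score.

*X-run cap.* A run of more than `x_run_cap` (default 10) consecutive all-`X`
codons zeroes the match state, so local alignments cannot bridge long
masked stretches for free — emulating alignment breakage at unpolishable
regions while still aligning reads intact.

*Search.* Every read is aligned on both strands against every candidate
protein. By default a seed prescreen (shared amino-acid 5-mers between the
six-frame translation of the read and the database) limits the dynamic
program to plausible pairs; `prefilter=False` disables it. Minus-strand
intervals and event positions are mapped back to original-strand
coordinates.

**Correction.** A forward shift at position p inserts a copy of
`read[p-1]` before p; a reverse shift deletes `read[p]`. On the minus
strand the "previous base" lives on the reverse complement: the repair
inserts a duplicate of `read[p+1]` right after the event position, and
deletions map position-for-position. Overlapping alignments on one read are
resolved greedily by descending score (ties by ascending protein id), so
each region is corrected by at most one protein; edits are applied in
descending position order. The frameshift rate is reported as events per
kilobase of kept (non-overlapping) aligned read sequence.

**Annotation.** ORFs are maximal stop-free stretches of ≥ `min_aa`
(default 30) amino acids in any of the six frames, open-ended at read
boundaries because reads are fragments; `X` does not terminate an ORF. Each
ORF is aligned protein-vs-protein (same matrix and gap costs) against the
KO-labelled database; the best hit with score ≥ `min_score` yields at most
one KO call per ORF, ties broken by ascending protein id. Evaluation
compares the multiset of KO calls per read against a gold multiset:
duplicate calls for one gene count as false positives. Micro averages
(pooled counts) are the headline; macro averages (per-read means) are also
reported. An alignment-based assigner was chosen deliberately: HMM-based
annotators assume locally intact frames and behave poorly on
frameshift-corrected reads.

## What the synthetic data emulates — and what it does not

`gen_reference` builds a coding-dense genome: ATG-started stop-free genes of
`gene_len_aa` codons (default 100) separated by `intergenic_len` (default
50) random spacers, each gene labelled with a unique synthetic KO id
(`KMOCK…`; no external database is needed). Spacers of ≥ 12 nt embed the
cassette `TTAATTAATTAA`, which contains a stop codon in all six frames, so
no open reading frame spans two genes — mirroring the stop-delimited
structure of real genes and keeping "one KO call per ORF" well defined.

`corrupt_sequence` hits each position independently at `total_rate`
(default 0.05) and draws the error type from `mix` (default 0.50
substitution / 0.25 insertion / 0.25 deletion — an approximation of
nanopore error composition; only the total rate is treated as a contract).
Error-free positions draw qualities uniformly from [10, 30], erroneous bases
from [3, 10), giving the masking stage realistic signal. Every read carries
a truth record whose edit list replays to the noisy sequence exactly. A
`homopolymer` mode restricts indels to duplications and homopolymer
deletions, as in real nanopore data.

What the generator does **not** emulate: position- and context-dependent
error hotspots, quality-score correlation along the read, chimeras, strand
bias (mock genes all lie on the forward strand; strand handling is
exercised by dedicated alignment tests), real KO families with paralogs,
and database incompleteness. Passing benchmarks therefore demonstrate the
correctness of the machinery under the stated error model, not performance
on real flow-cell data.

`gen_short_reads` places `ceil(coverage·L/read_len)` reads uniformly with
independent substitution errors and emits their true placements;
`project_to_noisy` re-expresses placements made on the clean fragment as
CIGARs against the corrupted read (truth deletions become query-only
columns, truth insertions target-only columns), standing in for a short-read
mapper with a perfect oracle. `gen_gas_series` produces
`intercept + slope·t + N(0, sd)` on the standard 0/20/40/60/80-minute
chamber grid.

## Benchmark design choices

**Exact-restoration benchmark (`inject_codon_indels`).** The repair rule —
insert a duplicate of the previous base, delete the current base — operates
at codon granularity. Analysis of the dynamic program shows it can restore
the *exact* original string only for indels at codon boundaries in
homopolymer context: a duplication of the base before a boundary, or a
deletion of a boundary base that equals its left neighbour. Mid-codon
indels are *frame*-repaired (downstream codons translate correctly again)
but leave one substituted codon behind. The round-trip benchmark therefore
injects exactly-invertible indels at ~1 per 100 nt. Two further
localisability limits are respected: crossing a shift costs `f = 15` while
each matching codon regains ~4–5, so events within ~6 codons of a read end,
or two opposite-sign events within ~10 codons of each other (skipping both
is cheaper than two shifts), cannot be identified by any local aligner with
these scores; the generator keeps a 6-codon end margin and a 10-codon
spacing. General 5%-error reads are scored by edit-distance reduction, not
string equality.

**Improvement benchmark.** Annotation of raw 5%-error reads is compared
with annotation after the full workflow (mask → polish → frameshift
correction) on the same reads, against the generator's gold KO map. Gold
membership requires ≥ 30 complete in-frame codons of a gene inside the
read's source window — the genes an ideal annotator of the clean fragment
could detect. To keep both repair stages visible, only a random half of the
reads receives short-read support (30× error-free), emulating the uneven
short-read coverage of real metagenomes where many long reads are
unpolishable; the other half is repaired by frameshift correction alone.
Under these conditions precision roughly doubles (duplicate fragment calls
collapse) and recall rises; residual frameshift events after correction
drop to near zero.

## Numerical and edge-case conventions

- Phred+33 is the only quality encoding; lowercase bases are uppercased and
  non-ACGTN characters become `N` with a warning.
- Coordinates are 0-based half-open in memory; SAM positions convert at the
  boundary. Only M/I/D/S/H CIGAR ops are accepted; clips are trimmed.
- `align_frameshift` returns `None` for DNA shorter than one codon or when
  the best local score is below the threshold (always when ≤ 0).
- A forward shift at read position 0 has no previous base and is skipped
  with a warning.
- Pileup insertions before the first aligned column have no anchor and are
  ignored; two polish decisions can never conflict because `tau > 0.5`.
- RPKM requires a positive total; per-gene counts may not exceed it.
- `fit_slope` with two points returns the finite-difference slope with an
  undefined (None) standard error.
- The flux formula returns μmol per A-unit per hour directly because ppm is
  μmol/mol and P·V/(R·T) converts chamber volume to moles; incubation mode
  reuses the formula with A = soil mass (kg). No dilution correction is
  applied for repeated syringe sampling or N₂ flushing.

## Known limitations

- The corrector never iterates (one search → one set of edits); substitution
  errors are out of its scope by design (masking and polishing handle them).
- One KO call per ORF means a single ORF genuinely spanning two genes (not
  possible in the mock genomes, rare in real data) yields one call.
- The k-mer prescreen can in principle miss a true hit whose every 5-mer is
  disrupted; `prefilter=False` gives the exhaustive behaviour.
- Scoring defaults (BLOSUM62, 11/1, f=15, S_min=60) follow common translated
  -search practice; they are configurable and not fitted to any dataset.
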