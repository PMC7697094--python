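# Methods

## Model

A circRNA's backsplice junction is the ligation of a downstream exon's 3′
end to the 5′ start of the same or an upstream exon of the same gene, read
in transcript orientation. `mecirc` treats a single-end, stranded read as
evidence for a junction when the read splits into

* a **donor fragment** — a suffix of the read-leading part that matches a
  suffix of some exon *ending exactly at that exon's 3′ boundary*,
* an optional **insert** of 0 or 3–30 nt (the microexon candidate), and
* an **acceptor fragment** — the remainder of the read matching a prefix of
  a same-gene exon *starting exactly at its 5′ boundary*, with acceptor
  exon index ≤ donor exon index.

The boundary-pinning is what distinguishes a backsplice from an arbitrary
chimera; the index ordering excludes forward (linear) splices. Gaps of
1–2 nt fall below the microexon definition and are rejected rather than
absorbed into either fragment: counting them as inserts would inflate the
ME class, and merging them into a fragment would silently accept indels.
The whole read must be explained by the two fragments plus the gap; reads
running past the acceptor exon's end (into the next exon of the circle) are
not decomposed — a sensitivity, not a correctness, limitation.

### Detection algorithm

Exon sequences are stored in transcript orientation (minus-strand exons
reverse-complemented) and indexed by exact k-mers (default k = 12). Every
k-mer of a read is looked up; a posting at exon offset `o` for read
position `i` proposes a donor alignment when `i ≤ o` (fragment length
`p = i + exon_len − o`) or an acceptor alignment at read position `q = i −
o`. Candidates are verified by Hamming comparison against the exon sequence
with at most `max_mismatch` mismatches per fragment, and verified
donor/acceptor pairs of one gene with an admissible gap become hits. A
fragment is found iff it contains one error-free k-mer; for error-free
reads with `min_anchor ≥ k` this makes the search provably exhaustive
(the test suite checks exact set-equality against a brute-force
decomposition enumerator over 10,000 reads).

When a read admits several decompositions, the reported hit minimizes
(total mismatches, −anchored length, insert length), then (acceptor, donor,
gene) order; unresolved ties are flagged `ambiguous`.

### Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 12 nt | index seed; 4¹² ≈ 1.7×10⁷ keeps chance collisions rare at toy-genome scale |
| `min_anchor` | 18 nt | minimum exon overlap per fragment; in the spirit of chimeric-segment minima used by spliced aligners |
| `max_mismatch` | 1 per fragment | conservative for clean data; use 2 for libraries with ~1% substitution error |
| `min_insert`/`max_insert` | 3 / 30 nt | the microexon definition |
| `cpm_min`, `min_samples` | 0.01, 3 | CPM floor for low-count filtering |
| `min_reads`, `min_samples` | 2, 3 | unique-read floor for high-confidence calls |

### Merging and quantification

Junctions are keyed by (gene, acceptor exon, donor exon, insert sequence);
canonical and insert-bearing calls over the same exon pair are deliberately
separate records so cognate pairs (same backsplice, ± ME) stay visible.
Read counts collapse duplicate read *sequences* (PCR duplicates), falling
back to read ids when sequences are unavailable. Across samples, the count
matrix takes the union of junction keys with structural zeros; library size
defaults to the per-sample column sum when the caller does not supply total
read counts (logged, since a circRNA-only sum understates true library
size). CPM is `count / library_size × 10⁶`; both abundance filters keep a
row iff enough samples individually pass, which makes them idempotent and —
for the CPM filter — invariant under joint rescaling of counts and library
sizes.

### Microexon placement and motifs

Inserts ≥ 6 nt are placed by exact substring search over the host gene's
intron sequences on the gene strand — junction-adjacent introns first, then
all introns — choosing the occurrence closest to the nearer backsplice
exon; equidistant ties break toward the transcript-5′ exon and are flagged.
Exact matching is deliberate: with ≥ 6 nt queries, allowing mismatches
multiplies spurious placements faster than it rescues real ones, and the
observed GT–AG enrichment is itself the check on placement precision.
Inserts of 3–5 nt are reported but left UNPLACED (`too_short_to_place`):
queries that short match essentially everywhere. Whether a search over
whole gene bodies rather than introns would be preferable is genuinely
open; the intron-first policy is recorded in the output.

For a placed ME the two intronic nucleotides immediately transcript-5′ of
it should read AG (acceptor splice site) and the two immediately 3′ GT
(donor). The motif matrix counts bases at 10 positions per boundary (5 nt
intron + 5 nt ME on the acceptor side; 5 nt ME + 5 nt intron on the donor
side), in transcript orientation — the standard WebLogo-style summary,
exported as TSV rather than rendered.

Known-ME catalogues (BED6) are handled separately: a catalogued ME is
"expressed" when some read contains its sequence contiguously joined to at
least `min_anchor` nt of a flanking exon of the same gene (a stricter
`require_both` mode demands one read crossing ME and both flanking exons —
both conventions exist in practice, so both are implemented). Expressed MEs
overlapping a circRNA span on the same strand are classified junction_5p /
junction_3p when they coincide with the span's transcript-5′/3′ terminus,
body when strictly inside, and not called when they straddle a boundary.

### Negative controls

Shuffle moves each detected insert, unchanged, to the backsplice of a
uniformly drawn *different* junction, rebuilding the flanks from that
junction's exon sequences with the source read's fragment lengths (clipped
to the target exons). Scramble permutes each insert's bases in place
(inserts > 6 nt only, per the usual convention; identity permutations are
redrawn unless the insert is a homopolymer, which passes through flagged
`degenerate`). A control read is a false positive when re-detection
reproduces a member of the original call set — by full junction key in the
default, strictest mode, or by insert sequence alone in `sequence` mode.
Both generators are driven by a named, seeded generator recorded in the
report.

## The simulator, and what passing tests do and do not show

`simulate` builds one gene per contig (pad / exon / GT..AG intron / … /
pad), assembled in transcript orientation and mirrored onto the minus
strand for about half the genes. Defaults: 4–8 exons of 60–120 nt,
introns 150–400 nt, read length 100 nt, fragments ≥ 20 nt into each exon,
15–25 reads per junction, half of circRNAs carrying a 3–30 nt insert, 5%
residual linear-mRNA reads (RNase R digestion is efficient but not
perfect), substitution errors i.i.d. at a configurable rate (0 by
default). Planted microexons sit inside an intron adjacent to a backsplice
exon with canonical AG/GT context; placeable (≥ 6 nt) inserts are
rejection-sampled to occur exactly once among the host gene's introns so
that the true placement is identifiable — shorter inserts are never placed,
so uniqueness is neither required nor (for 3-mers) achievable. Junction
offsets are drawn without replacement where the feasible range allows, so
the manifest's expected unique-read counts are exact. All randomness flows
from one seed through split generator streams; every artifact (FASTA, GTF,
FASTQ, BED, manifest) is byte-reproducible.

The simulator emulates the *structure* of RNase-R-enriched circRNA-seq, not
its biology: uniform base composition, uniform junction offsets, no
quality-score-correlated errors, no indels, no paired ends, no repeat
structure or paralogy, one transcript per gene, and exon/intron sizes drawn
narrowly. Perfect recovery on simulated data therefore demonstrates
algorithmic correctness (the caller finds exactly what the decomposition
model defines, with exact counts and placements), not expected performance
on patient libraries, where alignment ambiguity, repeats and chemistry
artifacts dominate the error budget.

## Study sizes used by tests and the acceptance script

Oracle equivalence is checked over 10,000 error-free reads on a 5-gene
genome; recovery over 50 circRNAs × 20 reads; motif recovery over 2,000
planted microexons — sized so that the ± 0.05 background tolerance on
per-position base frequencies sits beyond 3.5 σ of binomial sampling noise
(at 500 sequences the band is only ~2.6 σ and fails by chance across the
~64 free matrix cells); controls over 10,000 ME-junction reads, where both
false-positive rates are ~0 because a shuffled insert lands on a
junction-insert combination that never existed and a scrambled insert no
longer matches any original key. The error-rate study (1% substitutions,
`max_mismatch=2`) checks junction-level recall ≥ 0.9 averaged over seeds,
the regime where at most one error falls in each fragment for most reads.

## Known limitations

* No paired-end bridging, no genome-wide spliced alignment, no recovery of
  reads extending past the acceptor exon into the circle's next exon.
* Placement is exact-match and intron-restricted; an insert arising from an
  unannotated exon or from another gene (trans) will be UNPLACED.
* Multi-transcript genes collapse to the longest transcript's exons, fixing
  one canonical exon numbering; isoform-specific numbering is out of scope.
* Negative-gap (overlapping-fragment) decompositions are rejected and
  counted, not modelled.
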