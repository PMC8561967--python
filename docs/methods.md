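# Methods

This note documents the models, parameter choices and numerical
conventions behind `capss`, and what the simulated benchmark does and
does not demonstrate about real data.

## Pooling model

A superpool is a `plate_grid_rows x plate_grid_cols` grid of plates with
`well_rows x well_cols` wells each. Row pool `i` collects well row
`i mod well_rows` of every plate in grid row `i div well_rows`; column
pools are symmetric. This makes `pools_for_well` /
`well_at_intersection` a closed-form bijection, tested exhaustively.
Plates are ordered row-major over the grid; whether a physical
experiment numbers its plates row- or column-major only relabels pools,
it does not change the algorithm. Well rows are lettered (A, B, ...)
and columns numbered from 1 only in reports and GFF3 labels; all
internal indices are 0-based, and all internal intervals are 0-based
half-open. The GFF3 writer is the single place where coordinates become
1-based inclusive, and the GFF3 reader converts straight back — asserted
by a round-trip test.

Pool index barcodes are codewords of a systematic [7,4,3] Hamming-type
code over GF(4) mapped to A/C/G/T: up to 255 barcodes with pairwise
Hamming distance ≥ 3, so demultiplexing can tolerate one substitution
per index without ambiguity. Demultiplexing is exact by default
(`max_mismatch=0`), matching common practice for 7-bp indices.

## Simulator

The generator produces, from one seed: a uniform-random genome at 46%
GC with `n_gaps` planted N-runs (the gap truth is exactly the set of
maximal N-runs, enforced by non-adjacent placement with non-N flanks), a
dispersed family of near-identical repeat copies (~1% divergence per
copy, HindIII-free so repeats cannot manufacture shared clone ends), a
plastid-like organelle sequence, a random host ("E. coli") sequence,
and a synthetic vector: two border flanks of 500 bp free of AAGCTT
around the cloning site, nominal 7 kb backbone.

Clones are placed one per well. An insert length is drawn from a normal
truncated to `[insert_min, insert_max]` and snapped to the nearest
feasible HindIII site pair, so every insert begins and ends with
`AAGCTT` (the site is palindromic, hence both trimmed ends read `AAGCTT`
in either cloning orientation — the orientation of insertion is drawn
uniformly). By default end sites are sampled without replacement
(`unique_ends`): no two clones share a directed end site, which is the
generic situation for a sparse sampling of a large genome. Desk-scale
genomes are the one place this is not automatic: a 500 kb random
sequence has one HindIII site per ~4.1 kb, too few for 96 clones with
192 distinct directed ends, so the generator can inject additional
sites at a configurable spacing (`site_spacing`, 1.2 kb in the toy
preset). This emulates the effective site density that partial
digestion of a real, ~1000x larger genome provides.

Reads are drawn per pool from the linearized clone molecule
`left_flank + insert + right_flank` (circularity is ignored: only the
two junctions matter, and both are preserved). Fragment lengths are
normal (`frag_mean` 450 bp, sd 50 — the Bioanalyzer scale of a typical
PE150 library), paired reads come off both fragment ends in random
order, substitution errors are injected at `error_rate` with a lowered
quality score at errored positions, and `host_fraction` of fragments
are drawn from the host sequence instead. The pool's 7-bp barcode is
prepended to read 1; the index itself is modelled error-free (a real
index read is a separate read with its own, low, error profile). Read
ids carry library, barcode, source molecule, fragment interval and
orientation, so provenance is fully recoverable — truth tables for
deconvolution and placement tests derive from them.

Not modelled: indels, position-dependent Illumina error profiles,
duplicates, chimeric fragments, cloning bias, pooling-volume noise.
Consequently the benchmark demonstrates correctness of the pipeline's
logic and its behaviour under substitution noise, host contamination,
repeats and gaps — not robustness to indel-rich or heavily biased real
libraries.

## Preprocessing

Quality filtering drops a pair when either mate is shorter than
`min_len` (100 bp) or has mean Phred quality below `min_mean_q` (20):
a deliberately minimal stand-in for read trimmers, since downstream
stages only require that obviously bad pairs are gone and that pairs
stay intact (junction detection uses mates). Host screening tests each
mate's 21-mers against a both-strand host k-mer set; a mate with ≥ 50%
of its k-mers in the set is host, and the pair is removed whole. Exact
21-mer containment separates host from insert reads sharply at any
realistic substitution rate, and the screen is idempotent.

## Short-BES pathway

A read qualifies as a junction read when (in either orientation) it
contains ≥ `min_vector_anchor` (20) terminal bases of a vector border
immediately followed by `AAGCTT`; 20 bp is ample to be unique in a 7 kb
vector. Because all junction reads of one clone end share the same
anchored start, clustering reduces to anchored prefix comparison
(identity ≥ 0.95 over ≥ 50 bp against the cluster's longest read).
Majority-vote consensus is called per column while ≥ `min_depth` (3)
reads cover it — depth 3 rejects singleton chimeras — and ties break to
the lexicographically smallest base. Mates of clustered reads then
extend the consensus by exact suffix-prefix overlap ≥ 30 bp, longest
extension first; this reproduces paired-read reach (end sequences on
the library-fragment scale) without a full assembler. Columns are
substitution-only; indel-aware consensus is out of scope.

## Long-BES pathway

The built-in assembler merges reads (both mates, both strands, sorted
lexicographically for determinism) by unambiguous suffix-prefix overlap:
a 40 bp exact prefix seed proposes candidates, the full overlap is
verified at ≥ 0.98 identity, contained reads are consumed, and the
longest verified extension is applied — unless another candidate
extension disagrees beyond the error tolerance (≥ 2 mismatches and
identity below threshold over the compared region), which stops the
contig. A single mismatch never triggers a stop, so sequencing errors
do not fragment contigs, while genuine branches — repeat boundaries and
the vector junction, where one flank continues into many inserts — do.
After each contig a containment sweep (three probe k-mers per
orientation) consumes reads whose seed fell on an embedded error, so
they cannot re-seed redundant copies of the same region. The assembler
is contractually adequate for simulated/desk-scale pools; production
contigs from a dedicated assembler are accepted per pool via
`extract-long --contigs`.

Junction contigs are trimmed on both sides (leading vector before the
anchored `AAGCTT`, and any trailing `AAGCTT` + opposite-flank entry when
a contig spans the whole insert, in which case one long BES per end is
emitted and flagged). Near-identical long BESs of one pool and end are
collapsed onto the longest (anchored identity ≥ 0.99), absorbing
redundant contigs.

## Deconvolution

Within one source (short/long) and one end (forward/reverse) — the four
flows are fully independent — a row-pool BES and a column-pool BES
"share" when their anchored prefixes agree at ≥ 0.99 identity over the
shorter sequence; each share maps to the intersection well. Under the
STRICT policy a BES whose shares imply more than one distinct well is
dropped entirely: that is the unresolvable pattern produced by more
than two overlapping clones split across pools, and dropping trades
recall for precision (the benchmark asserts zero wrong-well
assignments). Within a well, near-identical candidates merge onto the
longest; genuinely different candidates for one end are all kept and
marked AMBIGUOUS for the mapping stage to adjudicate. KEEP_ALL retains
everything for genome-based rescue instead.

## Genome anchoring

Alignment follows the stringent mapping contract: identity ≥ 0.99 over
query coverage ≥ 0.99, exact 21-mer seeds on both strands proposing
diagonals, every distinct diagonal verified ungapped over the full
query. The aligner is ungapped by design: upstream error is
substitution-only, so gapped extension adds no recall, and the ungapped
contract makes the hit set exactly reproducible by an exhaustive
sliding-window oracle — which the acceptance suite checks on hundreds
of random instances. Repeat masking (optional, off by default — the
high-stringency pipeline adopts unmasked alignment and lets culling and
uniqueness handle repeats) lowercases query bases covered only by
genome k-mers occurring more than `mask_max_freq` (4) times; masked
bases are excluded from seeding and from both sides of the identity
ratio, and queries with < 50 unmasked bases are not aligned.

Culling removes a hit when a strictly higher-scoring hit overlaps ≥ 50%
of its query interval — with full-query hits, any strictly better hit
dominates — so queries classify as single-hit (exactly one survivor) or
multi-hit (co-optimal survivors); only single-hit ends place clones. A
consequence worth noting: a BES from a *diverged* repeat copy still
places uniquely at its own copy (its score strictly dominates), while
only exactly-tied copies produce multi-hit.

Pairing applies the paired-placement rule: same chromosome, opposite
strands, facing inward (the + strand hit leftmost), span < 250 kb;
interval = [plus hit start, minus hit end). Failed pairs are counted by
reason (CHROM_CONFLICT, STRAND_CONFLICT, SPAN_EXCEEDED) and demoted to
a single-end placement when an end is individually unique, preferring
the forward end deterministically.

Integration merges per-well short and long placements. Agreement is
judged on the ends both placements anchor — same chromosome and strand,
junction coordinate (hit start on +, hit end on −) within 1 kb — so a
single-end placement agrees with the paired placement that contains it.
Among agreeing candidates the most informative wins (paired evidence
over single-end, then long-source coordinates). When placements
conflict, or one source offers several ambiguous candidates, sequence
cross-evidence decides: a candidate whose end sequence matches the
other source's assigned sequence for that end at ≥ 0.99 anchored
identity wins if it is the only validated one; otherwise the well is
dropped and counted (INTEGRATION_CONFLICT). Assigned-but-unplaced
sequences participate in this vote, which is what rescues a well whose
two long forward candidates are disambiguated by a short forward BES
that itself never mapped.

Organelle screening aligns every well BES against the organelle
sequences under the same 99/99 contract; wells with hits are called,
paired evidence is flagged, and a BES that also places on the nuclear
genome marks the call NUCLEAR_ALSO.

## Gap and coverage accounting

Gaps are maximal N-runs (`min_run` 1 by default; configurable because
some assemblies emit fixed-size gap runs). A gap is covered only when a
paired-placed clone interval strictly contains it — single-end
placements bound the insert on one side only, so they cannot certify a
spanning clone. Chromosome coverage is the interval union of paired
clone placements; insert statistics (mean, sd, histogram of paired
spans) are the in-silico analogue of a gel-based insert-size estimate,
and the report's depth accounting divides pool yield by the effective
clone size (insert estimate + vector backbone; 132 kb + 7 kb = 139 kb
at production defaults).

## Benchmark scale and runtime

The toy preset (96 wells, 500 kb genome, 5 kb inserts, 30x pools,
~115k read pairs) runs the full pipeline in well under a minute on one
CPU; the mini preset (12 wells, 120 kb genome) in a few seconds. These
sizes were chosen so that every property — placement rate ≥ 90%,
placement accuracy within ±2 bp, zero wrong-well assignments, oracle
equivalence — is exercised end to end with comfortable statistical
margins while the whole suite stays interactive.

## Known limitations

* The in-house assembler and aligner target the simulator's error model;
  production data should use external contigs (`--contigs`) and may need
  gapped alignment, which the contract deliberately excludes.
* The STRICT policy discards all BESs implicated in multi-well sharing;
  the rectification of exactly-two overlapping clones by cross-axis
  bookkeeping is not implemented.
* One clone per well is assumed throughout (no double picks).
* Organelle calls are reported, not subtracted from pool depth
  accounting.
* `insert_stats` reports the placed-clone span distribution, which is
  censored at `max_span` by construction.
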