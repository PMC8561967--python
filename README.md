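# capss

**BAC end sequence profiling and genome anchoring from clone-array pooled
shotgun sequencing.**

Bacterial artificial chromosome (BAC) libraries carry 50–300 kb genomic
inserts, arrayed one clone per well of 384-well plates. They remain a key
physical resource for gap filling, FISH probes and region cloning — but
only once each clone is *anchored*: its two end sequences (BESs) located
on the reference genome. Sanger-sequencing ends clone by clone is slow
and expensive; `capss` implements the pooled alternative.

## The method

Plates are arranged in a 2-D grid (the shipped production design: 24
plates in a 6 × 4 grid of 16 × 24 wells). Pooling each physical plate row
across the grid gives 96 *row pools*; pooling each column gives 96
*column pools* — 192 secondary pools of 96 clones each covering 9216
wells. Each secondary pool is shotgun-sequenced with a 7-bp library
index (row pools mixed as library X, column pools as library Y). Because
every well is the unique intersection of one row pool and one column
pool, an end sequence observed in exactly one pool of each axis
identifies its well — clone-array pooled shotgun sequencing (CAPSS).

End sequences are recovered in two independent pathways:

* **short BESs** — reads spanning a vector border into the insert are
  clustered per pool and per end on their shared HindIII-anchored
  prefixes; a majority-vote consensus, extended by the clustered reads'
  mates, gives a fragment-scale end sequence starting exactly at the
  cloning site (`AAGCTT`);
* **long BESs** — each pool's reads are assembled into contigs
  (built-in greedy overlap merger, or externally assembled contigs);
  contigs running through a vector border are trimmed to the insert side
  of the junction, giving kilobase-scale end sequences.

Well-assigned BESs are anchored on the genome under a stringent
blastn-style contract (identity ≥ 99% over ≥ 99% of the query, culled to
the best placement, single-hit required). A clone is *paired-placed*
when its forward and reverse ends land on one chromosome, on opposite
strands facing inward, spanning < 250 kb (three GFF3 lines); a uniquely
mapped lone end gives a single-end placement (two lines). Short- and
long-source placements are then integrated, using sequence agreement
between the two pathways to break ties. Finally the package reports
per-chromosome clone coverage, assembly-gap coverage (a gap — a maximal
N-run — counts as covered when strictly contained in a paired clone
interval) and the in-silico insert-size distribution.

A full simulator generates the entire study: genome with gaps and
repeats, HindIII-constrained clone array, vector, indexed pooled reads
with substitution errors, E. coli contamination and organelle (plastid)
contamination — with truth tables for every stage, so the whole pipeline
is verifiable against known answers without any external data.

## Worked example

The `toy` preset is the self-contained benchmark: a 2 × 2 plate grid of
4 × 6 wells (96 clones; 8 row pools, 12 column pools), a 500 kb
two-chromosome genome with 6 gaps and a planted repeat family, 5 kb mean
inserts, 30× pool depth, PE150 reads with 0.1% substitution error, 10%
host contamination and 2% plastid contamination:

```bash
capss all --preset toy --seed 1 --outdir demo/
```

prints (abridged):

```
n_wells                 96
n_secondary_pools       20
read_pairs_raw          114783
read_pairs_valid        103022
n_short_bes             384
n_long_bes              390
wells_with_short_pair   96
clones_placed           94
clones_placed_paired    94
organelle_wells         2
wells_resolved          96
n_gaps                  6
n_gaps_covered          6
insert_mean_bp          4986.7
```

Reading this: host screening removed ~10% of pairs (the planted
contamination); every well received a short forward and reverse BES; 94
of 96 wells were anchored on the nuclear genome — all by paired ends —
and the two remaining wells are the planted plastid clones, recovered by
the organelle screen (`organelle_calls.tsv`). All six assembly gaps are
strictly spanned by placed clones, and the recovered insert-size mean
(4.99 kb) matches the simulated 5 kb target. `demo/clones.gff3` holds
the sorted three-line/two-line clone features ready for a genome
browser; `assignments.tsv`, `pool_accounting.tsv` and
`coverage_report.tsv` mirror the per-pool and per-chromosome accounting.

The stage subcommands (`simulate`, `demux`, `extract-short`,
`extract-long`, `assign`, `map`, `gaps`) run the same pipeline through
plain-text files in one directory and compose to exactly the same
output; `capss extract-long --contigs <fasta>` accepts externally
assembled pool contigs for production-scale data.

## Layout

```
src/capss/
  pool_design.py   superpool geometry, well/pool bijection, index barcodes
  simulate.py      synthetic genome / clone array / pooled-read generator
  preprocess.py    demultiplexing, quality filter, host k-mer screen
  bes_short.py     junction reads -> consensus -> short BESs
  bes_long.py      greedy pool assembly -> long BESs, N50
  assign.py        CAPSS row x column deconvolution, conflict policies
  genmap.py        seed-and-verify alignment, pairing, integration, GFF3
  gapstats.py      gap detection, gap/chromosome coverage, insert stats
  config.py        validated run configuration and presets
  pipeline.py      stage orchestration and artifact writing
  cli.py           the `capss` command
docs/methods.md    model, parameters and design notes
```
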