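"""Synthetic data generator for the whole pipeline.

Emulates the experimental system end to end with known truth: a nuclear
genome with assembly gaps (N-runs) and dispersed near-identical repeats,
a HindIII partial-digest BAC clone set arrayed one clone per well of a
plate-grid superpool, and indexed pooled paired-end shotgun reads of the
row-pool and column-pool libraries, with configurable substitution error,
E. coli carry-over and organelle contamination.

The generator is the ground-truth oracle for every downstream stage:
clone intervals, expected end sequences, per-pool read provenance and gap
positions are all recorded in :class:`TruthTables`.

What it deliberately does not model: indels and realistic Illumina error
profiles (substitutions only), optical duplicates, chimeric fragments,
cloning bias, and uneven pooling volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .io import ReadPair
from .pool_design import Axis, PoolRef, SuperpoolLayout, WellAddress, member_wells
from .seq import HINDIII, find_all, random_dna, revcomp


class CloneSource(str, Enum):
    NUCLEAR = "NUCLEAR"
    CHLOROPLAST = "CHLOROPLAST"
    HOST = "HOST"


@dataclass
class SyntheticGenome:
    """A genome with known gap (N-run) and planted-repeat truth."""

    sequences: dict[str, str]
    gap_truth: list[tuple[str, int, int]]
    repeat_truth: list[tuple[str, int, int]]


@dataclass(frozen=True)
class VectorModel:
    """The cloning vector as seen by sequencing: the two border sequences
    flanking the HindIII cloning site, plus the nominal backbone size used
    for depth accounting.  Flanks must not contain the HindIII site so the
    vector-insert junction is unambiguous."""

    left_flank: str
    right_flank: str
    backbone_length: int = 7000
    name: str = "synthetic-pIndigoBAC536S-like"

    def __post_init__(self):
        if len(self.left_flank) < 100 or len(self.right_flank) < 100:
            raise ValueError("vector flanks must be at least 100 bp")
        if HINDIII in self.left_flank or HINDIII in self.right_flank:
            raise ValueError("vector flanks must not contain the HindIII site")


@dataclass(frozen=True)
class CloneTruth:
    """Ground truth for one arrayed clone: its well and its insert interval.

    ``start``/``end`` are 0-based half-open on the source sequence; for
    nuclear and organelle clones both terminal hexamers of the interval
    are HindIII sites (the site is palindromic, so the trimmed end reads
    AAGCTT in either cloning orientation).
    """

    clone_id: str
    well: WellAddress
    chrom: str
    start: int
    end: int
    strand: str
    source: CloneSource = CloneSource.NUCLEAR


@dataclass
class TruthTables:
    """Everything downstream recovery tests compare against."""

    clones: list[CloneTruth]
    expected_bes: dict[str, tuple[str, str]]  # clone_id -> (forward, reverse)
    per_pool_fragments: dict[PoolRef, int] = field(default_factory=dict)


@dataclass
class PooledReadSets:
    """Simulated indexed reads: library X pools the rows, library Y the columns."""

    reads: dict[str, list[ReadPair]]
    per_pool_fragments: dict[PoolRef, int]


class PackingError(RuntimeError):
    """Raised when gaps, repeats or clones cannot be placed without overlap."""


def default_vector(flank_len: int = 500, seed: int = 7) -> VectorModel:
    """A reproducible synthetic vector: random border sequences free of AAGCTT."""
    rng = np.random.default_rng(seed)
    flanks = []
    while len(flanks) < 2:
        cand = random_dna(rng, flank_len, gc=0.5)
        if HINDIII not in cand:
            flanks.append(cand)
    return VectorModel(left_flank=flanks[0], right_flank=flanks[1])


def _place_intervals(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n: int,
    length: int,
    reserved: list[tuple[str, int, int]],
    margin: int = 2,
    max_tries: int = 10000,
) -> list[tuple[str, int, int]]:
    """Place n non-overlapping intervals uniformly, avoiding reserved ones."""
    names = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in names], dtype=float)
    weights /= weights.sum()
    placed: list[tuple[str, int, int]] = []
    for _ in range(n):
        for _try in range(max_tries):
            chrom = names[rng.choice(len(names), p=weights)]
            lo, hi = margin, chrom_lengths[chrom] - length - margin
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            cand = (chrom, start, start + length)
            busy = reserved + placed
            if any(
                c == chrom and start < e + margin and start + length > s - margin
                for c, s, e in busy
            ):
                continue
            placed.append(cand)
            break
        else:
            raise PackingError(
                f"could not place interval {len(placed) + 1}/{n} of length {length}"
            )
    return placed


def simulate_genome(
    n_chrom: int = 2,
    chrom_length: int = 250_000,
    n_gaps: int = 6,
    gap_length: int = 400,
    repeat_unit_length: int = 0,
    repeat_copies: int = 0,
    gc: float = 0.46,
    seed: int = 0,
    site_spacing: int | None = None,
    repeat_divergence: float = 0.01,
) -> SyntheticGenome:
    """Generate a genome with known gaps and planted repeats.

    ``n_gaps`` maximal N-runs of ``gap_length`` are distributed over the
    chromosomes with non-N flanks, so ``gap_truth`` is exactly the set of
    maximal N-runs.  ``repeat_copies`` near-identical copies (pairwise
    divergence ~``repeat_divergence``) of one random ``repeat_unit_length``
    unit are dispersed to exercise multi-hit classification; the unit is
    kept free of HindIII sites so planted repeats cannot manufacture
    shared clone ends.  ``site_spacing``, when set, injects additional
    HindIII sites at roughly that spacing: small test genomes need a
    denser site lattice than random sequence provides before they can host
    one distinct-ended clone per well.
    """
    if n_chrom < 1 or chrom_length < 1000:
        raise ValueError("need at least one chromosome of >= 1 kb")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    seqs = {name: bytearray(random_dna(rng, chrom_length, gc).encode()) for name in names}
    lengths = {name: chrom_length for name in names}

    repeat_truth: list[tuple[str, int, int]] = []
    if repeat_unit_length and repeat_copies:
        unit = random_dna(rng, repeat_unit_length, gc)
        while HINDIII in unit:
            unit = random_dna(rng, repeat_unit_length, gc)
        sites = _place_intervals(rng, lengths, repeat_copies, repeat_unit_length, [])
        for chrom, start, end in sites:
            copy = bytearray(unit.encode())
            n_mut = rng.binomial(repeat_unit_length, repeat_divergence)
            for pos in rng.choice(repeat_unit_length, size=n_mut, replace=False):
                copy[pos] = ord("ACGT"[rng.integers(4)])
            seqs[chrom][start:end] = copy
            repeat_truth.append((chrom, start, end))

    if site_spacing:
        site = HINDIII.encode()
        for name in names:
            pos = int(site_spacing * rng.uniform(0.5, 1.5))
            while pos + 6 < chrom_length - 2:
                if not any(
                    c == name and pos < e and pos + 6 > s for c, s, e in repeat_truth
                ):
                    seqs[name][pos : pos + 6] = site
                pos += int(site_spacing * rng.uniform(0.5, 1.5))

    gap_truth = _place_intervals(rng, lengths, n_gaps, gap_length, repeat_truth)
    for chrom, start, end in gap_truth:
        seqs[chrom][start:end] = b"N" * (end - start)
    gap_truth.sort()
    repeat_truth.sort()
    return SyntheticGenome(
        sequences={name: bytes(seqs[name]).decode() for name in names},
        gap_truth=gap_truth,
        repeat_truth=repeat_truth,
    )


def hindiii_sites(seq: str) -> list[int]:
    """Start positions of every AAGCTT occurrence."""
    return find_all(seq, HINDIII)


def clone_insert_seq(clone: CloneTruth, sequences: dict[str, str]) -> str:
    """The cloned insert in its own orientation (starts and ends with AAGCTT)."""
    s = sequences[clone.chrom][clone.start : clone.end]
    return revcomp(s) if clone.strand == "-" else s


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise PackingError("truncated normal rejection sampling failed")


def place_clones(
    genome: SyntheticGenome,
    layout: SuperpoolLayout,
    insert_mean: float,
    insert_sd: float,
    insert_min: float,
    insert_max: float,
    organelle_fraction: float = 0.0,
    organelle_genome: dict[str, str] | None = None,
    seed: int = 0,
    unique_ends: bool = True,
    max_retries: int = 500,
) -> list[CloneTruth]:
    """Array one clone per well, with HindIII-constrained insert boundaries.

    Each nuclear insert runs from the start of one AAGCTT occurrence to
    the end of another: a target length is drawn from a normal truncated
    to [insert_min, insert_max] and then snapped to the nearest feasible
    site pair.  With ``unique_ends`` (the default) no two clones share a
    directed end site, mimicking the generic case where clone ends give
    distinct end sequences; ``organelle_fraction`` of wells instead
    receive an insert from the organelle genome (contaminating plastid
    DNA surviving nuclei isolation).
    """
    if organelle_fraction > 0 and not organelle_genome:
        raise ValueError("organelle_fraction > 0 requires an organelle genome")
    rng = np.random.default_rng(seed)
    sources = dict(genome.sequences)
    organelle_names: set[str] = set()
    if organelle_genome:
        sources.update(organelle_genome)
        organelle_names = set(organelle_genome)

    site_map = {name: np.array(hindiii_sites(seq)) for name, seq in sources.items()}
    for name, sites in site_map.items():
        if name not in organelle_names and len(sites) < 2:
            raise PackingError(f"{name} has fewer than two HindIII sites")

    wells = list(layout.iter_wells())
    n_org = int(round(organelle_fraction * len(wells)))
    org_wells = set(
        rng.choice(len(wells), size=n_org, replace=False).tolist()
    ) if n_org else set()

    nuc_names = sorted(genome.sequences)
    nuc_weights = np.array([len(genome.sequences[c]) for c in nuc_names], dtype=float)
    nuc_weights /= nuc_weights.sum()
    org_names = sorted(organelle_names)

    used_starts: set[tuple[str, int]] = set()
    used_ends: set[tuple[str, int]] = set()
    clones: list[CloneTruth] = []
    for wi, well in enumerate(wells):
        is_org = wi in org_wells
        placed = None
        for _ in range(max_retries):
            if is_org:
                chrom = org_names[int(rng.integers(len(org_names)))]
            else:
                chrom = nuc_names[int(rng.choice(len(nuc_names), p=nuc_weights))]
            sites = site_map[chrom]
            target = _truncated_normal(rng, insert_mean, insert_sd, insert_min, insert_max)
            si = int(rng.integers(len(sites)))
            s = int(sites[si])
            if unique_ends and (chrom, s) in used_starts:
                continue
            # candidate end sites: insert spans [s, e) with e = site + 6
            lo = np.searchsorted(sites, s + insert_min - 6)
            hi = np.searchsorted(sites, s + insert_max - 6, side="right")
            cands = sites[lo:hi]
            if unique_ends:
                cands = np.array(
                    [p for p in cands if (chrom, int(p)) not in used_ends and p != s]
                )
            if len(cands) == 0:
                continue
            best = int(cands[np.argmin(np.abs(cands + 6 - s - target))])
            placed = (chrom, s, best + 6)
            break
        if placed is None:
            raise PackingError(f"no feasible HindIII site pair for well {well}")
        chrom, s, e = placed
        used_starts.add((chrom, s))
        used_ends.add((chrom, e - 6))
        clones.append(
            CloneTruth(
                clone_id=f"bac-{layout.well_label(well)}",
                well=well,
                chrom=chrom,
                start=s,
                end=e,
                strand="+" if rng.integers(2) else "-",
                source=CloneSource.CHLOROPLAST if is_org else CloneSource.NUCLEAR,
            )
        )
    return clones


def build_truth_tables(
    clones: list[CloneTruth],
    sequences: dict[str, str],
    bes_len: int = 1000,
    per_pool_fragments: dict[PoolRef, int] | None = None,
) -> TruthTables:
    """Expected forward/reverse end sequences: the terminal ``bes_len`` bp of
    each insert end, the reverse end reverse-complemented, both starting
    with AAGCTT."""
    expected: dict[str, tuple[str, str]] = {}
    for clone in clones:
        ins = clone_insert_seq(clone, sequences)
        expected[clone.clone_id] = (ins[:bes_len], revcomp(ins)[:bes_len])
    return TruthTables(
        clones=list(clones),
        expected_bes=expected,
        per_pool_fragments=dict(per_pool_fragments or {}),
    )


def _apply_errors(
    rng: np.random.Generator, seq: str, rate: float, hi_q: str = "I", lo_q: str = "+"
) -> tuple[str, str]:
    """Substitution errors at the given per-base rate; errored bases are
    flagged with a lower quality score so quality filtering has signal."""
    n = len(seq)
    qual = hi_q * n
    if rate <= 0:
        return seq, qual
    k = rng.binomial(n, rate)
    if k == 0:
        return seq, qual
    positions = rng.choice(n, size=k, replace=False)
    s = bytearray(seq.encode())
    q = bytearray(qual.encode())
    for pos in positions:
        old = chr(s[pos])
        alts = [b for b in "ACGT" if b != old]
        s[pos] = ord(alts[int(rng.integers(3))])
        q[pos] = ord(lo_q)
    return s.decode(), q.decode()


def simulate_pool_reads(
    sequences: dict[str, str],
    clones: list[CloneTruth],
    layout: SuperpoolLayout,
    vector: VectorModel,
    index_table: dict[PoolRef, str],
    read_len: int = 150,
    frag_mean: int = 450,
    frag_sd: int = 50,
    depth_per_pool: float = 30.0,
    error_rate: float = 0.001,
    host_fraction: float = 0.0,
    host_genome: str | None = None,
    seed: int = 0,
) -> PooledReadSets:
    """Indexed paired-end reads for every secondary pool.

    Each pool's fragments are drawn from the clone molecules (left vector
    flank + insert + right flank, treated as linear) of its member wells
    until the target per-pool read depth is reached; ``host_fraction`` of
    fragments come from the host genome instead.  The 7-bp pool barcode
    is prepended to read 1 (the index read is modelled as error free);
    read ids record library, barcode, source molecule, fragment interval
    and sequencing direction, so every read's provenance is recoverable.

    Row pools form library X, column pools library Y.  All randomness
    derives from ``seed``; a fixed seed yields byte-identical reads.
    """
    barcodes = list(index_table.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate index barcodes in index table")
    if read_len > frag_mean:
        raise ValueError("read length must not exceed the mean fragment size")
    by_well = {c.well: c for c in clones}
    molecules: dict[str, str] = {
        c.clone_id: vector.left_flank + clone_insert_seq(c, sequences) + vector.right_flank
        for c in clones
    }
    if host_fraction > 0 and not host_genome:
        raise ValueError("host_fraction > 0 requires a host genome")

    reads: dict[str, list[ReadPair]] = {"X": [], "Y": []}
    per_pool: dict[PoolRef, int] = {}
    for serial, pool in enumerate(layout.iter_pools()):
        rng = np.random.default_rng([seed, serial])
        lib = "X" if pool.axis is Axis.ROW else "Y"
        barcode = index_table[pool]
        members = [by_well[w] for w in member_wells(layout, pool) if w in by_well]
        mol_ids = [c.clone_id for c in members]
        mol_lens = np.array([len(molecules[m]) for m in mol_ids], dtype=float)
        total_len = mol_lens.sum()
        n_frag = int(round(depth_per_pool * total_len / (2 * read_len)))
        per_pool[pool] = n_frag
        weights = mol_lens / total_len
        which = rng.choice(len(mol_ids), size=n_frag, p=weights)
        frag_lens = rng.normal(frag_mean, frag_sd, size=n_frag).round().astype(int)
        frag_lens = np.clip(frag_lens, read_len, None)
        is_host = (
            rng.random(n_frag) < host_fraction
            if host_fraction > 0
            else np.zeros(n_frag, dtype=bool)
        )
        flips = rng.integers(2, size=n_frag)
        bc_qual = "I" * len(barcode)
        out = reads[lib]
        for i in range(n_frag):
            if is_host[i]:
                src_id, src = "host", host_genome
            else:
                src_id = mol_ids[which[i]]
                src = molecules[src_id]
            fl = min(int(frag_lens[i]), len(src))
            st = int(rng.integers(0, len(src) - fl + 1))
            frag = src[st : st + fl]
            r1, r2 = frag[:read_len], revcomp(frag[-read_len:])
            if flips[i]:
                r1, r2 = r2, r1
            r1, q1 = _apply_errors(rng, r1, error_rate)
            r2, q2 = _apply_errors(rng, r2, error_rate)
            rid = f"{lib}:{barcode}:{src_id}:{st}:{st + fl}:{'R' if flips[i] else 'F'}:{i}"
            out.append(ReadPair(rid, barcode + r1, bc_qual + q1, r2, q2))
    return PooledReadSets(reads=reads, per_pool_fragments=per_pool)
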