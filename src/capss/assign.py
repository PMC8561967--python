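"""CAPSS deconvolution: intersecting row-pool and column-pool end sequences.

An end sequence present in exactly one row pool and one column pool
belongs to the clone at the intersection well.  Overlapping clones break
this: the same end sequence seen in several pools of one axis implies
several candidate wells and cannot be resolved from pooling alone, so
under the default STRICT policy such sequences are filtered out (at the
cost of leaving their wells empty).  The forward-end and reverse-end
flows never interact; a well may end up with several distinct candidate
sequences for one end, which are all kept but flagged ambiguous for the
genome-mapping stage to adjudicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .bes_short import End, ShortBes
from .bes_long import LongBes
from .pool_design import Axis, SuperpoolLayout, WellAddress, well_at_intersection
from .seq import HINDIII, anchored_identity


class Source(str, Enum):
    SHORT = "SHORT"
    LONG = "LONG"
    INTEGRATED = "INTEGRATED"


class Status(str, Enum):
    UNIQUE = "UNIQUE"
    AMBIGUOUS = "AMBIGUOUS"


class Policy(str, Enum):
    STRICT = "STRICT"
    KEEP_ALL = "KEEP_ALL"


@dataclass
class WellBes:
    """An end sequence deconvolved to a single well."""

    well: WellAddress
    end: End
    source: Source
    seq: str
    status: Status
    bes_id: str

    def __post_init__(self):
        if not self.seq.startswith(HINDIII):
            raise ValueError("well-assigned BES must start with the HindIII site")


@dataclass
class Match:
    """A row-pool BES and a column-pool BES sharing one sequence."""

    row_index: int
    col_index: int
    well: WellAddress
    row_seq: str
    col_seq: str


@dataclass
class AssignmentStats:
    wells_with_forward: int = 0
    wells_with_reverse: int = 0
    wells_with_pair: int = 0
    wells_with_single: int = 0
    wells_empty: int = 0


PoolBes = ShortBes | LongBes


def match_pools(
    row_bes_list: list[PoolBes],
    col_bes_list: list[PoolBes],
    layout: SuperpoolLayout,
    min_identity: float = 0.99,
    min_cov: float = 0.9,
) -> list[Match]:
    """All (row BES, col BES) pairs sharing a sequence, mapped to wells.

    Both lists must carry the same end.  Because every BES starts at the
    HindIII junction, "shared" reduces to anchored comparison: the two
    sequences must agree at ``min_identity`` over the compared region,
    which must cover at least ``min_cov`` of the shorter sequence (the
    anchored comparison spans the full shorter sequence, so the coverage
    requirement only bites for degenerate inputs).
    """
    ends = {b.end for b in row_bes_list} | {b.end for b in col_bes_list}
    if len(ends) > 1:
        raise ValueError("match_pools compares one end at a time")
    for b in row_bes_list:
        if b.pool.axis is not Axis.ROW:
            raise ValueError("row_bes_list contains a non-ROW pool BES")
    for b in col_bes_list:
        if b.pool.axis is not Axis.COL:
            raise ValueError("col_bes_list contains a non-COL pool BES")
    out: list[Match] = []
    for i, rb in enumerate(row_bes_list):
        for j, cb in enumerate(col_bes_list):
            shorter = min(len(rb.seq), len(cb.seq))
            # the anchored comparison spans min(len) bases, i.e. 100% of the
            # shorter sequence; min_cov expresses the minimum such span
            if shorter < max(len(HINDIII), min_cov * shorter):
                continue
            if anchored_identity(rb.seq, cb.seq) >= min_identity:
                out.append(
                    Match(
                        row_index=i,
                        col_index=j,
                        well=well_at_intersection(layout, rb.pool, cb.pool),
                        row_seq=rb.seq,
                        col_seq=cb.seq,
                    )
                )
    return out


def resolve_conflicts(
    matches: list[Match],
    end: End,
    source: Source,
    policy: Policy | str = Policy.STRICT,
    max_wells_per_bes: int = 1,
    merge_identity: float = 0.99,
) -> tuple[dict[WellAddress, list[WellBes]], int]:
    """Turn pool-sharing matches into per-well assignments under a policy.

    STRICT drops every pool BES whose matches imply more than
    ``max_wells_per_bes`` distinct wells (the unresolvable overlapping-
    clone pattern); KEEP_ALL retains everything for downstream
    genome-based rescue.  Within a well, near-identical candidates are
    merged onto the longest; genuinely different candidates for the same
    end are all kept and marked AMBIGUOUS.  Returns the assignments and
    the number of matches filtered out.
    """
    policy = Policy(policy)
    n_filtered = 0
    kept = matches
    if policy is Policy.STRICT:
        row_wells: dict[int, set[WellAddress]] = {}
        col_wells: dict[int, set[WellAddress]] = {}
        for m in matches:
            row_wells.setdefault(m.row_index, set()).add(m.well)
            col_wells.setdefault(m.col_index, set()).add(m.well)
        bad_rows = {i for i, ws in row_wells.items() if len(ws) > max_wells_per_bes}
        bad_cols = {j for j, ws in col_wells.items() if len(ws) > max_wells_per_bes}
        kept = [
            m for m in matches if m.row_index not in bad_rows and m.col_index not in bad_cols
        ]
        n_filtered = len(matches) - len(kept)

    by_well: dict[WellAddress, list[str]] = {}
    for m in kept:
        seq = m.row_seq if len(m.row_seq) >= len(m.col_seq) else m.col_seq
        cands = by_well.setdefault(m.well, [])
        for idx, existing in enumerate(cands):
            if anchored_identity(existing, seq) >= merge_identity:
                if len(seq) > len(existing):
                    cands[idx] = seq
                break
        else:
            cands.append(seq)

    out: dict[WellAddress, list[WellBes]] = {}
    for well in sorted(by_well):
        cands = by_well[well]
        status = Status.UNIQUE if len(cands) == 1 else Status.AMBIGUOUS
        out[well] = [
            WellBes(
                well=well,
                end=end,
                source=source,
                seq=seq,
                status=status,
                bes_id=f"{source.value[0]}{end.value[0]}.{len(out):05d}.{k}",
            )
            for k, seq in enumerate(sorted(cands, key=lambda s: (-len(s), s)))
        ]
    return out, n_filtered


def merge_assignments(
    per_flow: list[dict[WellAddress, list[WellBes]]],
) -> dict[WellAddress, list[WellBes]]:
    """Union the independent per-(end, source) assignment flows by well."""
    out: dict[WellAddress, list[WellBes]] = {}
    for flow in per_flow:
        for well, items in flow.items():
            out.setdefault(well, []).extend(items)
    return {w: out[w] for w in sorted(out)}


def assignment_stats(
    assignments: dict[WellAddress, list[WellBes]],
    layout: SuperpoolLayout,
    source: Source | None = None,
) -> AssignmentStats:
    """Well-level accounting: forward/reverse/pair/single-end/empty counts."""
    stats = AssignmentStats()
    n_assigned = 0
    for items in assignments.values():
        if source is not None:
            items = [b for b in items if b.source is source]
        if not items:
            continue
        n_assigned += 1
        has_f = any(b.end is End.FORWARD for b in items)
        has_r = any(b.end is End.REVERSE for b in items)
        stats.wells_with_forward += has_f
        stats.wells_with_reverse += has_r
        stats.wells_with_pair += has_f and has_r
        stats.wells_with_single += has_f != has_r
    stats.wells_empty = layout.n_wells - n_assigned
    return stats
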