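"""Clone-array superpool geometry.

A superpool arranges 384-well plates in a rectangular grid (the shipped
default is the 24-plate, 6 x 4 configuration).  Pooling every physical
plate row across the grid gives the row pools, pooling every physical
column gives the column pools; together these are the secondary pools.
Each well then lies at the intersection of exactly one row pool and one
column pool, which is what lets a sequence observed in one pool of each
axis be deconvolved back to a single well.

Internally everything is 0-based arithmetic; human-readable labels such
as ``32G16`` (plate 32, well row G, well column 16) exist only at the
presentation layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Sequence


class Axis(str, Enum):
    ROW = "ROW"
    COL = "COL"


@dataclass(frozen=True, order=True)
class WellAddress:
    """A single well: plate index into the layout's plate list plus well row/col."""

    plate_index: int
    row: int
    col: int


@dataclass(frozen=True, order=True)
class PoolRef:
    """A secondary pool: its axis (ROW or COL) and its 0-based index on that axis."""

    axis: Axis
    index: int


@dataclass(frozen=True)
class SuperpoolLayout:
    """Geometry of a plate-grid superpool.

    ``plate_ids`` is row-major over the plate grid: the plate at grid row
    ``g_r`` and grid column ``g_c`` is ``plate_ids[g_r * plate_grid_cols + g_c]``.
    """

    plate_grid_rows: int
    plate_grid_cols: int
    well_rows: int
    well_cols: int
    plate_ids: tuple[str, ...]

    @property
    def n_plates(self) -> int:
        return self.plate_grid_rows * self.plate_grid_cols

    @property
    def n_row_pools(self) -> int:
        return self.plate_grid_rows * self.well_rows

    @property
    def n_col_pools(self) -> int:
        return self.plate_grid_cols * self.well_cols

    @property
    def n_secondary_pools(self) -> int:
        return self.n_row_pools + self.n_col_pools

    @property
    def n_wells(self) -> int:
        return self.n_plates * self.well_rows * self.well_cols

    def plate_grid_position(self, plate_index: int) -> tuple[int, int]:
        """(grid_row, grid_col) of a plate, row-major over ``plate_ids``."""
        if not 0 <= plate_index < self.n_plates:
            raise ValueError(f"plate_index {plate_index} out of range")
        return divmod(plate_index, self.plate_grid_cols)

    def iter_wells(self) -> Iterator[WellAddress]:
        for p in range(self.n_plates):
            for r in range(self.well_rows):
                for c in range(self.well_cols):
                    yield WellAddress(p, r, c)

    def iter_pools(self) -> Iterator[PoolRef]:
        for i in range(self.n_row_pools):
            yield PoolRef(Axis.ROW, i)
        for i in range(self.n_col_pools):
            yield PoolRef(Axis.COL, i)

    def validate_well(self, well: WellAddress) -> None:
        if not (
            0 <= well.plate_index < self.n_plates
            and 0 <= well.row < self.well_rows
            and 0 <= well.col < self.well_cols
        ):
            raise ValueError(f"well {well} out of range for layout")

    def validate_pool(self, pool: PoolRef) -> None:
        n = self.n_row_pools if pool.axis is Axis.ROW else self.n_col_pools
        if not 0 <= pool.index < n:
            raise ValueError(f"pool {pool} out of range for layout")

    def well_label(self, well: WellAddress) -> str:
        """Human label like ``32G16``: plate id, well-row letter, 1-based column."""
        self.validate_well(well)
        letters = ""
        r = well.row
        while True:
            letters = chr(ord("A") + r % 26) + letters
            r = r // 26 - 1
            if r < 0:
                break
        return f"{self.plate_ids[well.plate_index]}{letters}{well.col + 1:02d}"


def build_layout(
    plate_grid_rows: int,
    plate_grid_cols: int,
    well_rows: int,
    well_cols: int,
    plate_ids: Sequence[str] | None = None,
) -> SuperpoolLayout:
    """Build a superpool layout, deriving pool counts from the grid dimensions.

    When ``plate_ids`` is omitted, plates are labelled "01", "02", ... in
    row-major grid order.
    """
    for name, v in (
        ("plate_grid_rows", plate_grid_rows),
        ("plate_grid_cols", plate_grid_cols),
        ("well_rows", well_rows),
        ("well_cols", well_cols),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    n_plates = plate_grid_rows * plate_grid_cols
    if plate_ids is None:
        plate_ids = [f"{i + 1:02d}" for i in range(n_plates)]
    if len(plate_ids) != n_plates:
        raise ValueError(
            f"expected {n_plates} plate ids for a "
            f"{plate_grid_rows}x{plate_grid_cols} grid, got {len(plate_ids)}"
        )
    if len(set(plate_ids)) != len(plate_ids):
        raise ValueError("plate_ids must be unique")
    return SuperpoolLayout(
        plate_grid_rows, plate_grid_cols, well_rows, well_cols, tuple(plate_ids)
    )


def pools_for_well(layout: SuperpoolLayout, well: WellAddress) -> tuple[PoolRef, PoolRef]:
    """The (row pool, column pool) containing a well.

    The row-pool index runs over the plate-grid rows times the well rows;
    the column-pool index runs over the plate-grid columns times the well
    columns.
    """
    layout.validate_well(well)
    g_r, g_c = layout.plate_grid_position(well.plate_index)
    return (
        PoolRef(Axis.ROW, g_r * layout.well_rows + well.row),
        PoolRef(Axis.COL, g_c * layout.well_cols + well.col),
    )


def well_at_intersection(
    layout: SuperpoolLayout, row_pool: PoolRef, col_pool: PoolRef
) -> WellAddress:
    """The unique well at the intersection of a row pool and a column pool.

    Inverse of :func:`pools_for_well`.
    """
    if row_pool.axis is not Axis.ROW or col_pool.axis is not Axis.COL:
        raise ValueError("well_at_intersection needs one ROW pool and one COL pool")
    layout.validate_pool(row_pool)
    layout.validate_pool(col_pool)
    g_r, r = divmod(row_pool.index, layout.well_rows)
    g_c, c = divmod(col_pool.index, layout.well_cols)
    return WellAddress(g_r * layout.plate_grid_cols + g_c, r, c)


def member_wells(layout: SuperpoolLayout, pool: PoolRef) -> list[WellAddress]:
    """All wells pooled into one secondary pool.

    A row pool spans one physical plate row across every plate in its grid
    row, so it holds ``well_cols * plate_grid_cols`` wells; symmetrically a
    column pool holds ``well_rows * plate_grid_rows`` wells.
    """
    layout.validate_pool(pool)
    wells: list[WellAddress] = []
    if pool.axis is Axis.ROW:
        g_r, r = divmod(pool.index, layout.well_rows)
        for g_c in range(layout.plate_grid_cols):
            plate = g_r * layout.plate_grid_cols + g_c
            for c in range(layout.well_cols):
                wells.append(WellAddress(plate, r, c))
    else:
        g_c, c = divmod(pool.index, layout.well_cols)
        for g_r in range(layout.plate_grid_rows):
            plate = g_r * layout.plate_grid_cols + g_c
            for r in range(layout.well_rows):
                wells.append(WellAddress(plate, r, c))
    return wells


# --- pool index barcodes -------------------------------------------------

# GF(4) multiplication table with elements {0,1,2,3} encoded as the
# polynomials {0, 1, x, x+1} over GF(2) modulo x^2 + x + 1.  Addition in
# GF(4) is bitwise XOR.
_GF4_MUL = (
    (0, 0, 0, 0),
    (0, 1, 2, 3),
    (0, 2, 3, 1),
    (0, 3, 1, 2),
)

# Parity-check columns for a [7,4,3] code over GF(4): seven pairwise
# linearly independent vectors of GF(4)^3, the last three forming an
# identity block so the code is systematic.
_H_COLUMNS = (
    (1, 1, 0),
    (1, 0, 1),
    (0, 1, 1),
    (1, 1, 1),
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
)

_DIGIT_TO_BASE = "ACGT"


def make_barcodes(n: int, length: int = 7) -> list[str]:
    """Deterministic 7-bp pool barcodes with pairwise Hamming distance >= 3.

    Barcodes are codewords of a systematic [7,4,3] Hamming-type code over
    GF(4) with digits mapped to A/C/G/T, so up to 255 pools can be indexed
    while still tolerating one sequencing error per index during
    demultiplexing.  The all-A codeword is skipped.
    """
    if length != 7:
        raise ValueError("barcode design is fixed at 7 bp")
    if not 1 <= n <= 255:
        raise ValueError("between 1 and 255 barcodes are available")
    codes: list[str] = []
    for msg_id in range(1, n + 1):
        msg = [(msg_id >> (2 * j)) & 3 for j in range(4)]
        checks = [0, 0, 0]
        for i, m in enumerate(msg):
            col = _H_COLUMNS[i]
            for j in range(3):
                checks[j] ^= _GF4_MUL[m][col[j]]
        digits = msg + checks
        codes.append("".join(_DIGIT_TO_BASE[d] for d in digits))
    return codes


def build_index_table(
    layout: SuperpoolLayout, barcodes: Sequence[str] | None = None
) -> dict[PoolRef, str]:
    """Assign one index barcode to every secondary pool (row pools first)."""
    pools = list(layout.iter_pools())
    if barcodes is None:
        barcodes = make_barcodes(len(pools))
    if len(barcodes) != len(pools):
        raise ValueError(
            f"need {len(pools)} barcodes for this layout, got {len(barcodes)}"
        )
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes must be unique")
    return dict(zip(pools, barcodes))
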