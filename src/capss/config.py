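"""Run configuration: one validated object covering every stage's knobs.

Unknown keys are rejected so a typo in a config file fails loudly.  Two
presets ship: ``toy`` (the self-contained simulated benchmark: a 2 x 2
plate grid of 4 x 6 wells — 96 clones — on a 500 kb two-chromosome
genome with 5 kb mean inserts at 30x pool depth and 0.1% substitution
error) and ``paper-scale`` (the 24-plate, 6 x 4 grid of 16 x 24 wells
with ~123.5 kb inserts, for production-scale inputs).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .pool_design import SuperpoolLayout, build_layout


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayoutConfig(_Strict):
    plate_grid_rows: int = 2
    plate_grid_cols: int = 2
    well_rows: int = 4
    well_cols: int = 6
    plate_ids: list[str] | None = None

    def build(self) -> SuperpoolLayout:
        return build_layout(
            self.plate_grid_rows,
            self.plate_grid_cols,
            self.well_rows,
            self.well_cols,
            self.plate_ids,
        )


class SimulateConfig(_Strict):
    n_chrom: int = 2
    chrom_length: int = 250_000
    n_gaps: int = 6
    gap_length: int = 400
    repeat_unit_length: int = 400
    repeat_copies: int = 3
    gc: float = 0.46
    # small genomes need a denser HindIII lattice than random sequence
    # offers before one distinct-ended clone can sit in every well
    site_spacing: int | None = 1200
    insert_mean: float = 5000.0
    insert_sd: float = 800.0
    insert_min: float = 2000.0
    insert_max: float = 10_000.0
    unique_ends: bool = True
    organelle_fraction: float = 0.02
    organelle_length: int = 30_000
    host_length: int = 100_000
    flank_len: int = 500
    read_len: int = 150
    frag_mean: int = 450
    frag_sd: int = 50
    depth_per_pool: float = 30.0
    error_rate: float = 0.001
    host_fraction: float = 0.1
    bes_truth_len: int = 2000


class PreprocessConfig(_Strict):
    max_mismatch: int = 0
    min_mean_q: float = 20.0
    min_len: int = 100
    host_k: int = 21
    host_hit_fraction: float = 0.5


class ShortBesConfig(_Strict):
    min_vector_anchor: int = 20
    min_overlap: int = 50
    min_identity: float = 0.95
    min_depth: int = 3


class LongBesConfig(_Strict):
    min_overlap: int = 40
    min_identity: float = 0.98
    min_vector_anchor: int = 20


class AssignConfig(_Strict):
    min_identity: float = 0.99
    min_cov: float = 0.9
    policy: str = "STRICT"
    max_wells_per_bes: int = 1


class MapConfig(_Strict):
    min_identity: float = 0.99
    min_qcov: float = 0.99
    seed_k: int = 21
    culling_overlap: float = 0.5
    max_span: int = 250_000
    mask: bool = False
    mask_max_freq: int = 4
    min_agreement_identity: float = 0.99


class GapConfig(_Strict):
    min_run: int = 1


class RunConfig(_Strict):
    seed: int = 1
    layout: LayoutConfig = Field(default_factory=LayoutConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    bes_short: ShortBesConfig = Field(default_factory=ShortBesConfig)
    bes_long: LongBesConfig = Field(default_factory=LongBesConfig)
    assign: AssignConfig = Field(default_factory=AssignConfig)
    genmap: MapConfig = Field(default_factory=MapConfig)
    gaps: GapConfig = Field(default_factory=GapConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.model_dump(), f, sort_keys=False)


def toy_config(seed: int = 1) -> RunConfig:
    """The self-contained simulated benchmark (the defaults)."""
    cfg = RunConfig(seed=seed)
    return cfg


def mini_config(seed: int = 1) -> RunConfig:
    """A very small configuration for quick smoke runs: a single plate of
    3 x 4 wells on a 120 kb genome with 2 kb inserts."""
    return RunConfig(
        seed=seed,
        layout=LayoutConfig(plate_grid_rows=1, plate_grid_cols=1, well_rows=3, well_cols=4),
        simulate=SimulateConfig(
            n_chrom=1,
            chrom_length=120_000,
            n_gaps=2,
            gap_length=300,
            repeat_copies=0,
            repeat_unit_length=0,
            site_spacing=500,
            insert_mean=2000.0,
            insert_sd=300.0,
            insert_min=1000.0,
            insert_max=4000.0,
            organelle_fraction=0.0,
            depth_per_pool=25.0,
            host_fraction=0.05,
            host_length=50_000,
        ),
    )


def paper_scale_config(seed: int = 1) -> RunConfig:
    """The production-scale superpool: 24 plates in a 6 x 4 grid of
    16 x 24 wells (96 row pools, 96 column pools, 9216 clones), insert
    sizes around 123.5 kb.  Intended for real pooled libraries; the
    built-in simulator is not meant to run at this scale."""
    return RunConfig(
        seed=seed,
        layout=LayoutConfig(
            plate_grid_rows=6,
            plate_grid_cols=4,
            well_rows=16,
            well_cols=24,
            plate_ids=[str(i) for i in range(25, 49)],
        ),
        simulate=SimulateConfig(
            n_chrom=18,
            chrom_length=47_000_000,
            n_gaps=829,
            gap_length=1000,
            site_spacing=None,
            insert_mean=123_480.0,
            insert_sd=20_000.0,
            insert_min=50_000.0,
            insert_max=300_000.0,
            depth_per_pool=45.0,
            host_fraction=0.4,
        ),
    )


PRESETS = {
    "toy": toy_config,
    "mini": mini_config,
    "paper-scale": paper_scale_config,
}
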