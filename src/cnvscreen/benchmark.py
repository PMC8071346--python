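"""Genome-scale benchmark harness for the in-silico accuracy study.

Builds the study conditions end to end from synthetic data: a CNV-free
reference panel of 100 samples at 10 M reads on GRCh37 chromosome sizes,
a trained reference model, and CNV-free test samples generated at 12 M
reads to be downsampled to the depths under study.  The injection design
(one random bin-aligned single-copy CNV at a time, avoiding filtered
bins) then measures detection and boundary accuracy per
(CNV length × read count) cell.

Problem sizes are the package's reference configuration; everything is
deterministic given one integer seed.
"""

from __future__ import annotations

import dataclasses
import logging

from .binning import RawBinCounts, scale_compartments
from .genome import BinGrid, GCTrack
from .insilico import AccuracyCell, run_grid
from .normalize import (
    NormalizationConfig,
    ReferenceModel,
    loess_gc_correct,
    train_reference_model,
)
from .segment import CBSParams
from .synthetic import hg19_spec, make_case, make_panel, make_reference_genome

logger = logging.getLogger(__name__)

PANEL_SIZE = 100
PANEL_READS = 10_000_000.0
TEST_SAMPLE_READS = 12_000_000.0  # generated above the deepest studied depth

#: CBS settings for the genome-scale study; 500 permutations resolve the
#: default alpha of 0.01 while keeping thousands of trials affordable.
STUDY_CBS = CBSParams(n_permutations=500)


@dataclasses.dataclass
class Study:
    grid: BinGrid
    gc: GCTrack
    truth: dict
    model: ReferenceModel
    cases: list[RawBinCounts]
    seed: int


def build_study(seed: int, n_panel: int = PANEL_SIZE, n_test: int = 10) -> Study:
    """Generate the panel, train the model, and create the test samples."""
    spec = hg19_spec(n_samples=n_panel, reads_per_sample=PANEL_READS, seed=seed)
    grid, gc, truth = make_reference_genome(spec)
    samples, _ = make_panel(spec, grid, gc, truth)
    logger.info("panel: %d samples, %d bins", n_panel, grid.n_bins)
    corrected = [
        loess_gc_correct(scale_compartments(s, grid), gc, grid) for s in samples
    ]
    del samples
    model = train_reference_model(corrected, gc, grid, NormalizationConfig())
    del corrected
    case_spec = dataclasses.replace(spec, reads_per_sample=TEST_SAMPLE_READS)
    cases = [
        make_case(case_spec, [], case_seed=i, grid=grid, gc=gc, truth=truth)[0]
        for i in range(n_test)
    ]
    return Study(grid=grid, gc=gc, truth=truth, model=model, cases=cases, seed=seed)


def measure_cell(
    study: Study,
    length_bp: int,
    read_count: int,
    n_variants: int = 100,
    seed_offset: int = 0,
) -> AccuracyCell:
    """One accuracy-grid cell over all the study's test samples."""
    [cell] = run_grid(
        study.cases,
        study.model,
        study.gc,
        study.grid,
        lengths=[length_bp],
        read_counts=[read_count],
        n_variants=n_variants,
        cbs_params=STUDY_CBS,
        seed=(study.seed + seed_offset) % (2**31 - 1),
    )
    return cell
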