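"""Read counting into bins and per-compartment count scaling.

Reads are counted by the leftmost mapped base of each mate into the bin
``start // bin_size``; records that are unmapped, secondary, supplementary,
duplicate-flagged, or below the mapping-quality cutoff (40 by default) are
discarded.  Nothing about a read other than its position and mapping
quality is used.

Counts are then rescaled so every sample has the same total per
compartment: the autosomal bins sum to a fixed target, and chrX and chrY
are rescaled separately.  The default targets give a mean scaled bin count
of 100, so one copy of a single-copy gain or loss corresponds to a level
of ±50 downstream.  A consequence of the separate sex-chromosome scaling
is that whole sex-chromosome aneuploidies are invisible by construction;
only sub-chromosomal variation on X/Y can be seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AUTOSOME, CHR_X, CHR_Y, BinGrid

logger = logging.getLogger(__name__)

DEFAULT_MAPQ_MIN = 40
DEFAULT_TARGET_MEAN = 100.0

COMPARTMENTS = (AUTOSOME, CHR_X, CHR_Y)
_COMP_NAMES = {AUTOSOME: "autosome", CHR_X: "chrX", CHR_Y: "chrY"}


@dataclass
class RawBinCounts:
    """Per-bin read-start counts for one sample.

    ``counts`` is float-valued so that in-silico CNV injection (which
    multiplies bins by 0.5/1.5) composes without a separate type, but
    values produced by counting are integral.
    """

    sample_id: str
    counts: np.ndarray
    grid_fingerprint: str
    total_discarded_low_mapq: int = 0
    total_discarded_flags: int = 0
    total_skipped_unknown_chrom: int = 0

    @property
    def total_counted(self) -> float:
        return float(self.counts.sum())

    def copy_with(self, counts: np.ndarray, **kw) -> "RawBinCounts":
        return replace(self, counts=counts, **kw)


@dataclass
class ScaledBinCounts:
    """Counts rescaled to fixed per-compartment totals."""

    sample_id: str
    values: np.ndarray
    grid_fingerprint: str
    scale_factors: dict[int, float]
    targets: dict[int, float]
    unusable_compartments: frozenset[int] = frozenset()
    # bins the GC correction could not handle (undefined GC / bad fit)
    gc_uncorrected: np.ndarray | None = field(default=None, repr=False)


def bin_reads(
    alignments,
    grid: BinGrid,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    sample_id: str | None = None,
) -> RawBinCounts:
    """Count read starts per bin from a SAM/BAM/CRAM file or record stream.

    ``alignments`` may be a path or an open ``pysam.AlignmentFile``.  Each
    mate passing the filters increments exactly one bin; mates are counted
    independently.  Records on chromosomes absent from the grid are skipped
    and tallied.
    """
    import pysam

    own = False
    if isinstance(alignments, (str, Path)):
        if sample_id is None:
            sample_id = Path(alignments).stem
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    if sample_id is None:
        sample_id = "sample"

    counts = np.zeros(grid.n_bins, dtype=np.float64)
    offsets: dict[str, tuple[int, int]] = {}
    for name, _ in grid.chromosomes:
        sl = grid.chrom_slice(name)
        offsets[name] = (sl.start, sl.stop - sl.start)

    n_mapq = n_flags = n_unknown = 0
    bs = grid.bin_size
    try:
        for rec in alignments:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                n_flags += 1
                continue
            if rec.mapping_quality < mapq_min:
                n_mapq += 1
                continue
            ref = rec.reference_name
            entry = offsets.get(ref)
            if entry is None:
                n_unknown += 1
                continue
            off, nbins = entry
            b = rec.reference_start // bs
            if 0 <= b < nbins:
                counts[off + b] += 1
            else:
                n_unknown += 1
    finally:
        if own:
            alignments.close()

    if n_unknown:
        logger.warning("%s: skipped %d records on chromosomes outside the grid", sample_id, n_unknown)
    logger.info(
        "%s: counted %d reads (discarded %d low-MAPQ, %d flagged)",
        sample_id, int(counts.sum()), n_mapq, n_flags,
    )
    return RawBinCounts(
        sample_id=sample_id,
        counts=counts,
        grid_fingerprint=grid.fingerprint(),
        total_discarded_low_mapq=n_mapq,
        total_discarded_flags=n_flags,
        total_skipped_unknown_chrom=n_unknown,
    )


def default_targets(grid: BinGrid, target_mean: float = DEFAULT_TARGET_MEAN) -> dict[int, float]:
    """Per-compartment target sums: number of bins × target mean."""
    return {
        comp: float((grid.compartment == comp).sum()) * target_mean
        for comp in COMPARTMENTS
        if (grid.compartment == comp).any()
    }


def scale_compartments(
    raw: RawBinCounts,
    grid: BinGrid,
    targets: dict[int, float] | None = None,
) -> ScaledBinCounts:
    """Rescale counts so each compartment sums to its target.

    Relative proportions within a compartment are unchanged.  A compartment
    with zero total reads but a nonzero target is flagged unusable (values
    set to NaN) rather than divided by zero.
    """
    if raw.grid_fingerprint != grid.fingerprint():
        raise ValueError("counts were produced on a different grid")
    if targets is None:
        targets = default_targets(grid)
    values = np.array(raw.counts, dtype=np.float64)
    factors: dict[int, float] = {}
    unusable = set()
    for comp, target in targets.items():
        sel = grid.compartment == comp
        total = values[sel].sum()
        if total <= 0:
            if target > 0:
                logger.warning(
                    "%s: compartment %s has zero reads; flagged unusable",
                    raw.sample_id, _COMP_NAMES.get(comp, comp),
                )
                values[sel] = np.nan
                unusable.add(comp)
            factors[comp] = np.nan
            continue
        f = target / total
        values[sel] *= f
        factors[comp] = f
    return ScaledBinCounts(
        sample_id=raw.sample_id,
        values=values,
        grid_fingerprint=raw.grid_fingerprint,
        scale_factors=factors,
        targets=dict(targets),
        unusable_compartments=frozenset(unusable),
    )


# ---------------------------------------------------------------------------
# TSV front end (chrom, start, end, count) — lets the pipeline run without
# alignment files.


def write_counts_tsv(path: str | Path, raw: RawBinCounts, grid: BinGrid) -> None:
    df = grid.to_frame()[["chrom", "start", "end"]].copy()
    df["count"] = raw.counts
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_counts_tsv(path: str | Path, grid: BinGrid, sample_id: str | None = None) -> RawBinCounts:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"count TSV must have columns {sorted(required)}")
    counts = np.zeros(grid.n_bins, dtype=np.float64)
    idx = np.empty(len(df), dtype=np.int64)
    for chrom, sub in df.groupby("chrom", sort=False):
        sl = grid.chrom_slice(str(chrom))
        idx[sub.index.to_numpy()] = sl.start + sub["start"].to_numpy() // grid.bin_size
    counts[idx] = df["count"].to_numpy(float)
    return RawBinCounts(
        sample_id=sample_id or Path(path).stem,
        counts=counts,
        grid_fingerprint=grid.fingerprint(),
    )
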