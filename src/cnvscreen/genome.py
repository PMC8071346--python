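"""Genomic bin tiling and per-bin GC content.

The pipeline's basic datum is the count of reads starting in a fixed-width
genomic bin (20 kb by default).  This module owns every coordinate
convention: bins are 0-based, half-open, laid out chromosome by chromosome
in the order the chromosome-sizes table lists them, and addressed either by
a global index or by (chromosome, local index).

Chromosomes are partitioned into three *compartments* — autosomes, chrX and
chrY — because read totals are rescaled per compartment and the principal
component denoising is trained on autosomes only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 20_000

# compartment codes
AUTOSOME = 0
CHR_X = 1
CHR_Y = 2

_CANONICAL_AUTOSOMES = {str(i) for i in range(1, 23)}


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def compartment_of(chrom: str) -> int | None:
    """Compartment code for a chromosome name, or None if non-canonical.

    Accepts names with or without a ``chr`` prefix.  Mitochondrial and
    other non-canonical contigs map to None and are excluded from grids
    by default.
    """
    core = _strip_chr(chrom).upper()
    if core in _CANONICAL_AUTOSOMES:
        return AUTOSOME
    if core == "X":
        return CHR_X
    if core == "Y":
        return CHR_Y
    return None


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of a genome into bins.

    Attributes
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Nominal bin width in bp; the last bin of each chromosome may be
        truncated.
    chrom_index, start, end, compartment
        Per-bin parallel arrays (global bin order).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    chrom_index: np.ndarray = field(repr=False)
    start: np.ndarray = field(repr=False)
    end: np.ndarray = field(repr=False)
    compartment: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return self.start.size

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def chrom_slice(self, chrom: str) -> slice:
        """Global-index slice covering one chromosome's bins."""
        try:
            ci = self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in grid") from None
        lo = int(np.searchsorted(self.chrom_index, ci, side="left"))
        hi = int(np.searchsorted(self.chrom_index, ci, side="right"))
        return slice(lo, hi)

    def global_index(self, chrom: str, local: int) -> int:
        sl = self.chrom_slice(chrom)
        n = sl.stop - sl.start
        if not 0 <= local < n:
            raise IndexError(f"local bin {local} out of range for {chrom} ({n} bins)")
        return sl.start + local

    def local_index(self, global_idx: int) -> tuple[str, int]:
        if not 0 <= global_idx < self.n_bins:
            raise IndexError(global_idx)
        ci = int(self.chrom_index[global_idx])
        chrom = self.chromosomes[ci][0]
        return chrom, global_idx - self.chrom_slice(chrom).start

    def bin_of_position(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing 0-based position ``pos``."""
        sl = self.chrom_slice(chrom)
        length = dict(self.chromosomes)[chrom]
        if not 0 <= pos < length:
            raise IndexError(f"position {pos} outside {chrom} (length {length})")
        return sl.start + pos // self.bin_size

    @property
    def autosomal(self) -> np.ndarray:
        """Boolean per-bin mask of autosomal bins."""
        return self.compartment == AUTOSOME

    @property
    def bin_widths(self) -> np.ndarray:
        return self.end - self.start

    def fingerprint(self) -> str:
        """Hash identifying bin size and chromosome names/lengths."""
        h = hashlib.sha256()
        h.update(str(self.bin_size).encode())
        for name, length in self.chromosomes:
            h.update(f"{name}:{length};".encode())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        names = np.asarray(self.chrom_names, dtype=object)
        return pd.DataFrame(
            {
                "chrom": names[self.chrom_index],
                "start": self.start,
                "end": self.end,
                "compartment": self.compartment,
            }
        )


def build_bin_grid(
    chrom_sizes: Mapping[str, int] | Sequence[tuple[str, int]],
    bin_size: int = DEFAULT_BIN_SIZE,
    include: Iterable[str] | None = None,
) -> BinGrid:
    """Tile a genome into fixed-width bins.

    Parameters
    ----------
    chrom_sizes
        Ordered mapping or sequence of ``(name, length_bp)``.
    bin_size
        Bin width in bp (> 0).
    include
        Explicit whitelist of chromosome names to keep.  By default, all
        canonical chromosomes (1-22, X, Y, with or without ``chr`` prefix)
        are kept and everything else (chrM, unplaced contigs, ...) dropped.

    The last bin of a chromosome is truncated when the length is not a
    multiple of ``bin_size``; truncated bins are kept (downstream low-mean
    filtration removes them if problematic).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    items = list(chrom_sizes.items()) if isinstance(chrom_sizes, Mapping) else list(chrom_sizes)
    seen: set[str] = set()
    kept: list[tuple[str, int, int]] = []
    whitelist = set(include) if include is not None else None
    for name, length in items:
        if name in seen:
            raise ValueError(f"duplicate chromosome name {name!r}")
        seen.add(name)
        length = int(length)
        if length <= 0:
            raise ValueError(f"non-positive length for {name!r}: {length}")
        comp = compartment_of(name)
        if whitelist is not None:
            if name not in whitelist:
                continue
            if comp is None:
                comp = AUTOSOME  # user explicitly asked for it
        elif comp is None:
            continue
        kept.append((name, length, comp))
    if not kept:
        raise ValueError("no chromosomes left after filtering")

    chrom_idx, starts, ends, comps = [], [], [], []
    for ci, (name, length, comp) in enumerate(kept):
        n = -(-length // bin_size)  # ceil
        s = np.arange(n, dtype=np.int64) * bin_size
        e = np.minimum(s + bin_size, length)
        chrom_idx.append(np.full(n, ci, dtype=np.int32))
        starts.append(s)
        ends.append(e)
        comps.append(np.full(n, comp, dtype=np.int8))
    return BinGrid(
        chromosomes=tuple((n, l) for n, l, _ in kept),
        bin_size=bin_size,
        chrom_index=np.concatenate(chrom_idx),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        compartment=np.concatenate(comps),
    )


@dataclass(frozen=True)
class GCTrack:
    """Per-bin GC fraction and fraction of defined (non-N) bases.

    ``gc`` is NaN (undefined) wherever fewer than half of a bin's bases are
    defined; ``defined`` returns the mask of bins with a usable GC value.
    """

    gc: np.ndarray
    defined_fraction: np.ndarray

    MIN_DEFINED = 0.5

    def __post_init__(self):
        if self.gc.shape != self.defined_fraction.shape:
            raise ValueError("gc and defined_fraction lengths differ")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.gc) & (self.defined_fraction >= self.MIN_DEFINED)

    @property
    def n_bins(self) -> int:
        return self.gc.size


def compute_gc_track(sequences: Mapping[str, str], grid: BinGrid) -> GCTrack:
    """Per-bin GC fraction from chromosome sequences.

    ``sequences`` maps chromosome name to its sequence (string or anything
    sliceable yielding str, e.g. a ``pyfaidx.Fasta`` record mapping).  GC is
    (G+C)/(A+C+G+T) over the bin span; N and other ambiguous bases count in
    neither numerator nor denominator.  GC is undefined (NaN) when fewer
    than half the bin's bases are A/C/G/T.
    """
    gc = np.full(grid.n_bins, np.nan)
    defined = np.zeros(grid.n_bins)
    for name, length in grid.chromosomes:
        if name not in sequences:
            raise KeyError(f"no sequence for chromosome {name!r}")
        seq = str(sequences[name][:length]).upper()
        if len(seq) < length:
            seq = seq + "N" * (length - len(seq))
        sl = grid.chrom_slice(name)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_at = (arr == ord("A")) | (arr == ord("T"))
        # per-bin sums via reduceat on bin starts
        starts = grid.start[sl]
        gc_counts = np.add.reduceat(is_gc.astype(np.int64), starts)
        at_counts = np.add.reduceat(is_at.astype(np.int64), starts)
        widths = grid.bin_widths[sl]
        denom = gc_counts + at_counts
        frac_defined = denom / widths
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(denom > 0, gc_counts / np.maximum(denom, 1), np.nan)
        vals = np.where(frac_defined >= GCTrack.MIN_DEFINED, vals, np.nan)
        gc[sl] = vals
        defined[sl] = frac_defined
    return GCTrack(gc=gc, defined_fraction=defined)


# ---------------------------------------------------------------------------
# plain-text interfaces


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    """Read a two-column (name, length) TSV."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, length = line.split("\t")[:2]
        out.append((name, int(length)))
    return out


def write_gc_track(path: str | Path, grid: BinGrid, track: GCTrack) -> None:
    df = grid.to_frame()[["chrom", "start", "end"]].copy()
    df["gc"] = track.gc
    df["defined_fraction"] = track.defined_fraction
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="nan")


def read_gc_track(path: str | Path, grid: BinGrid) -> GCTrack:
    df = pd.read_csv(path, sep="\t")
    if len(df) != grid.n_bins:
        raise ValueError(
            f"GC track has {len(df)} rows but grid has {grid.n_bins} bins"
        )
    return GCTrack(
        gc=df["gc"].to_numpy(float), defined_fraction=df["defined_fraction"].to_numpy(float)
    )
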