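"""In-silico accuracy study: CNV injection over a (length × depth) grid.

Detection power is measured without re-sequencing anything: a CNV-free
sample's bin counts are downsampled to the studied depth by binomial
thinning, a random bin-aligned region avoiding filtered bins is chosen,
its counts are multiplied by 0.5 (single-copy loss) or 1.5 (single-copy
gain), and the unchanged calling pipeline runs on the result.  A trial is
a *detection* when any non-green call of the matching sign overlaps the
injected region; boundary accuracy is scored as exact coordinate match
and as both boundaries within one bin of the truth.

Aggregating over samples and injected variants for every combination of
CNV length and read count yields an accuracy table in the shape of a
power grid; detection fractions increase with both length and depth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import RawBinCounts
from .genome import AUTOSOME, BinGrid, GCTrack
from .normalize import ReferenceModel, normalize_sample
from .segment import CBSParams, Segment, call_cnvs

logger = logging.getLogger(__name__)

LOSS_MULTIPLIER = 0.5
GAIN_MULTIPLIER = 1.5


@dataclass(frozen=True)
class SimulatedCNV:
    """A planted single-copy CNV, aligned to bin boundaries."""

    chromosome: str
    start_bp: int
    end_bp: int
    multiplier: float  # 0.5 = loss, 1.5 = gain

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def is_deletion(self) -> bool:
        return self.multiplier < 1.0


@dataclass
class AccuracyCell:
    """Detection metrics for one (CNV length, read count) grid cell."""

    variation_length: int
    read_count: int
    n_trials: int
    detected_fraction: float
    exact_match_fraction: float
    within_one_bin_fraction: float

    def __post_init__(self):
        if self.exact_match_fraction > self.within_one_bin_fraction + 1e-12:
            raise ValueError("exact matches cannot exceed within-one-bin matches")


def downsample(
    raw: RawBinCounts, target_reads: float, seed: int | np.random.Generator
) -> RawBinCounts:
    """Binomially thin bin counts to ``target_reads`` total in expectation.

    Each bin's count is replaced by Binomial(count, target/total) — the
    distribution read-level subsampling would induce on per-bin start
    counts.  Deterministic given the seed.
    """
    total = raw.total_counted
    if target_reads > total:
        raise ValueError(f"target {target_reads:.0f} exceeds available reads {total:.0f}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = target_reads / total
    if q == 1.0:
        return raw.copy_with(raw.counts.copy())
    counts = rng.binomial(np.round(raw.counts).astype(np.int64), q).astype(np.float64)
    return raw.copy_with(counts)


def eligible_window_starts(
    grid: BinGrid, usable: np.ndarray, length_bp: int
) -> np.ndarray:
    """Global start-bin indices of eligible injection windows.

    A window is eligible when it is autosomal, spans ``length_bp // bin_size``
    consecutive full-width bins of one chromosome, and overlaps no filtered
    bin.
    """
    if length_bp % grid.bin_size != 0:
        raise ValueError("CNV length must be a multiple of the bin size")
    nb = length_bp // grid.bin_size
    ok = (
        usable
        & (grid.compartment == AUTOSOME)
        & (grid.bin_widths == grid.bin_size)
    ).astype(np.int64)
    # run-length: window valid if all nb bins from i are ok and on one chromosome
    csum = np.concatenate([[0], np.cumsum(ok)])
    starts = np.arange(grid.n_bins - nb + 1)
    full = csum[starts + nb] - csum[starts] == nb
    same_chrom = grid.chrom_index[starts] == grid.chrom_index[starts + nb - 1]
    return starts[full & same_chrom]


def sample_random_region(
    grid: BinGrid,
    usable: np.ndarray,
    length_bp: int,
    rng: np.random.Generator,
    multiplier: float | None = None,
) -> SimulatedCNV:
    """Uniformly sample an eligible bin-aligned autosomal window.

    When ``multiplier`` is None a loss (0.5) or gain (1.5) is chosen with
    equal probability.
    """
    starts = eligible_window_starts(grid, usable, length_bp)
    if starts.size == 0:
        raise ValueError(f"no eligible window of length {length_bp} bp")
    b = int(rng.choice(starts))
    nb = length_bp // grid.bin_size
    chrom, _ = grid.local_index(b)
    if multiplier is None:
        multiplier = LOSS_MULTIPLIER if rng.random() < 0.5 else GAIN_MULTIPLIER
    return SimulatedCNV(
        chromosome=chrom,
        start_bp=int(grid.start[b]),
        end_bp=int(grid.end[b + nb - 1]),
        multiplier=float(multiplier),
    )


def cnv_bin_range(cnv: SimulatedCNV, grid: BinGrid) -> tuple[int, int]:
    """Global half-open bin-index range covered by a bin-aligned CNV."""
    sl = grid.chrom_slice(cnv.chromosome)
    lo = sl.start + cnv.start_bp // grid.bin_size
    hi = sl.start + (cnv.end_bp - 1) // grid.bin_size + 1
    if lo < sl.start or hi > sl.stop:
        raise ValueError("CNV outside the grid")
    return lo, hi


def inject_cnv(
    raw: RawBinCounts,
    cnv: SimulatedCNV,
    grid: BinGrid,
    usable: np.ndarray | None = None,
) -> RawBinCounts:
    """Multiply the counts of the CNV's member bins by its multiplier.

    All other bins are untouched (bit-identical).  The real-valued result
    is retained — the downstream pipeline is real-valued after scaling
    anyway.  Raises if the region overlaps filtered bins (when a mask is
    given).
    """
    lo, hi = cnv_bin_range(cnv, grid)
    if usable is not None and not usable[lo:hi].all():
        raise ValueError("CNV region overlaps filtered bins")
    counts = raw.counts.copy()
    counts[lo:hi] *= cnv.multiplier
    return raw.copy_with(counts)


def score_detection(
    truth: SimulatedCNV, calls: list[Segment], bin_size: int
) -> dict[str, bool]:
    """Score one trial against the injected truth region.

    ``detected``: some non-green call of the matching sign overlaps the
    truth by >= 1 bp.  ``exact``: such a call matches both boundaries.
    ``within_one_bin``: both boundaries within ± one bin.
    """
    want = "deletion" if truth.is_deletion else "duplication"
    detected = exact = within = False
    for s in calls:
        if s.significance in (None, "green") or s.call_type != want:
            continue
        if s.chromosome != truth.chromosome:
            continue
        if s.start_bp < truth.end_bp and s.end_bp > truth.start_bp:
            detected = True
            if s.start_bp == truth.start_bp and s.end_bp == truth.end_bp:
                exact = True
            if (
                abs(s.start_bp - truth.start_bp) <= bin_size
                and abs(s.end_bp - truth.end_bp) <= bin_size
            ):
                within = True
    return {"detected": detected, "exact": exact, "within_one_bin": within}


def planned_trials(
    n_samples: int, lengths, read_counts, n_variants: int
) -> int:
    """Total trial count of a full grid design."""
    return n_samples * len(list(lengths)) * len(list(read_counts)) * n_variants


def run_grid(
    base_samples: list[RawBinCounts],
    model: ReferenceModel,
    gc: GCTrack,
    grid: BinGrid,
    lengths,
    read_counts,
    n_variants: int,
    cbs_params: CBSParams | None = None,
    seed: int = 0,
    restrict_to_cnv_chrom: bool = True,
) -> list[AccuracyCell]:
    """Run the full injection design and tabulate accuracy per cell.

    For each (length, read count) cell, every base sample is downsampled
    once and ``n_variants`` random CNVs are injected one at a time — one
    artificial sample per variant.  ``restrict_to_cnv_chrom`` segments only
    the chromosome carrying the injection; scoring inspects only calls
    overlapping the truth region, so the reported fractions are identical
    either way.  Fully deterministic given ``seed``.
    """
    if cbs_params is None:
        cbs_params = CBSParams()
    lengths = [int(l) for l in lengths]
    read_counts = [int(r) for r in read_counts]
    usable = model.usable
    cells: list[AccuracyCell] = []
    for ci, (length, rc) in enumerate(
        (l, r) for l in lengths for r in read_counts
    ):
        cell_ss = np.random.SeedSequence(entropy=seed, spawn_key=(ci,))
        hits = {"detected": 0, "exact": 0, "within_one_bin": 0}
        n_trials = 0
        for si, base in enumerate(base_samples):
            srng = np.random.default_rng(cell_ss.spawn(1)[0])
            down = downsample(base, rc, srng)
            for vi in range(n_variants):
                cnv = sample_random_region(grid, usable, length, srng)
                injected = inject_cnv(down, cnv, grid, usable=usable)
                profile = normalize_sample(injected, gc, model, grid)
                chroms = [cnv.chromosome] if restrict_to_cnv_chrom else None
                params = dataclasses.replace(
                    cbs_params, rng_seed=int(srng.integers(1, 2**31 - 1))
                )
                calls = call_cnvs(profile, params, chromosomes=chroms)
                res = score_detection(cnv, calls, grid.bin_size)
                for k in hits:
                    hits[k] += res[k]
                n_trials += 1
        cells.append(
            AccuracyCell(
                variation_length=length,
                read_count=rc,
                n_trials=n_trials,
                detected_fraction=hits["detected"] / n_trials,
                exact_match_fraction=hits["exact"] / n_trials,
                within_one_bin_fraction=hits["within_one_bin"] / n_trials,
            )
        )
        logger.info(
            "cell length=%d reads=%d: detected %.3f exact %.3f within1 %.3f (%d trials)",
            length, rc, cells[-1].detected_fraction,
            cells[-1].exact_match_fraction, cells[-1].within_one_bin_fraction, n_trials,
        )
    return cells


def accuracy_frame(cells: list[AccuracyCell]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cells])


def plot_accuracy_heatmap(cells: list[AccuracyCell], path) -> None:
    """Detection-fraction heatmap over (CNV length × read count)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = accuracy_frame(cells)
    pivot = df.pivot(
        index="variation_length", columns="read_count", values="detected_fraction"
    )
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto", vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), [f"{c/1e6:g}M" for c in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{i/1e3:g}k" for i in pivot.index])
    ax.set_xlabel("read count")
    ax.set_ylabel("CNV length")
    for (yi, xi), v in np.ndenumerate(pivot.to_numpy()):
        ax.text(xi, yi, f"{100*v:.0f}", ha="center", va="center", fontsize=7,
                color="white" if v < 0.6 else "black")
    fig.colorbar(im, ax=ax, label="detected fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
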