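"""Segmentation of normalized profiles and significance classification.

Each chromosome's unfiltered bins are partitioned into constant-level
segments by circular binary segmentation (CBS): recursively, the arc of
the circularized series maximizing the standardized mean-difference
statistic is tested against a permutation null and, if significant, the
series is split at the arc boundaries.  Runs of unfiltered bins separated
by more than ``max_gap_bp`` (1 Mb by default, e.g. across centromeres) are
segmented independently so no segment bridges such a gap.

Every segment is then classified against the single-copy level
L = m/2 (m = mean scaled bin count): with r = |mean| / L,

    magenta  r >= 0.75  and span >= 200 kb
    red      r >= 0.25  and span >= 200 kb
    orange   r >= 0.25  and span >=  40 kb
    yellow   r >= 0.125 and span >=  40 kb
    green    everything else (short segments or segments around zero)

Non-green segments are CNV calls; the sign of the mean decides deletion
vs duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import _cbs
from .normalize import NormalizedProfile

logger = logging.getLogger(__name__)

SIGNIFICANCE_RANK = {"green": 0, "yellow": 1, "orange": 2, "red": 3, "magenta": 4}

# (significance, min relative level, min span bp); first match wins
_CLASS_RULES = (
    ("magenta", 0.75, 200_000),
    ("red", 0.25, 200_000),
    ("orange", 0.25, 40_000),
    ("yellow", 0.125, 40_000),
)


@dataclass(frozen=True)
class CBSParams:
    """Circular-binary-segmentation parameters.

    alpha
        Significance level for accepting a split (permutation p-value).
    n_permutations
        Permutations per split test (>= 100).
    min_seg_bins
        Minimum bins on each side of a split.
    undo_sd
        Merge adjacent segments whose standardized mean difference is
        below this many SDs (0 disables).
    rng_seed
        Seed for the permutation RNG; results are deterministic given it.
    exact_perm_n
        Series at most this long use the exact all-arcs statistic inside
        the permutation test; longer series use the width-ladder family.
    max_gap_bp
        Unfiltered-bin gaps longer than this break segments.
    smooth_outliers / smooth_halfwidth / outlier_sd / shrink_sd
        Before segmentation, points further than ``outlier_sd`` robust SDs
        from their running median (window ``2*halfwidth+1``) are shrunk to
        the median ± ``shrink_sd`` SDs.  Isolated spikes from single
        misbehaving bins would otherwise dominate the arc statistic while
        being exchangeable under permutation, suppressing real splits.
    """

    alpha: float = 0.01
    n_permutations: int = 10_000
    min_seg_bins: int = 1
    undo_sd: float = 0.0
    rng_seed: int = 0
    exact_perm_n: int = 1024
    max_gap_bp: int = 1_000_000
    smooth_outliers: bool = True
    smooth_halfwidth: int = 2
    outlier_sd: float = 4.0
    shrink_sd: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass(frozen=True)
class Segment:
    """A maximal run of unfiltered bins with a common level."""

    chromosome: str
    start_bin: int  # half-open, in unfiltered-bin order within the chromosome
    end_bin: int
    start_bp: int
    end_bp: int
    n_bins: int
    length_bp: int  # sum of member-bin spans (bridged filtered gaps excluded)
    mean_level: float
    call_type: str = "neutral"  # deletion | duplication | neutral
    significance: str | None = None
    relative_level: float = float("nan")


def smooth_outlier_bins(x: np.ndarray, params: CBSParams) -> np.ndarray:
    """Shrink isolated spikes toward their running median.

    A point whose residual from the running median exceeds ``outlier_sd``
    robust SDs is pulled to the median ± ``shrink_sd`` SDs — unless an
    adjacent bin is extreme in the same direction.  The smallest callable
    event spans two bins (the 40 kb length minimum), so same-direction
    runs of two or more extreme bins are never touched; only lone spikes
    are.  The robust scale is 1.4826 × MAD of the residuals from the
    running median.
    """
    n = x.size
    w = params.smooth_halfwidth
    if n < 2 * w + 1:
        return x
    from scipy.ndimage import median_filter

    med = median_filter(x, size=2 * w + 1, mode="nearest")
    resid = x - med
    sigma = 1.4826 * float(np.median(np.abs(resid)))
    if sigma <= 0:
        return x
    thr = params.outlier_sd * sigma
    hi = resid > thr
    lo = resid < -thr
    protected = np.zeros(n, bool)
    for ext in (hi, lo):
        protected[:-1] |= ext[:-1] & ext[1:]
        protected[1:] |= ext[1:] & ext[:-1]
    outlier = (hi | lo) & ~protected
    out = x.copy()
    shrink = np.sign(resid) * params.shrink_sd * sigma
    out[outlier] = med[outlier] + shrink[outlier]
    return out


def _find_split(x: np.ndarray, params: CBSParams, rng: np.random.Generator):
    """Best significant split of a series, or None.

    Returns change points ``(a, b)`` with ``0 <= a < b <= n`` and at least
    one of them internal.
    """
    n = x.size
    kmin = max(1, params.min_seg_bins)
    kmax = min(n // 2, n - params.min_seg_bins)
    if n < 2 or kmin > kmax:
        return None
    C = _cbs.centered_cumsum(np.ascontiguousarray(x, dtype=np.float64))
    stat, i, j = _cbs.max_arc_stat(C, n, kmin, kmax)
    if stat <= 0:
        return None
    exact = n <= params.exact_perm_n
    widths = _cbs.ladder_widths(n, kmin, kmax)
    obs = stat if exact else _cbs.ladder_max_stat(C, n, widths)
    min_accept = min(params.n_permutations, int(np.ceil(2.0 / params.alpha)))
    seed = int(rng.integers(1, 2**31 - 1))
    _, _, significant = _cbs.perm_test(
        np.ascontiguousarray(x, dtype=np.float64),
        obs,
        widths,
        params.n_permutations,
        params.alpha,
        min_accept,
        seed,
        exact,
        kmin,
        kmax,
    )
    if not significant:
        return None
    if j > n:  # wrapped arc: change points are (j - n, i)
        a, b = j - n, i
    else:
        a, b = i, j
    if a == 0 and b == n:
        return None
    return a, b


def _segment_series(x: np.ndarray, params: CBSParams, rng: np.random.Generator) -> list[int]:
    """Recursive CBS on one series; returns sorted internal change points."""
    cps: set[int] = set()

    def rec(lo: int, hi: int) -> None:
        res = _find_split(x[lo:hi], params, rng)
        if res is None:
            return
        a, b = res
        pieces = sorted({lo, lo + a, lo + b, hi})
        cps.update(p for p in pieces if lo < p < hi)
        for p0, p1 in zip(pieces[:-1], pieces[1:]):
            rec(p0, p1)

    rec(0, x.size)
    out = sorted(cps)
    if params.undo_sd > 0:
        out = _undo_splits(x, out, params.undo_sd)
    return out


def _undo_splits(x: np.ndarray, cps: list[int], undo_sd: float) -> list[int]:
    """Remove change points whose between-segment contrast is too small."""
    s = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if s <= 0:
        return []
    cps = list(cps)
    while cps:
        bounds = [0] + cps + [x.size]
        worst_idx, worst_z = -1, np.inf
        for ci, cp in enumerate(cps):
            left = x[bounds[ci]:cp]
            right = x[cp:bounds[ci + 2]]
            z = abs(left.mean() - right.mean()) / (
                s * np.sqrt(1.0 / left.size + 1.0 / right.size)
            )
            if z < worst_z:
                worst_idx, worst_z = ci, z
        if worst_z >= undo_sd:
            break
        cps.pop(worst_idx)
    return cps


def cbs_segment(
    profile: NormalizedProfile,
    params: CBSParams | None = None,
    chromosomes: list[str] | None = None,
) -> list[Segment]:
    """Partition a profile into constant-level segments (unclassified).

    Only unfiltered bins participate; a segment's genomic span runs from
    its first member bin's start to its last member bin's end, so small
    filtered gaps inside a segment are bridged, while gaps longer than
    ``params.max_gap_bp`` break the series.
    """
    if params is None:
        params = CBSParams()
    grid = profile.grid
    rng = np.random.default_rng(params.rng_seed)
    names = chromosomes if chromosomes is not None else list(grid.chrom_names)
    segments: list[Segment] = []
    for chrom in names:
        sl = grid.chrom_slice(chrom)
        vals = profile.values[sl]
        usable_local = np.flatnonzero(np.isfinite(vals))
        if usable_local.size == 0:
            logger.info("%s: no unfiltered bins; skipped", chrom)
            continue
        g = sl.start + usable_local  # global bin indices, unfiltered order
        # break into chunks at long gaps
        gaps = grid.start[g[1:]] - grid.end[g[:-1]]
        chunk_bounds = [0, *list(np.flatnonzero(gaps > params.max_gap_bp) + 1), usable_local.size]
        for c0, c1 in zip(chunk_bounds[:-1], chunk_bounds[1:]):
            gc_idx = g[c0:c1]
            x = profile.values[gc_idx]
            if params.smooth_outliers:
                x = smooth_outlier_bins(x, params)
            cps = _segment_series(x, params, rng) if x.size > 1 else []
            bounds = [0, *cps, x.size]
            for u, v in zip(bounds[:-1], bounds[1:]):
                member = gc_idx[u:v]
                segments.append(
                    Segment(
                        chromosome=chrom,
                        start_bin=c0 + u,
                        end_bin=c0 + v,
                        start_bp=int(grid.start[member[0]]),
                        end_bp=int(grid.end[member[-1]]),
                        n_bins=v - u,
                        length_bp=int(grid.bin_widths[member].sum()),
                        mean_level=float(x[u:v].mean()),
                    )
                )
    return segments


def classify_segment(seg: Segment, m: float) -> Segment:
    """Assign the five-level significance class and call type.

    ``m`` is the mean scaled bin count; the single-copy level is m/2.
    """
    if m <= 0:
        raise ValueError("mean bin count must be positive")
    r = abs(seg.mean_level) / (m / 2.0)
    significance = "green"
    for name, min_r, min_bp in _CLASS_RULES:
        if r >= min_r and seg.length_bp >= min_bp:
            significance = name
            break
    if significance == "green":
        call = "neutral"
    else:
        call = "deletion" if seg.mean_level < 0 else "duplication"
    return replace(seg, significance=significance, call_type=call, relative_level=r)


def call_cnvs(
    profile: NormalizedProfile,
    params: CBSParams | None = None,
    chromosomes: list[str] | None = None,
) -> list[Segment]:
    """Segment and classify; non-green segments are the CNV calls."""
    return [
        classify_segment(s, profile.mean_bin_count)
        for s in cbs_segment(profile, params, chromosomes)
    ]


def cnv_calls(segments: list[Segment]) -> list[Segment]:
    return [s for s in segments if s.significance not in (None, "green")]


# ---------------------------------------------------------------------------
# reporting

_TSV_COLUMNS = (
    "chromosome start_bp end_bp start_bin end_bin n_bins length_bp "
    "mean_level relative_level call_type significance"
).split()


def report_calls(
    segments: list[Segment],
    profile: NormalizedProfile,
    tsv_path: str | Path,
    bed_path: str | Path | None = None,
) -> None:
    """Write segments as a machine-readable TSV and a BED file.

    BED rows are 0-based half-open with ``name`` = call type and
    ``score`` = round(1000 × min(relative level, 1)).
    """
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                f"{s.chromosome}\t{s.start_bp}\t{s.end_bp}\t{s.start_bin}\t{s.end_bin}\t"
                f"{s.n_bins}\t{s.length_bp}\t{s.mean_level:.4f}\t{s.relative_level:.4f}\t"
                f"{s.call_type}\t{s.significance}\n"
            )
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            fh.write('track name="cnvscreen_segments"\n')
            for s in segments:
                r = 0.0 if np.isnan(s.relative_level) else s.relative_level
                fh.write(
                    f"{s.chromosome}\t{s.start_bp}\t{s.end_bp}\t{s.call_type}\t"
                    f"{round(1000 * min(r, 1.0))}\t.\n"
                )


_SEG_COLORS = {
    "green": "#2ca02c",
    "yellow": "#e6c700",
    "orange": "#ff7f0e",
    "red": "#d62728",
    "magenta": "#d02090",
    None: "#2ca02c",
}


def plot_chromosome(
    profile: NormalizedProfile,
    segments: list[Segment],
    chromosome: str,
    path: str | Path,
) -> None:
    """Per-chromosome profile plot: bin values, segment means, ±m/2 lines.

    Filtered bins appear as black marks on the zero line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = profile.grid
    sl = grid.chrom_slice(chromosome)  # raises for unknown chromosome
    mid = (grid.start[sl] + grid.end[sl]) / 2e6
    vals = profile.values[sl]
    L = profile.single_copy_level

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(mid, vals, ".", color="0.6", ms=2, rasterized=True)
    filtered = ~np.isfinite(vals)
    if filtered.any():
        ax.plot(mid[filtered], np.zeros(int(filtered.sum())), "|", color="black", ms=8)
    for lvl in (L, -L):
        ax.axhline(lvl, color="#d02090", ls="--", lw=0.8)
    for s in segments:
        if s.chromosome != chromosome:
            continue
        ax.hlines(
            s.mean_level,
            s.start_bp / 1e6,
            s.end_bp / 1e6,
            color=_SEG_COLORS.get(s.significance, "#2ca02c"),
            lw=2.5,
        )
    ax.set_xlabel(f"{chromosome} position (Mb)")
    ax.set_ylabel("normalized bin count")
    ax.set_ylim(-3 * L, 3 * L)
    ax.set_title(f"{profile.sample_id} — {chromosome}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
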