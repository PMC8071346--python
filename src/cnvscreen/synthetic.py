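"""Synthetic low-coverage WGS bin-count data.

Generates reference panels and test samples with the statistical structure
the pipeline assumes so that training, calling and the in-silico grid run
with zero downloads:

* a smooth per-bin GC landscape in [0.3, 0.7] and a multiplicative,
  unimodal GC bias on read rates;
* unmappable regions (zero rate) — one contiguous centromere-like block
  per chromosome plus scattered bins;
* a small fraction of N-heavy bins with undefined GC;
* rank-k cross-sample artifacts: per-bin loading vectors shared by the
  population, multiplied by per-sample factor values on the log-rate
  scale (what the PCA denoising is meant to remove);
* a fraction of highly variable bins with extra per-sample noise (what
  the variance filter is meant to remove);
* Poisson counting noise, with an optional overdispersion knob.

Counts are drawn Poisson with per-sample expected totals equal to
``reads_per_sample``.  Everything is deterministic given the spec seed;
generated truth (mappability, loadings, factors) is returned for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .binning import RawBinCounts
from .genome import BinGrid, GCTrack, build_bin_grid
from .insilico import SimulatedCNV, cnv_bin_range

#: GRCh37 chromosome lengths (bp), autosomes + X + Y.
HG19_CHROM_SIZES: tuple[tuple[str, int], ...] = (
    ("chr1", 249_250_621), ("chr2", 243_199_373), ("chr3", 198_022_430),
    ("chr4", 191_154_276), ("chr5", 180_915_260), ("chr6", 171_115_067),
    ("chr7", 159_138_663), ("chr8", 146_364_022), ("chr9", 141_213_431),
    ("chr10", 135_534_747), ("chr11", 135_006_516), ("chr12", 133_851_895),
    ("chr13", 115_169_878), ("chr14", 107_349_540), ("chr15", 102_531_392),
    ("chr16", 90_354_753), ("chr17", 81_195_210), ("chr18", 78_077_248),
    ("chr19", 59_128_983), ("chr20", 63_025_520), ("chr21", 48_129_895),
    ("chr22", 51_304_566), ("chrX", 155_270_560), ("chrY", 59_373_566),
)

#: ~60 Mb toy genome: 3 autosomes + X + Y; keeps the test suite fast.
TOY_GENOME: tuple[tuple[str, int], ...] = (
    ("chr1", 20_000_000),
    ("chr2", 16_000_000),
    ("chr3", 12_000_000),
    ("chrX", 8_000_000),
    ("chrY", 4_000_000),
)


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Generative model parameters for a synthetic cohort."""

    genome: tuple[tuple[str, int], ...] = TOY_GENOME
    bin_size: int = 20_000
    n_samples: int = 100
    reads_per_sample: float = 5_000_000
    # log-rate GC bias: slope*(gc-0.5) + curvature*(gc-0.5)^2
    gc_slope: float = 1.0
    gc_curvature: float = -4.0
    artifact_rank: int = 3
    artifact_scale: float = 0.05  # per-bin log-rate sd of each factor
    unmappable_fraction: float = 0.10
    centromere_fraction: float = 0.04  # contiguous block, part of unmappable
    undefined_gc_fraction: float = 0.01
    high_variance_fraction: float = 0.02
    high_variance_sd: float = 0.5  # log-rate sd of per-sample jitter
    overdispersion: float = 0.0  # extra lognormal log-sd on every bin
    seed: int = 0

    def __post_init__(self):
        for name in ("unmappable_fraction", "undefined_gc_fraction", "high_variance_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.artifact_rank >= self.n_samples:
            raise ValueError("artifact rank must be smaller than the panel size")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")


def hg19_spec(**overrides) -> SyntheticPanelSpec:
    """A genome-scale spec on GRCh37 chromosome sizes (~155k bins)."""
    kw = {"genome": HG19_CHROM_SIZES, "reads_per_sample": 10_000_000.0}
    kw.update(overrides)
    return SyntheticPanelSpec(**kw)


def make_reference_genome(
    spec: SyntheticPanelSpec,
) -> tuple[BinGrid, GCTrack, dict]:
    """Bin grid, GC track and mappability truth for a spec's genome.

    GC values come from a smoothed spatial noise process rescaled into
    [0.3, 0.7].  Unmappable bins (centromere block + scatter) get zero
    read rate; N-heavy bins get undefined GC and zero rate as well.
    """
    grid = build_bin_grid(spec.genome, spec.bin_size)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))
    gc = np.empty(grid.n_bins)
    mappable = np.ones(grid.n_bins, dtype=bool)
    for name, _ in grid.chromosomes:
        sl = grid.chrom_slice(name)
        n = sl.stop - sl.start
        smooth = gaussian_filter1d(rng.standard_normal(n), sigma=10.0, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        gc[sl] = np.clip(0.5 + 0.08 * smooth, 0.3, 0.7)
        # centromere-like contiguous unmappable block
        width = max(1, int(round(spec.centromere_fraction * n)))
        lo = int(rng.integers(n // 3, max(n // 3 + 1, 2 * n // 3 - width)))
        mappable[sl.start + lo: sl.start + lo + width] = False

    # scattered unmappable bins up to the requested overall fraction
    target_unmappable = int(round(spec.unmappable_fraction * grid.n_bins))
    deficit = target_unmappable - int((~mappable).sum())
    candidates = np.flatnonzero(mappable)
    if deficit > 0 and candidates.size:
        extra = rng.choice(candidates, size=min(deficit, candidates.size), replace=False)
        mappable[extra] = False

    defined_fraction = np.clip(rng.uniform(0.9, 1.0, grid.n_bins), 0, 1)
    n_undef = int(round(spec.undefined_gc_fraction * grid.n_bins))
    if n_undef:
        undef = rng.choice(grid.n_bins, size=n_undef, replace=False)
        defined_fraction[undef] = 0.0
        gc[undef] = np.nan
        mappable[undef] = False

    hv_candidates = np.flatnonzero(mappable)
    n_hv = int(round(spec.high_variance_fraction * grid.n_bins))
    hv_bins = (
        rng.choice(hv_candidates, size=min(n_hv, hv_candidates.size), replace=False)
        if n_hv
        else np.empty(0, dtype=np.int64)
    )

    track = GCTrack(gc=gc, defined_fraction=defined_fraction)
    truth = {"mappable": mappable, "hv_bins": np.sort(hv_bins)}
    return grid, track, truth


def _population(spec: SyntheticPanelSpec, grid: BinGrid, gc: GCTrack, truth: dict):
    """Shared population structure: base log-rates and artifact loadings."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2,)))
    g = np.where(np.isfinite(gc.gc), gc.gc, 0.5) - 0.5
    log_rate = spec.gc_slope * g + spec.gc_curvature * g * g
    base = np.where(truth["mappable"], np.exp(log_rate), 0.0)
    # bin-level (white) loading vectors: recurrent artifacts in low-coverage
    # WGS are dominated by bin-specific mappability/chemistry interactions,
    # not long-range smooth structure
    loadings = spec.artifact_scale * rng.standard_normal(
        (spec.artifact_rank, grid.n_bins)
    )
    return base, loadings


def _draw_sample(
    spec: SyntheticPanelSpec,
    grid: BinGrid,
    base: np.ndarray,
    loadings: np.ndarray,
    hv_bins: np.ndarray,
    rng: np.random.Generator,
    sample_id: str,
    cnv_multiplier: np.ndarray | None = None,
) -> tuple[RawBinCounts, np.ndarray]:
    factors = rng.standard_normal(spec.artifact_rank)
    log_adj = loadings.T @ factors
    if hv_bins.size:
        log_adj[hv_bins] += rng.normal(0.0, spec.high_variance_sd, hv_bins.size)
    if spec.overdispersion > 0:
        log_adj += rng.normal(0.0, spec.overdispersion, grid.n_bins)
    rate = base * np.exp(log_adj)
    if cnv_multiplier is not None:
        rate = rate * cnv_multiplier
    total = rate.sum()
    if total <= 0:
        raise ValueError("degenerate spec: zero total rate")
    expected = rate * (spec.reads_per_sample / total)
    counts = rng.poisson(expected).astype(np.float64)
    raw = RawBinCounts(sample_id=sample_id, counts=counts, grid_fingerprint=grid.fingerprint())
    return raw, factors


def make_panel(
    spec: SyntheticPanelSpec,
    grid: BinGrid | None = None,
    gc: GCTrack | None = None,
    truth: dict | None = None,
) -> tuple[list[RawBinCounts], dict]:
    """Generate a CNV-free reference panel plus generative truth."""
    if grid is None or gc is None or truth is None:
        grid, gc, truth = make_reference_genome(spec)
    base, loadings = _population(spec, grid, gc, truth)
    samples = []
    factors = np.empty((spec.n_samples, spec.artifact_rank))
    for i in range(spec.n_samples):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, i))
        )
        raw, f = _draw_sample(
            spec, grid, base, loadings, truth["hv_bins"], rng, f"panel{i:03d}"
        )
        samples.append(raw)
        factors[i] = f
    panel_truth = dict(truth, base_rate=base, loadings=loadings, factors=factors)
    return samples, panel_truth


def make_case(
    spec: SyntheticPanelSpec,
    cnvs: list[SimulatedCNV] = (),
    case_seed: int = 0,
    sample_id: str | None = None,
    grid: BinGrid | None = None,
    gc: GCTrack | None = None,
    truth: dict | None = None,
) -> tuple[RawBinCounts, dict]:
    """Generate one test sample, optionally carrying planted CNVs.

    CNVs multiply the *expected* counts before Poisson sampling; with an
    empty list the sample is exchangeable with a panel sample (up to its
    own seed).
    """
    if grid is None or gc is None or truth is None:
        grid, gc, truth = make_reference_genome(spec)
    base, loadings = _population(spec, grid, gc, truth)
    mult = np.ones(grid.n_bins)
    for cnv in cnvs:
        lo, hi = cnv_bin_range(cnv, grid)
        mult[lo:hi] *= cnv.multiplier
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(3, case_seed))
    )
    raw, factors = _draw_sample(
        spec, grid, base, loadings, truth["hv_bins"], rng,
        sample_id or f"case{case_seed}",
        cnv_multiplier=None if not len(cnvs) else mult,
    )
    case_truth = dict(truth, factors=factors, cnvs=list(cnvs))
    return raw, case_truth


def make_sequences(
    grid: BinGrid, gc: GCTrack, seed: int = 0
) -> dict[str, str]:
    """Literal chromosome sequences matching a GC track (toy scale only).

    Each bin gets ``round(gc × width)`` G/C bases at random positions;
    bins with undefined GC become runs of N.  Intended for small genomes
    where exercising the sequence → GC path end to end is affordable.
    """
    rng = np.random.default_rng(seed)
    out = {}
    bases_at = np.frombuffer(b"AT", dtype=np.uint8)
    bases_gc = np.frombuffer(b"GC", dtype=np.uint8)
    for name, length in grid.chromosomes:
        sl = grid.chrom_slice(name)
        chrom = np.empty(length, dtype=np.uint8)
        for i in range(sl.start, sl.stop):
            s, e = int(grid.start[i]), int(grid.end[i])
            w = e - s
            if not np.isfinite(gc.gc[i]):
                chrom[s:e] = ord("N")
                continue
            n_gc = int(round(gc.gc[i] * w))
            seg = np.concatenate(
                [rng.choice(bases_gc, n_gc), rng.choice(bases_at, w - n_gc)]
            )
            rng.shuffle(seg)
            chrom[s:e] = seg
        out[name] = chrom.tobytes().decode("ascii")
    return out
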