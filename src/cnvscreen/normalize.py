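"""Reference-panel normalization of scaled bin counts.

A test sample's scaled counts pass through three steps:

1. **GC correction** — a sample-wise LOESS of count on GC fraction is
   fitted over usable autosomal bins; each bin is multiplied by
   ``median(fit) / fit(gc_bin)``.  Multiplicative correction preserves
   non-negativity and the Poisson mean-variance relation.
2. **PCA denoising** — the sample's autosomal bins are projected onto the
   top principal components (15 by default) learned from a panel of
   CNV-free samples, and the reconstruction is subtracted.  This removes
   recurrent cross-sample artifacts (batch effects, residual mappability
   structure) while leaving sample-specific CNV signal, which is nearly
   orthogonal to a low-rank basis learned from CNV-free data.
   Denoising applies to autosomes only.
3. **Centering** — per-bin training means are subtracted so the profile
   fluctuates around zero and a single-copy gain or loss sits near
   ±m/2, where m is the target mean scaled bin count.

Training additionally derives the unusable-bin mask: bins with low mean
(poor mappability), high mean (repeats / systematic over-mapping), high
variance across the panel, or undefined GC.  An optional user-supplied
exclusion BED is merged in with reason ``manual``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .binning import ScaledBinCounts, RawBinCounts, scale_compartments
from .genome import AUTOSOME, BinGrid, GCTrack

logger = logging.getLogger(__name__)

FORMAT_TAG = "cnvscreen-refmodel-1"

# mask reason codes
USABLE = 0
REASON_UNDEFINED_GC = 1
REASON_LOW_MEAN = 2
REASON_HIGH_MEAN = 3
REASON_HIGH_VARIANCE = 4
REASON_MANUAL = 5

REASON_NAMES = {
    USABLE: "usable",
    REASON_UNDEFINED_GC: "undefined_gc",
    REASON_LOW_MEAN: "low_mean",
    REASON_HIGH_MEAN: "high_mean",
    REASON_HIGH_VARIANCE: "high_variance",
    REASON_MANUAL: "manual",
}


@dataclass
class NormalizationConfig:
    """Tunable parameters of training and normalization."""

    n_components: int = 15
    loess_span: float = 0.3
    loess_min_bins: int = 1000
    loess_max_fit_bins: int = 20_000
    # filtration thresholds, relative to the median over bins
    low_mean_factor: float = 0.25
    high_mean_factor: float = 2.0
    high_variance_factor: float = 3.0
    min_training_samples: int = 100

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "NormalizationConfig":
        return cls(**json.loads(s))


def loess_gc_correct(
    scaled: ScaledBinCounts,
    gc: GCTrack,
    grid: BinGrid,
    span: float = 0.3,
    usable: np.ndarray | None = None,
    min_bins: int = 1000,
    max_fit_bins: int = 20_000,
) -> ScaledBinCounts:
    """Sample-wise multiplicative LOESS GC correction.

    The curve is fitted on autosomal bins with defined GC and a positive
    count (zero-count bins carry no GC information and would drag the fit
    toward zero near unmappable regions); when ``usable`` is given the fit
    is additionally restricted to those bins.  The fitted curve is applied
    to *all* compartments — X and Y bins share the same GC physics, while
    fitting on autosomes avoids copy-number effects of the sex chromosomes.

    Bins with undefined GC, or where the fitted value is not positive, are
    left uncorrected and flagged in ``gc_uncorrected``.
    """
    values = scaled.values
    fit_sel = grid.autosomal & gc.defined & np.isfinite(values) & (values > 0)
    if usable is not None:
        fit_sel &= usable
    n_fit = int(fit_sel.sum())
    if n_fit < min_bins:
        raise ValueError(
            f"only {n_fit} bins available for the GC fit (need >= {min_bins})"
        )

    x = gc.gc[fit_sel]
    y = values[fit_sel]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x.size > max_fit_bins:
        # deterministic thinning, even coverage of the GC range
        pick = np.linspace(0, x.size - 1, max_fit_bins).astype(np.int64)
        x, y = x[pick], y[pick]
    delta = (x[-1] - x[0]) / 200.0 if x[-1] > x[0] else 0.0
    fitted = lowess(y, x, frac=span, it=1, delta=delta, return_sorted=True)
    fx, fy = fitted[:, 0], fitted[:, 1]

    defined = gc.defined
    fit_at_bin = np.full(grid.n_bins, np.nan)
    fit_at_bin[defined] = np.interp(gc.gc[defined], fx, fy)
    reference = float(np.median(fy))
    good = defined & np.isfinite(fit_at_bin) & (fit_at_bin > 0)

    corrected = np.array(values, dtype=np.float64)
    corrected[good] = values[good] * (reference / fit_at_bin[good])
    flagged = ~good
    return replace(scaled, values=corrected, gc_uncorrected=flagged)


@dataclass
class ReferenceModel:
    """Trained normalization state.

    ``components`` is an orthonormal (k × n_usable_autosomal) PCA basis over
    the usable autosomal bins, with ``pca_mean`` the panel centering vector
    on the same bins.  ``bin_means`` holds the per-bin training mean on the
    scale the test sample reaches just before centering: PCA-denoised for
    autosomes, GC-corrected for chrX/chrY; NaN at filtered bins.
    """

    grid_fingerprint: str
    bin_size: int
    chromosomes: tuple[tuple[str, int], ...]
    components: np.ndarray  # (k, n_usable_auto)
    pca_mean: np.ndarray  # (n_usable_auto,)
    usable_auto_idx: np.ndarray  # global indices of usable autosomal bins
    bin_means: np.ndarray  # (n_bins,)
    mask_reason: np.ndarray  # (n_bins,) uint8, 0 = usable
    targets: dict[int, float]
    n_training_samples: int
    config: NormalizationConfig = field(default_factory=NormalizationConfig)
    training_bin_mean: np.ndarray | None = None
    training_bin_sd: np.ndarray | None = None

    @property
    def usable(self) -> np.ndarray:
        return self.mask_reason == USABLE

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "format": FORMAT_TAG,
            "grid_fingerprint": self.grid_fingerprint,
            "bin_size": self.bin_size,
            "chromosomes": [[n, l] for n, l in self.chromosomes],
            "targets": {str(k): v for k, v in self.targets.items()},
            "n_training_samples": self.n_training_samples,
            "config": self.config.__dict__,
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            components=self.components,
            pca_mean=self.pca_mean,
            usable_auto_idx=self.usable_auto_idx,
            bin_means=self.bin_means,
            mask_reason=self.mask_reason,
            training_bin_mean=self.training_bin_mean if self.training_bin_mean is not None else np.empty(0),
            training_bin_sd=self.training_bin_sd if self.training_bin_sd is not None else np.empty(0),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if meta.get("format") != FORMAT_TAG:
                raise ValueError(f"unrecognized model format: {meta.get('format')!r}")
            tm = z["training_bin_mean"]
            ts = z["training_bin_sd"]
            return cls(
                grid_fingerprint=meta["grid_fingerprint"],
                bin_size=int(meta["bin_size"]),
                chromosomes=tuple((n, int(l)) for n, l in meta["chromosomes"]),
                components=z["components"],
                pca_mean=z["pca_mean"],
                usable_auto_idx=z["usable_auto_idx"],
                bin_means=z["bin_means"],
                mask_reason=z["mask_reason"],
                targets={int(k): float(v) for k, v in meta["targets"].items()},
                n_training_samples=int(meta["n_training_samples"]),
                config=NormalizationConfig(**meta["config"]),
                training_bin_mean=tm if tm.size else None,
                training_bin_sd=ts if ts.size else None,
            )


def model_mean_bin_count(model: ReferenceModel, grid: BinGrid) -> float:
    """Target mean scaled bin count m for the autosomal compartment."""
    n_auto = int((grid.compartment == AUTOSOME).sum())
    return model.targets[AUTOSOME] / n_auto


@dataclass
class NormalizedProfile:
    """Zero-centered per-bin values for one sample.

    Filtered bins hold NaN and are flagged in ``mask_reason``; they are
    excluded from all downstream statistics.  ``mean_bin_count`` m is the
    compartment target mean on the scaled scale; the expected level of a
    single-copy gain/loss is ±m/2.
    """

    sample_id: str
    values: np.ndarray
    mask_reason: np.ndarray
    mean_bin_count: float
    grid: BinGrid

    @property
    def usable(self) -> np.ndarray:
        return self.mask_reason == USABLE

    @property
    def single_copy_level(self) -> float:
        return self.mean_bin_count / 2.0


def derive_filter_mask(
    panel_matrix: np.ndarray,
    gc: GCTrack,
    config: NormalizationConfig,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Per-bin mask reasons from panel statistics (GC-corrected scale).

    A bin is filtered when its training mean is below
    ``low_mean_factor × median(mean)``, above ``high_mean_factor × median``,
    or its training standard deviation exceeds
    ``high_variance_factor × median(sd)``; medians are taken over bins with
    defined GC.  Tightening any threshold can only filter more bins.
    """
    n_bins = panel_matrix.shape[1]
    reason = np.zeros(n_bins, dtype=np.uint8)
    reason[~gc.defined] = REASON_UNDEFINED_GC

    means = np.nanmean(panel_matrix, axis=0)
    sds = np.nanstd(panel_matrix, axis=0, ddof=1) if panel_matrix.shape[0] > 1 else np.zeros(n_bins)
    ok = reason == USABLE
    med_mean = float(np.median(means[ok & np.isfinite(means)]))
    pos_sd = sds[ok & np.isfinite(sds) & (sds > 0)]
    med_sd = float(np.median(pos_sd)) if pos_sd.size else 0.0

    with np.errstate(invalid="ignore"):
        low = ok & ~(means >= config.low_mean_factor * med_mean)  # catches NaN too
        high = ok & (means > config.high_mean_factor * med_mean)
        hivar = ok & (med_sd > 0) & (sds > config.high_variance_factor * med_sd)
    reason[low] = REASON_LOW_MEAN
    reason[high & (reason == USABLE)] = REASON_HIGH_MEAN
    reason[hivar & (reason == USABLE)] = REASON_HIGH_VARIANCE
    if exclude is not None:
        reason[exclude & (reason == USABLE)] = REASON_MANUAL
    return reason


def read_exclusion_bed(path: str | Path, grid: BinGrid) -> np.ndarray:
    """Per-bin boolean mask of bins overlapping intervals of a BED file."""
    mask = np.zeros(grid.n_bins, dtype=bool)
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        try:
            sl = grid.chrom_slice(chrom)
        except KeyError:
            continue
        lo = sl.start + int(start) // grid.bin_size
        hi = sl.start + (int(end) - 1) // grid.bin_size + 1
        mask[max(lo, sl.start): min(hi, sl.stop)] = True
    return mask


def train_reference_model(
    panel: list[ScaledBinCounts],
    gc: GCTrack,
    grid: BinGrid,
    config: NormalizationConfig | None = None,
    exclude: np.ndarray | None = None,
) -> ReferenceModel:
    """Train the normalization state from GC-corrected panel samples.

    The panel must be CNV-free ("non-aberrated") samples on one grid; at
    least 100 are recommended — smaller panels over-filter bins through the
    variance rule and weaken the PCA basis (a warning is emitted).
    """
    if config is None:
        config = NormalizationConfig()
    if len(panel) < 2:
        raise ValueError("need at least 2 panel samples")
    fps = {s.grid_fingerprint for s in panel}
    if fps != {grid.fingerprint()}:
        raise ValueError("panel samples and grid disagree")
    if len(panel) < config.min_training_samples:
        warnings.warn(
            f"training on {len(panel)} samples; at least "
            f"{config.min_training_samples} recommended",
            stacklevel=2,
        )

    M = np.vstack([s.values for s in panel])  # (n_samples, n_bins)
    reason = derive_filter_mask(M, gc, config, exclude=exclude)
    usable = reason == USABLE

    # PCA over usable autosomal bins
    usable_auto = usable & grid.autosomal
    usable_auto_idx = np.flatnonzero(usable_auto)
    A = M[:, usable_auto_idx]
    k = min(config.n_components, len(panel) - 1, usable_auto_idx.size)
    if k < config.n_components:
        warnings.warn(
            f"panel supports only {k} principal components "
            f"(requested {config.n_components})",
            stacklevel=2,
        )
    pca_mean = A.mean(axis=0)
    Ac = A - pca_mean
    # economy SVD: n_samples << n_bins
    _, _, Vt = np.linalg.svd(Ac, full_matrices=False)
    components = Vt[:k] if k > 0 else np.empty((0, usable_auto_idx.size))

    # per-bin training means: PCA-denoised for autosomes, GC-corrected for X/Y
    bin_means = np.full(grid.n_bins, np.nan)
    if k > 0:
        recon = pca_mean + (Ac @ components.T) @ components
    else:
        recon = np.broadcast_to(pca_mean, A.shape)
    denoised = A - recon
    bin_means[usable_auto_idx] = denoised.mean(axis=0)
    sex_usable = usable & ~grid.autosomal
    bin_means[sex_usable] = M[:, sex_usable].mean(axis=0)

    return ReferenceModel(
        grid_fingerprint=grid.fingerprint(),
        bin_size=grid.bin_size,
        chromosomes=grid.chromosomes,
        components=components,
        pca_mean=pca_mean,
        usable_auto_idx=usable_auto_idx,
        bin_means=bin_means,
        mask_reason=reason,
        targets=dict(panel[0].targets),
        n_training_samples=len(panel),
        config=config,
        training_bin_mean=np.nanmean(M, axis=0),
        training_bin_sd=np.nanstd(M, axis=0, ddof=1),
    )


def pca_denoise(sample: ScaledBinCounts, model: ReferenceModel) -> np.ndarray:
    """Remove the panel-PCA reconstruction from a sample's autosomal bins.

    Returns a full-length value vector: for usable autosomal bins
    ``x − (μ + VᵀV(x − μ))``; chrX/chrY (and filtered) bins pass through
    unchanged.
    """
    if sample.grid_fingerprint != model.grid_fingerprint:
        raise ValueError("sample and model were built on different grids")
    out = np.array(sample.values, dtype=np.float64)
    idx = model.usable_auto_idx
    x = out[idx]
    xc = x - model.pca_mean
    if model.components.shape[0] > 0:
        recon = model.pca_mean + model.components.T @ (model.components @ xc)
    else:
        recon = model.pca_mean
    out[idx] = x - recon
    return out


def center_profile(
    values: np.ndarray,
    model: ReferenceModel,
    grid: BinGrid,
    sample_id: str = "sample",
) -> NormalizedProfile:
    """Subtract per-bin training means and apply the filter mask."""
    out = values - model.bin_means  # NaN at filtered bins by construction
    out[~model.usable] = np.nan
    return NormalizedProfile(
        sample_id=sample_id,
        values=out,
        mask_reason=model.mask_reason.copy(),
        mean_bin_count=model_mean_bin_count(model, grid),
        grid=grid,
    )


def normalize_sample(
    raw: RawBinCounts,
    gc: GCTrack,
    model: ReferenceModel,
    grid: BinGrid,
) -> NormalizedProfile:
    """Full chain: compartment scaling → GC LOESS → PCA denoise → center."""
    scaled = scale_compartments(raw, grid, targets=model.targets)
    cfg = model.config
    corrected = loess_gc_correct(
        scaled,
        gc,
        grid,
        span=cfg.loess_span,
        usable=model.usable,
        min_bins=cfg.loess_min_bins,
        max_fit_bins=cfg.loess_max_fit_bins,
    )
    denoised = pca_denoise(corrected, model)
    return center_profile(denoised, model, grid, sample_id=raw.sample_id)


def write_mask_bed(path: str | Path, model: ReferenceModel, grid: BinGrid) -> None:
    """Filtered bins as BED with the filter reason in column 4."""
    names = np.asarray(grid.chrom_names, dtype=object)
    with open(path, "w") as fh:
        for i in np.flatnonzero(model.mask_reason != USABLE):
            fh.write(
                f"{names[grid.chrom_index[i]]}\t{grid.start[i]}\t{grid.end[i]}\t"
                f"{REASON_NAMES[int(model.mask_reason[i])]}\n"
            )
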