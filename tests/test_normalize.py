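"""GC correction, reference-model training, PCA denoising, centering."""

import warnings

import numpy as np
import pytest

from cnvscreen.binning import ScaledBinCounts, scale_compartments
from cnvscreen.genome import AUTOSOME, build_bin_grid, GCTrack
from cnvscreen.normalize import (
    REASON_LOW_MEAN,
    REASON_MANUAL,
    USABLE,
    NormalizationConfig,
    ReferenceModel,
    derive_filter_mask,
    loess_gc_correct,
    model_mean_bin_count,
    normalize_sample,
    pca_denoise,
    train_reference_model,
)
from cnvscreen.synthetic import make_case
from cnvscreen.insilico import SimulatedCNV, cnv_bin_range


def _scaled(grid, values):
    return ScaledBinCounts(
        sample_id="s",
        values=np.asarray(values, float),
        grid_fingerprint=grid.fingerprint(),
        scale_factors={},
        targets={AUTOSOME: float(np.sum(values))},
    )


class TestLoessGCCorrect:
    def test_constant_counts_identity(self, toy_grid, toy_gc):
        vals = np.full(toy_grid.n_bins, 100.0)
        out = loess_gc_correct(_scaled(toy_grid, vals), toy_gc, toy_grid)
        good = ~out.gc_uncorrected
        np.testing.assert_allclose(out.values[good], 100.0, rtol=1e-6)

    def test_gc_slope_shrinks_tenfold(self, toy_grid, toy_gc):
        """A linear count-GC trend is reduced >=10x by the correction."""
        g = np.where(np.isfinite(toy_gc.gc), toy_gc.gc, 0.5)
        vals = 100.0 * (0.5 + g)
        out = loess_gc_correct(_scaled(toy_grid, vals), toy_gc, toy_grid)
        sel = toy_gc.defined & toy_grid.autosomal
        slope_before = np.polyfit(g[sel], vals[sel], 1)[0]
        slope_after = np.polyfit(g[sel], out.values[sel], 1)[0]
        assert abs(slope_after) < abs(slope_before) / 10

    def test_identical_gc_identical_counts_same_correction(self):
        grid = build_bin_grid([("chr1", 40_000_000)], 20_000)
        rng = np.random.default_rng(0)
        gc_vals = rng.uniform(0.35, 0.65, grid.n_bins)
        gc_vals[10] = gc_vals[20] = 0.5
        gc = GCTrack(gc=gc_vals, defined_fraction=np.ones(grid.n_bins))
        vals = rng.poisson(100, grid.n_bins).astype(float)
        vals[10] = vals[20] = 123.0
        out = loess_gc_correct(_scaled(grid, vals), gc, grid)
        assert out.values[10] == pytest.approx(out.values[20])

    def test_undefined_gc_flagged_not_corrected(self, toy_grid, toy_gc):
        vals = np.full(toy_grid.n_bins, 50.0)
        out = loess_gc_correct(_scaled(toy_grid, vals), toy_gc, toy_grid)
        und = ~toy_gc.defined
        assert out.gc_uncorrected[und].all()
        np.testing.assert_array_equal(out.values[und], vals[und])

    def test_too_few_bins_raises(self):
        grid = build_bin_grid([("chr1", 200_000)], 20_000)
        gc = GCTrack(gc=np.full(10, 0.5), defined_fraction=np.ones(10))
        with pytest.raises(ValueError, match="GC fit"):
            loess_gc_correct(_scaled(grid, np.ones(10)), gc, grid, min_bins=1000)


class TestTrainReferenceModel:
    def test_identical_samples_give_their_own_means(self, toy_grid, toy_gc):
        vals = np.abs(np.random.default_rng(1).normal(100, 5, toy_grid.n_bins))
        panel = [_scaled(toy_grid, vals) for _ in range(5)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_reference_model(panel, toy_gc, toy_grid)
        # autosomal means are on the denoised scale (residuals ~ 0);
        # chrX/chrY means equal the common sample
        sex = model.usable & ~toy_grid.autosomal
        np.testing.assert_allclose(model.bin_means[sex], vals[sex], rtol=1e-9)
        auto = model.usable & toy_grid.autosomal
        np.testing.assert_allclose(model.bin_means[auto], 0.0, atol=1e-8)

    def test_always_zero_bin_filtered_low_mean(self, toy_grid, toy_gc):
        rng = np.random.default_rng(2)
        panel = []
        for _ in range(6):
            v = rng.poisson(100, toy_grid.n_bins).astype(float)
            v[5] = 0.0
            panel.append(_scaled(toy_grid, v))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_reference_model(panel, toy_gc, toy_grid)
        assert model.mask_reason[5] == REASON_LOW_MEAN

    def test_planted_rank3_artifacts_captured(self, toy_model, toy_corrected, toy_panel, toy_grid):
        """First 3 PCs account for >=99% of the planted 3-factor energy.

        The planted artifact is log-linear, so its linear-space signal (what
        PCA sees) is its noiseless expected effect after per-sample total
        scaling; the variance the first 3 components explain must cover it.
        """
        idx = toy_model.usable_auto_idx
        truth = toy_panel[1]
        # noiseless per-sample expected counts given the planted factors
        E = truth["base_rate"][None, :] * np.exp(truth["factors"] @ truth["loadings"])
        E *= toy_model.targets[AUTOSOME] / E[:, toy_grid.autosomal].sum(axis=1, keepdims=True)
        A = E[:, idx]
        A -= A.mean(axis=0)
        planted_energy = (A**2).sum()
        M = np.vstack([s.values for s in toy_corrected])[:, idx]
        M -= M.mean(axis=0)
        V3 = toy_model.components[:3]
        explained = ((M @ V3.T) ** 2).sum()
        assert explained >= 0.99 * planted_energy
        # and the components point at the planted subspace, not at noise
        alignment = ((A @ V3.T) ** 2).sum() / (A**2).sum()
        assert alignment >= 0.95

    def test_components_orthonormal(self, toy_model):
        G = toy_model.components @ toy_model.components.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-9)

    def test_mask_monotone_in_thresholds(self, toy_corrected, toy_gc):
        M = np.vstack([s.values for s in toy_corrected])
        loose = NormalizationConfig(low_mean_factor=0.1, high_mean_factor=3.0, high_variance_factor=5.0)
        tight = NormalizationConfig(low_mean_factor=0.3, high_mean_factor=1.8, high_variance_factor=2.5)
        m_loose = derive_filter_mask(M, toy_gc, loose) != USABLE
        m_tight = derive_filter_mask(M, toy_gc, tight) != USABLE
        assert (m_loose <= m_tight).all()  # tightening never unfilters

    def test_manual_exclusion_merged(self, toy_corrected, toy_gc, toy_grid):
        exclude = np.zeros(toy_grid.n_bins, bool)
        # pick bins that would otherwise be usable
        base = derive_filter_mask(
            np.vstack([s.values for s in toy_corrected]), toy_gc, NormalizationConfig()
        )
        target = np.flatnonzero(base == USABLE)[:3]
        exclude[target] = True
        reason = derive_filter_mask(
            np.vstack([s.values for s in toy_corrected]), toy_gc,
            NormalizationConfig(), exclude=exclude,
        )
        assert (reason[target] == REASON_MANUAL).all()

    def test_too_small_panel_raises(self, toy_gc, toy_grid):
        with pytest.raises(ValueError, match="at least 2"):
            train_reference_model([], toy_gc, toy_grid)


class TestPCADenoise:
    def test_sample_in_span_reduced_to_zero_deviation(self, toy_model, toy_grid):
        idx = toy_model.usable_auto_idx
        coef = np.array([3.0, -2.0, 1.0])
        vals = np.zeros(toy_grid.n_bins)
        vals[idx] = toy_model.pca_mean + coef @ toy_model.components[:3]
        sample = _scaled(toy_grid, vals)
        sample.targets = dict(toy_model.targets)
        out = pca_denoise(sample, toy_model)
        np.testing.assert_allclose(out[idx], 0.0, atol=1e-8)

    def test_orthogonal_sample_unchanged(self, toy_model, toy_grid):
        idx = toy_model.usable_auto_idx
        rng = np.random.default_rng(3)
        dev = rng.normal(0, 1, idx.size)
        dev -= toy_model.components.T @ (toy_model.components @ dev)
        vals = np.zeros(toy_grid.n_bins)
        vals[idx] = toy_model.pca_mean + dev
        sample = _scaled(toy_grid, vals)
        out = pca_denoise(sample, toy_model)
        np.testing.assert_allclose(out[idx], dev, atol=1e-8)

    def test_fingerprint_mismatch_raises(self, toy_model):
        other = build_bin_grid([("chr1", 100_000)], 20_000)
        sample = _scaled(other, np.ones(other.n_bins))
        with pytest.raises(ValueError, match="different grids"):
            pca_denoise(sample, toy_model)

    def test_planted_cnv_survives_denoising(self, toy_spec, toy_genome, toy_model):
        """PCA removal must not swallow a 50-bin +50% duplication."""
        grid, gc, truth = toy_genome
        cnv = SimulatedCNV("chr2", 2_000_000, 3_000_000, 1.5)
        case, _ = make_case(toy_spec, [cnv], case_seed=11, grid=grid, gc=gc, truth=truth)
        scaled = scale_compartments(case, grid, targets=toy_model.targets)
        corrected = loess_gc_correct(scaled, gc, grid, usable=toy_model.usable)
        lo, hi = cnv_bin_range(cnv, grid)
        sel = np.zeros(grid.n_bins, bool)
        sel[lo:hi] = True
        sel &= toy_model.usable
        before = (corrected.values[sel] - toy_model.training_bin_mean[sel]).mean()
        out = pca_denoise(corrected, toy_model)
        after = (out[sel] - toy_model.bin_means[sel]).mean()
        assert abs(after - before) / abs(before) < 0.10


class TestCenterAndFullChain:
    def test_training_sample_centers_near_zero(self, toy_panel, toy_genome, toy_model):
        grid, gc, _ = toy_genome
        raw = toy_panel[0][0]
        prof = normalize_sample(raw, gc, toy_model, grid)
        for name, _ in grid.chromosomes:
            sl = grid.chrom_slice(name)
            v = prof.values[sl]
            v = v[np.isfinite(v)]
            se = v.std(ddof=1) / np.sqrt(v.size)
            assert abs(v.mean()) < 3 * se + 1e-9

    def test_filtered_bins_flagged_nan(self, toy_panel, toy_genome, toy_model):
        grid, gc, _ = toy_genome
        prof = normalize_sample(toy_panel[0][0], gc, toy_model, grid)
        assert np.isnan(prof.values[~toy_model.usable]).all()
        assert np.isfinite(prof.values[toy_model.usable]).all()

    def test_het_deletion_sits_at_minus_half_m(self, toy_spec, toy_genome, toy_model):
        grid, gc, truth = toy_genome
        cnv = SimulatedCNV("chr1", 5_000_000, 6_000_000, 0.5)
        case, _ = make_case(toy_spec, [cnv], case_seed=21, grid=grid, gc=gc, truth=truth)
        prof = normalize_sample(case, gc, toy_model, grid)
        lo, hi = cnv_bin_range(cnv, grid)
        seg = prof.values[lo:hi]
        m = prof.mean_bin_count
        observed = np.nanmean(seg)
        assert observed == pytest.approx(-m / 2, rel=0.15)

    def test_mean_bin_count_is_autosomal_target_mean(self, toy_model, toy_grid):
        m = model_mean_bin_count(toy_model, toy_grid)
        n_auto = int(toy_grid.autosomal.sum())
        assert m == pytest.approx(toy_model.targets[AUTOSOME] / n_auto)


class TestSerialization:
    def test_roundtrip_bit_identical_profiles(self, tmp_path, toy_panel, toy_genome, toy_model):
        grid, gc, _ = toy_genome
        path = tmp_path / "model.npz"
        toy_model.save(path)
        loaded = ReferenceModel.load(path)
        raw = toy_panel[0][1]
        a = normalize_sample(raw, gc, toy_model, grid)
        b = normalize_sample(raw, gc, loaded, grid)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(toy_model.mask_reason, loaded.mask_reason)
        np.testing.assert_array_equal(toy_model.components, loaded.components)
        assert loaded.targets == toy_model.targets

    def test_format_tag_checked(self, tmp_path, toy_model):
        path = tmp_path / "model.npz"
        np.savez(path, meta=np.frombuffer(b'{"format": "other"}', dtype=np.uint8))
        with pytest.raises(ValueError, match="format"):
            ReferenceModel.load(path)
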