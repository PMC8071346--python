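"""Train on a synthetic panel and call a planted deletion.

Generates a ~60 Mb toy cohort (40 CNV-free samples), trains the
normalization model (GC LOESS + panel PCA + per-bin means + filter mask),
plants a heterozygous 200 kb deletion in a fresh sample and calls it.
"""

import warnings

from cnvscreen import (
    CBSParams,
    SimulatedCNV,
    SyntheticPanelSpec,
    call_cnvs,
    make_case,
    make_panel,
    make_reference_genome,
    normalize_sample,
    plot_chromosome,
    train_reference_model,
)
from cnvscreen.binning import scale_compartments
from cnvscreen.normalize import loess_gc_correct

spec = SyntheticPanelSpec(n_samples=40, seed=7)
grid, gc, truth = make_reference_genome(spec)
panel, _ = make_panel(spec, grid, gc, truth)

corrected = [loess_gc_correct(scale_compartments(s, grid), gc, grid) for s in panel]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # toy panel is smaller than the recommended 100
    model = train_reference_model(corrected, gc, grid)
print(f"trained on {len(panel)} samples; "
      f"{(~model.usable).mean():.1%} of bins filtered as unusable")

# a heterozygous deletion: one of two copies lost -> counts x 0.5
cnv = SimulatedCNV("chr1", 5_000_000, 5_200_000, multiplier=0.5)
case, _ = make_case(spec, [cnv], case_seed=42, grid=grid, gc=gc, truth=truth)
profile = normalize_sample(case, gc, model, grid)

segments = call_cnvs(profile, CBSParams(n_permutations=1000, rng_seed=1))
print(f"\n{len(segments)} segments; single-copy level = ±{profile.single_copy_level:.0f}")
for s in segments:
    if s.significance != "green":
        print(f"  {s.chromosome}:{s.start_bp:,}-{s.end_bp:,}  "
              f"mean {s.mean_level:+.1f} ({s.relative_level:.0%} of single-copy level) "
              f"-> {s.call_type}, {s.significance}")

# The call should cover chr1:5,000,000-5,200,000 with a mean near -50
# (half the mean bin count of 100) and red/orange significance.
plot_chromosome(profile, segments, "chr1", "toy_chr1.png")
print("\nwrote toy_chr1.png (bin values, segment means, ±m/2 guides)")
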