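"""A scaled-down in-silico accuracy grid on the toy genome.

Downsamples a CNV-free sample to several depths, injects random
single-copy CNVs one at a time (multiplying the affected bins by 0.5 or
1.5), reruns the unchanged caller and tabulates detection and boundary
accuracy.  The genome-scale version of this experiment is what
scripts/acceptance.py runs.
"""

import warnings

from cnvscreen import (
    CBSParams,
    SyntheticPanelSpec,
    make_case,
    make_panel,
    make_reference_genome,
    run_grid,
    train_reference_model,
)
from cnvscreen.binning import scale_compartments
from cnvscreen.insilico import accuracy_frame
from cnvscreen.normalize import loess_gc_correct

spec = SyntheticPanelSpec(n_samples=40, seed=7)
grid, gc, truth = make_reference_genome(spec)
panel, _ = make_panel(spec, grid, gc, truth)
corrected = [loess_gc_correct(scale_compartments(s, grid), gc, grid) for s in panel]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = train_reference_model(corrected, gc, grid)

base, _ = make_case(spec, [], case_seed=9, grid=grid, gc=gc, truth=truth)

cells = run_grid(
    [base], model, gc, grid,
    lengths=[40_000, 100_000],          # 2 and 5 bins
    read_counts=[1_000_000, 3_000_000],
    n_variants=25,
    cbs_params=CBSParams(n_permutations=500),
    seed=11,
)
print(accuracy_frame(cells).to_string(index=False))

# Detection rises with both CNV length and depth; the exact-boundary
# fraction trails detection because boundary placement needs each edge
# bin to clear half the single-copy level.
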