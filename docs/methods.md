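# Methods

## Data model and coordinate conventions

The unit of data is the count of read starts in a fixed-width genomic bin
(default 20 kb).  Coordinates are 0-based, half-open everywhere; BED
output follows BED conventions.  Bins tile each chromosome exactly; the
terminal bin may be truncated and is kept (low-mean filtration removes it
if it misbehaves).  Canonical chromosomes 1–22, X, Y form the grid by
default; chrM and non-canonical contigs are excluded unless whitelisted.
Chromosomes belong to one of three compartments — autosomes, chrX, chrY —
because count scaling and PCA training treat them differently.

Only a read's position and mapping quality are used: mates of a pair are
counted independently by their leftmost mapped base; records that are
unmapped, secondary, supplementary, duplicate-flagged, or below
MAPQ 40 are discarded.  Whether the original mates-vs-fragments
convention matters is moot at the depths involved; counting mates is the
simplest faithful reading of "binned by their starts".

## Power model

Sequencing is modelled as drawing n reads uniformly from a mappable
genome of length lg, so the count in a region of length lc is
binomial with p = lc/lg, mean np and variance np(1 − p).  A single-copy
gain or loss shifts the expected region count to n(p ± p/2); the
resulting detection Z-score obeys Z² = n·lc / (4(lg − lc)), identical for
gain and loss.  Inverting gives the minimal read count
n ≥ 4Z²(lg − lc)/lc and minimal detectable length
lc = 4Z²·lg / (n + 4Z²).  The default lg is 3.1 × 10⁹ bp (human-genome
scale); it is a parameter, and the model deliberately ignores
overdispersion, mappability loss and GC structure — it is a lower bound
on real requirements.

## Normalization

**Compartment scaling.**  Each sample's autosomal bins are scaled to sum
to (number of autosomal bins) × 100, and chrX/chrY likewise,
independently.  The constant fixes the mean scaled bin count at m = 100,
making the single-copy level m/2 = 50 comparable across samples.  A
compartment with zero reads is flagged unusable, not divided by zero.

**GC correction.**  Per sample, a LOESS curve (span 0.3, one robustness
iteration) of scaled count on GC fraction is fitted over autosomal bins
with defined GC and a positive count — zero-count bins carry no GC
information and would drag the curve down near unmappable regions.  For
speed the fit uses a deterministic GC-sorted thinning to ≤ 20,000 points
and statsmodels' `delta` linear-interpolation acceleration; fitted values
are interpolated to every bin.  Each bin is multiplied by
median(fit)/fit(gc): a multiplicative correction preserves
non-negativity and the Poisson mean–variance relation (an additive one
would not).  The autosomal curve is applied to X and Y as well — the GC
physics is shared, while fitting on autosomes avoids sex-chromosome copy
effects.  Bins with undefined GC (< 50% non-N bases) or a non-positive
fitted value pass through unchanged and are flagged.

**Unusable-bin mask.**  From the GC-corrected panel: a bin is filtered
when its training mean is < 0.25× or > 2.0× the median training mean, or
its training SD exceeds 3.0× the median SD (all three configurable).
These scale-free defaults express the intended reasons — poor
mappability, repeat pile-ups, and erratic regions — without hard-coded
counts.  Bins with undefined GC are filtered outright.  Manual curation
is replaced by an optional user-supplied exclusion BED merged into the
mask with reason `manual`, because a file is reproducible and curation is
not.  On default synthetic cohorts ~13% of the genome is masked.

**PCA denoising.**  PCA is fitted on the usable autosomal bins of the
corrected panel (mask first, then PCA — garbage bins would otherwise
donate spurious variance to the basis); the first 15 components and the
centering vector are stored.  A test sample's autosomal vector x becomes
x − (μ + VᵀV(x − μ)).  CNV signal in a test sample is essentially
orthogonal to a low-rank basis learned from CNV-free data, so planted
segments survive denoising (verified by test).  chrX/chrY are not
denoised — the reference-panel composition does not support a
sex-chromosome basis — so their per-bin means are trained on GC-corrected
values instead, and sex-chromosome calls are accordingly noisier.

**Centering.**  Per-bin training means (post-PCA where available) are
subtracted; filtered bins are NaN, never silently zero.  Training
requires ≥ 2 samples and warns below 100: small panels over-filter
through the variance rule and weaken the basis.

The trained state (grid fingerprint, basis, means, mask with reasons,
targets, config) serializes to a single `.npz` archive with a format tag;
round-trips are bit-exact.

## Segmentation

Each chromosome's unfiltered bins are segmented by circular binary
segmentation.  The statistic for an arc [i, j) of the circularized
series versus its complement is the standardized mean difference
|C_j − C_i| / (s·√(k(n−k)/n)) with C the centred cumulative sums; the
exact search covers every arc width k ≤ n/2 at every position (wrapped
arcs included), with a range-bound early exit.  A split is accepted when
its permutation p-value is below alpha (default 0.01); recursion
continues on each resulting piece.  Numerical choices:

* **Permutation test.**  Exceedances count ties (the observed labelling
  is itself a permutation), with a 10⁻⁹ relative tolerance absorbing
  floating-point round-trip error — without it, symmetric small pieces
  are spuriously split.  Sequential early stopping rejects a split as
  soon as exceedances exceed alpha·n_permutations and accepts after
  ⌈2/alpha⌉ permutations with none.  For series longer than 1,024 bins
  the per-permutation maximum is taken over a geometric ladder of arc
  widths (all widths ≤ 16, then ×1.25 steps) and the observed statistic
  entering the test is maximized over the same family, which keeps the
  test a valid permutation test of the restricted-family maximum while
  making genome-scale segmentation affordable; split locations always
  come from the exact search.  Default n_permutations is 10,000; the
  genome-scale study uses 500, which still resolves alpha = 0.01.
* **Outlier smoothing.**  Before segmentation, a bin whose residual from
  its ±2-bin running median exceeds 4 robust SDs (1.4826 × MAD) is pulled
  to the median ± 2 SDs — unless an adjacent bin is extreme in the same
  direction.  Isolated spikes from single misbehaving bins would
  otherwise dominate the arc statistic while being exchangeable under
  permutation, suppressing real splits; the same-direction-run exemption
  exists because the smallest callable event spans two bins (the 40 kb
  length minimum), and smoothing must never remove what the classifier
  could call.
* **Gaps and ties.**  Runs of unfiltered bins separated by more than
  1 Mb (e.g. across centromeres) are segmented independently, so
  segments bridge small masked gaps but never a centromere.  Arc-search
  ties resolve to the smallest width, then smallest start.  Everything is
  deterministic given the RNG seed.
* **Undo.**  An optional merge of adjacent segments whose standardized
  mean difference falls below `undo_sd` is provided but off by default.

**Classification.**  With L = m/2 the single-copy level and
r = |segment mean|/L, the first matching rule of
magenta (r ≥ 0.75, ≥ 200 kb) → red (r ≥ 0.25, ≥ 200 kb) →
orange (r ≥ 0.25, ≥ 40 kb) → yellow (r ≥ 0.125, ≥ 40 kb) → green
assigns the significance class; length is the sum of member-bin spans and
thresholds are enforced in bp so non-default bin sizes behave sensibly.
The denominator L (rather than m) is the natural reading of
"percent of the single-copy level"; it makes a clean heterozygous
deletion r ≈ 1.  Non-green segments are calls; the sign of the mean
distinguishes deletion from duplication.

## In-silico accuracy study

Depth is varied by binomial thinning of bin counts (distributionally
identical to subsampling reads for start-position counts).  A CNV is
injected by multiplying the counts of a uniformly chosen bin-aligned
autosomal window — avoiding filtered bins — by 0.5 or 1.5; everything
downstream runs unchanged.  A trial is a detection when any non-green
call of the matching sign overlaps the truth (a wrong-sign overlap is not
a detection); exact and within-one-bin rates compare call and truth
boundaries.  The grid runner downsamples each base sample once per depth,
injects variants one at a time (one artificial sample per variant), and
by default segments only the chromosome carrying the injection — scoring
inspects only calls overlapping the truth, so reported fractions are
identical either way and the computation drops by an order of magnitude.

## Synthetic data

The generator emulates the structure the pipeline assumes: per-bin GC
from a smoothed spatial process rescaled into [0.3, 0.7]; a unimodal
multiplicative GC bias exp(1.0·(gc−0.5) − 4.0·(gc−0.5)²); one contiguous
centromere-like unmappable block per chromosome plus scatter (10% of
bins overall, zero rate); 1% N-heavy bins with undefined GC; rank-3
cross-sample artifacts as bin-level white loading vectors (per-factor
per-bin log-rate SD 0.05) multiplied by per-sample standard-normal
factors — white because recurrent low-coverage artifacts are dominated by
bin-specific mappability/chemistry effects, and spatially smooth loadings
would fabricate CNV-mimicking waves; 2% high-variance bins with
per-sample log-normal jitter (SD 0.5); Poisson counts with expected
totals equal to the requested read count, plus an off-by-default
overdispersion knob.  Truth (mappability, loadings, factors) is recorded
for recovery tests.  Literal sequences consistent with the GC track can
be materialized for toy genomes to exercise the sequence→GC path;
genome-scale runs use the GC track directly, since the pipeline's datum
is the bin count.

What passing tests show — and what they do not: the synthetic cohort has
no spatial correlation in its noise, no mappability waves, no family
structure between panel and test samples, and artifacts that are exactly
low-rank.  Detection results therefore transfer optimistically to real
data, while *boundary-exactness* results transfer pessimistically: real
bin noise is spatially correlated, which sharpens step contrast relative
to the local background, whereas white noise maximizes boundary jitter.
At a per-bin signal-to-noise ratio of ~3 (200 kb at 5 M reads) the
exact-boundary rate is limited by the maximum-likelihood changepoint
estimator itself — a boundary flips when an edge bin's value crosses half
the single-copy level — not by any tunable of this implementation.

## Reference study configuration

The benchmark harness trains on 100 synthetic CNV-free samples at 10 M
reads on GRCh37 chromosome sizes (154,794 bins), generates test samples
at 12 M reads, and measures 1,000 injection trials per cell
(10 samples × 100 variants) with 500-permutation CBS.  These problem
sizes keep a full study under ten minutes on one CPU while leaving
binomial standard errors around one percentage point.  Measured under
this configuration (seed 1): detection of 100 kb CNVs at 8 M reads
99.3%; exact / within-one-bin boundary rates for 200 kb CNVs at 10 M
reads 87.7% / 97.8%; exact rate at 5 M reads 65.1%.

## Known limitations

* Whole sex-chromosome aneuploidies are invisible by construction
  (per-compartment scaling); only sub-chromosomal X/Y events are
  callable, and with more noise than autosomal ones.
* No mosaicism or fetal-fraction modelling: levels are interpreted
  against full single-copy gains/losses.
* Exon-scale resolution is out of reach at 20 kb bins; boundary
  coordinates are multiples of the bin size with ±1–2 bin jitter at low
  depth.
* The false-positive rate is guarded only by synthetic checks (≤ 1
  non-green call per clean sample on the toy cohort); it has no
  real-data calibration here.
* Read mapping is out of scope: the pipeline consumes existing
  alignments or count tables.
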