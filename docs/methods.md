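# Methods

## Model and procedure

The package models expression mapping by slab tomography. The space is an
isotropic voxel grid (µm units internally; default 100 µm voxels, giving
10 voxels per 1,000 µm slab). A *sectioning series* is a family of parallel
slabs of fixed width along a unit normal; a voxel belongs to the slab
containing its center (half-open intervals, no partial-volume weighting).
This convention makes every geometric operation exactly reproducible by a
per-voxel reference loop, which the test suite exploits.

The forward model treats a fraction's measurement as the **volume-averaged
concentration** of the density field over the fraction's in-tissue voxels:
microarray intensity tracks relative transcript concentration in the
pooled RNA of a slab, not total amount. A summed-amount variant is
available (`mode="sum"`) for sensitivity analysis. Measurement noise is
multiplicative log-normal with log-sd `sdlog` (natural log), the standard
first-order model for intensity data; the default 0.1 (~10% noise) is
consistent with the very high replicate correlations such designs produce.

Reconstruction is single-pass pseudo-back-projection: each fraction's value
is written to every voxel of that fraction, and per-voxel values are
averaged with equal weight across series. Maps are defined on the coverage
volume (voxels holding a fraction in *every* series); voxels covered by
only some series are excluded. No iterative or regularized inversion is
attempted — resolution is set by slab width and the number of sectioning
directions, and the characteristic artifact is size inflation of compact
sources.

### The cutoff filter

The "80% cutoff" is defined as threshold = `keep_fraction` × map maximum
over the coverage volume (default 0.8), membership `value >= threshold`.
Two alternative readings were implemented and adjudicated on the phantom
experiment's diameter-inflation statistic: a percentile threshold (the
`keep_fraction` quantile of covered values) yields a mean diameter ratio
near 4.7 and a 20%-of-max threshold yields ~5.0, both grossly inconsistent
with the reference behaviour of the filter, while 0.8 × max yields ~1.54.
The max-referenced threshold is therefore the default; the percentile
variant remains available via `method="percentile"`.

### Phantom evaluation

Test spheres are uniform-density phantoms with centers drawn uniformly
from in-mask voxel centers; spheres may protrude beyond the tissue. The
true-positive rate of a sphere is 100·|sphere ∩ suprathreshold region| /
|sphere ∩ coverage|, all volumes counted in voxels; the region's size is
summarized as the equivalent-sphere diameter (6V/π)^(1/3). A sphere whose
reconstruction carries no signal, or that lies wholly outside coverage,
scores zero on both. The mean diameter ratio is taken over spheres with a
non-empty reconstructed region.

On the synthetic brain (full run: 1,366 spheres of 1,000 µm at 100 µm
voxels, seconds per thousand spheres) the pipeline reproduces the
qualitative reference behaviour — a heavy upper tail of near-complete
recovery, a median around 80% overlap, and ~1.5-fold diameter inflation —
but two quantitative deviations are expected and persistent across seeds:
the fraction of spheres with ≥5% overlap is ~99.6% rather than ~95%, and
the mean diameter ratio is ~1.54 rather than ~1.73. Both stem from the
same structural simplification: the synthetic mask yields *complete,
exact* coverage (one analytic mask shared by all six series), whereas real
fraction templates come from six separately sectioned and registered
brains whose common volume is ragged and strictly smaller than the brain,
producing peripheral reconstruction failures and registration smear that
enlarges suprathreshold regions. The synthetic-data generator deliberately
does not model inter-animal variability or registration error, so passing
phantom tests demonstrate the correctness of the geometry, forward model
and reconstruction — not the field-realism of the failure tails.

## Probe statistics

All log transforms are log2(x + 1); the offset stabilizes low intensities.
Per-chip normalization divides each fraction (chip) by its 75th-percentile
intensity (median available by flag). Note a statistical side effect
verified in simulation: because the normalizer is estimated from the data,
strong spatial structure in a large share of probes induces small
correlated column effects, which inflate the across-fraction ANOVA for
truly uniform probes (their raw p-values are exactly uniform on
unnormalized data). This mirrors what any per-chip normalization does to
real data; the type-I control property is therefore stated for null
studies, where the effect is negligible.

Replicate pairing is greedy on descending Pearson correlation between
orthogonal-group and oblique-group fractions, with ties broken
anatomically (counterpart series first, then smallest fraction-index
difference). The ANOVA treats each replicate pair as a 2-observation
level: with P pairs the statistic is F = (SSB/(P−1))/(SSW/P) with
SSW = Σ(a−b)²/2, vectorized across probes and checked against a reference
ANOVA implementation in the tests. Probes with zero variance get p = 1;
zero within-pair variance with non-zero between-pair variance gets p = 0.
BH adjustment is applied across probes; the I-split is strict
(I > median ⇒ group I, ties to i), so group counts obey
|IV|+|Iv| = |iV|+|iv| up to median ties.

The diagnostic correlation between I and V is computed between I and
log10(V) (V clipped at 1e-300); it is reported, not asserted.

## Synthetic data

The synthetic brain is a union of three axis-aligned ellipsoids (cerebral
body, posterior cerebellar bulge, ventral stem) inside the 9 × 13 × 6 mm
design box, mirror-symmetric about the mid-sagittal plane. The reference
design is fixed by the method: S/C/H series of 9/13/6 fractions and
So/Co/Ho of 10/16/7 fractions, all 1,000 µm wide, 61 fractions in total.
The oblique tilt is not dictated by the geometry alone; it defaults to 10°
about a fixed perpendicular axis per series and is configurable (per
series if desired), as are the slab offsets, which default to centering
each span on the mask.

One geometric consequence is unavoidable: any tissue shape fitting the
design box projects to less than the 16,000 µm Co span at a 10° tilt, so
the outermost oblique fractions contain no tissue. Empty fractions measure
nothing; they are flagged absent in generated studies, reported as zero
when sectioning is asked to tolerate them (`on_empty="zero"`), dropped by
`drop_absent_fractions` before correlation analyses, and are harmless to
reconstruction (no voxel maps to them).

Planted studies draw a set of distinct spatial patterns (random linear
gradients and ellipsoidal regions, half-axes 1.5–3.5 mm) and assign each
non-uniform probe one pattern. `effect_size` is calibrated on the
*measurement* scale: each pattern field is sectioned through the design
and its log fraction profile is standardized to standard deviation
`effect_size` (natural log), so the planted-to-noise contrast is exactly
`effect_size/sdlog` regardless of how much slab averaging dilutes the
underlying spatial pattern. Defaults: 2,000 probes, half non-uniform,
effect 0.4 vs noise 0.1, log-normal per-probe baselines (log2 sd 2).
All randomness flows from one seed through named substreams (patterns,
assignment, baseline, noise). Probe-statistics studies default to 200 µm
voxels — fraction-level measurements are insensitive to discretization
well below the 1,000 µm slab width — while phantom and reconstruction
accuracy work uses 100 µm.

## Numerical choices and degenerate inputs

Accumulation is double precision in fixed voxel order, so results are
bit-reproducible. A uniform field is reconstructed exactly (relative error
below 1e-12). Degenerate inputs raise rather than guess: non-unit normals,
empty templates, empty joint coverage, all-zero maps under the cutoff,
constant fractions under correlation, overlapping replicate groups.
8-bit export rounds half away from zero (127.5 → 128) and is for
visualization only. The voxelwise t-test in area comparisons treats voxel
values as observations; neighbouring voxels share fraction values by
construction, so it is a descriptive contrast, not an
independence-respecting inference, and is documented as such.

## Problem sizes

The test suite exercises exact per-voxel oracle comparisons on grids up to
32³, the full 1,366-sphere phantom experiment at 100 µm voxels, a
10,000-probe null study and a 2,000-probe power study; the whole suite
runs in well under a minute on one CPU. These sizes were chosen as the
smallest that exercise every code path at the method's native scale.

## Known limitations

- One analytic mask stands in for six registered real brains: coverage is
  complete and exact, so peripheral failure modes and registration smear
  are absent (see the phantom discussion above).
- Fraction measurements assume perfect RNA recovery per slab; extraction
  yield, probe-specific hybridization and chip spatial artifacts are not
  modeled.
- Registration of real block-face imagery, deformable atlas integration
  and viewer/database functionality are out of scope; atlases and area
  centroids are accepted as inputs.
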