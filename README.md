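# ttomo — slab-tomographic 3D gene-expression mapping

`ttomo` reconstructs three-dimensional gene-expression density maps from
*fraction data*: expression measurements of serial tissue slabs cut along
several body axes. Cutting a whole organ into ~1 mm slabs along each of
sagittal, coronal and horizontal axes (plus slightly oblique repeats) turns
a 3D mapping problem into a few dozen bulk measurements; assigning each
slab's measured density back to every voxel of that slab
(*pseudo-back-projection*) and averaging the slab volumes across sectioning
directions recovers an isotropic 3D density map. The package is for
computational biologists who want to build, validate or simulate such maps
without any wet-lab input: every stage runs on synthetic data.

## The method

For a density field *f* and a sectioning series *s* with unit normal
**n**<sub>s</sub>, slab width *w* and offset *o*, voxel *x* belongs to slab

&nbsp;&nbsp;&nbsp;&nbsp;k(x) = ⌊(**n**<sub>s</sub>·x − o) / w⌋,

and the measured value of fraction *k* is the volume-averaged concentration
mean{ f(x) : k(x) = k, x in tissue }. The reconstruction at voxel *x* is
the unweighted mean over series of the measured value of the slab containing
*x*, defined on the *coverage* volume (voxels assigned a slab in every
series). The *80% cutoff filter* keeps voxels with value ≥ 0.8 × the map
maximum over the coverage; area expression density is the suprathreshold
sum within an area divided by the area's voxel count.

Probe-level statistics on the fraction matrix classify each probe by two
variables: *I*, the median log2 intensity across fractions, and *V*, the
Benjamini–Hochberg-adjusted FDR of a one-way ANOVA across replicate
fraction pairs (orthogonal vs oblique series paired by highest Pearson
correlation, anatomical order breaking ties). Probes fall into groups
IV / iV / Iv / iv by I above/below the median of all probes' I and
V < / ≥ 0.05.

## Worked example

```python
from ttomo import (synthetic_brain_mask, default_design, build_fraction_template,
                   planted_pattern, section_field, add_measurement_noise,
                   reconstruct, cutoff_filter, sphere_area, area_density, coverage)

mask = synthetic_brain_mask(voxel_size=200.0)          # 9 x 13 x 6 mm brain shape
design = default_design(mask.grid, mask, oblique_angle_deg=10.0)
templates = [build_fraction_template(mask.grid, mask, s) for s in design]
print("mask volume: %.1f mm^3, fractions: %d"
      % (mask.volume_um3 / 1e9, sum(s.n_fractions for s in design)))

# a gene expressed in a 3 mm hotspot on a uniform background, 10% noise
truth = planted_pattern("sphere", mask.grid, center=(4500, 6500, 3000),
                        diameter=3000.0, inside=5.0, outside=1.0)
data = [add_measurement_noise(section_field(truth, t, mask, on_empty="zero"),
                              sdlog=0.1, seed=7 + i)
        for i, t in enumerate(templates)]
emap = reconstruct(data, templates, probe_id="demo")
region = cutoff_filter(emap, keep_fraction=0.8)
print("cutoff threshold: %.3f, suprathreshold volume: %.1f mm^3"
      % (region.threshold, region.volume_um3 / 1e9))

cov = coverage(templates)
for center, name in [((4500, 6500, 3000), "hotspot"), ((4500, 10500, 3000), "distal")]:
    area = sphere_area(mask.grid, center, diameter=1000.0, area_id=name, coverage=cov)
    print(f"{name}: suprathreshold density {area_density(emap, area).density:.3f}")
```

prints

```
mask volume: 269.9 mm^3, fractions: 61
cutoff threshold: 1.267, suprathreshold volume: 84.9 mm^3
hotspot: suprathreshold density 1.551
distal: suprathreshold density 0.653
```

The 61 slab measurements localize the hotspot (its area density is 2.4-fold
the distal control), but slab averaging smears the signal: the
suprathreshold region is far larger than the 14 mm³ hotspot, the size
inflation inherent to back-projection at 1 mm slab width.

A command-line interface mirrors the library:
`ttomo synth` (simulate a study), `ttomo reconstruct`, `ttomo phantom`,
`ttomo stats` and `ttomo area`; every run writes a JSON provenance record.

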