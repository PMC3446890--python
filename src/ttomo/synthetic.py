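"""Synthetic study generator.

Builds a brain-shaped tissue mask, the 6-series/61-fraction reference
design, spatially patterned per-probe density fields and noisy fraction
measurements, so that every stage of the pipeline is testable without any
external data.

The mask is a union of axis-aligned ellipsoids — a main cerebral
ellipsoid, a posterior cerebellar bulge and a ventral brainstem — sized to
fit the design's fraction spans (9 x 13 x 6 mm at 1,000 µm slab width) and
mirror-symmetric about the mid-sagittal plane.

All randomness flows through one seed via named ``SeedSequence``
substreams (patterns / assignment / baseline / noise), so individual
stages are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward import DensityField, section_field
from .fraction_stats import FractionDataMatrix
from .geometry import (
    BrainMask,
    FractionTemplate,
    SectioningSeries,
    VoxelGrid,
    build_fraction_template,
    default_design,
    sphere_voxel_mask,
)

# (center, half-axes) in µm within the 9 x 13 x 6 mm design box.
_BRAIN_ELLIPSOIDS = (
    ((4500.0, 7800.0, 3200.0), (4200.0, 4600.0, 2600.0)),  # cerebrum
    ((4500.0, 2600.0, 3000.0), (3000.0, 2400.0, 2000.0)),  # cerebellar bulge
    ((4500.0, 3000.0, 1600.0), (1600.0, 2800.0, 1500.0)),  # ventral stem
)
_BOX_CENTER = np.array([4500.0, 6500.0, 3000.0])
_BOX_EXTENT = np.array([9000.0, 13000.0, 6000.0])


def default_grid(voxel_size: float = 100.0) -> VoxelGrid:
    """Grid spanning the 9 x 13 x 6 mm design box at a given voxel size."""
    shape = tuple(int(round(e / voxel_size)) for e in _BOX_EXTENT)
    return VoxelGrid(shape=shape, voxel_size=voxel_size)


def synthetic_brain_mask(
    grid: VoxelGrid | None = None,
    voxel_size: float = 100.0,
    scale: float = 1.0,
) -> BrainMask:
    """Brain-shaped mask: union of ellipsoids, x-mirror symmetric.

    ``scale`` shrinks or grows the shape about the box center (half-axes
    and center offsets scale together), keeping the mask within the design
    spans for scale <= 1.
    """
    if grid is None:
        grid = default_grid(voxel_size)
    if not (scale > 0):
        raise ValueError("scale must be positive")
    cx, cy, cz = (grid.axis_centers(a) for a in range(3))
    inside = np.zeros(grid.shape, dtype=bool)
    for center, half in _BRAIN_ELLIPSOIDS:
        c = _BOX_CENTER + scale * (np.asarray(center) - _BOX_CENTER)
        h = scale * np.asarray(half)
        term = (
            ((cx - c[0]) / h[0])[:, None, None] ** 2
            + ((cy - c[1]) / h[1])[None, :, None] ** 2
            + ((cz - c[2]) / h[2])[None, None, :] ** 2
        )
        inside |= term <= 1.0
    return BrainMask(grid=grid, inside=inside)


def planted_pattern(kind: str, grid: VoxelGrid, **params) -> DensityField:
    """Deterministic spatial density pattern of a given kind.

    Kinds: ``uniform(value)``; ``sphere(center, diameter, inside, outside)``;
    ``gradient(direction, low, high)`` — linear ramp of the projection onto
    ``direction`` scaled to [low, high] over the grid; ``region_marker
    (region, inside, outside)`` — indicator of a stored sub-mask.
    """
    if kind == "uniform":
        value = float(params.get("value", 1.0))
        return DensityField(grid=grid, value=np.full(grid.shape, value))
    if kind == "sphere":
        m = sphere_voxel_mask(grid, params["center"], params["diameter"])
        inside = float(params.get("inside", 1.0))
        outside = float(params.get("outside", 0.0))
        return DensityField(grid=grid, value=np.where(m, inside, outside))
    if kind == "gradient":
        direction = np.asarray(params.get("direction", (0.0, 1.0, 0.0)), dtype=float)
        direction = direction / np.linalg.norm(direction)
        low = float(params.get("low", 0.0))
        high = float(params.get("high", 1.0))
        proj = grid.center_projections(direction)
        t = (proj - proj.min()) / (proj.max() - proj.min())
        return DensityField(grid=grid, value=low + (high - low) * t)
    if kind == "region_marker":
        region = np.asarray(params["region"], dtype=bool)
        inside = float(params.get("inside", 1.0))
        outside = float(params.get("outside", 0.0))
        return DensityField(grid=grid, value=np.where(region, inside, outside))
    raise ValueError(f"unknown pattern kind {kind!r}")


@dataclass
class SyntheticStudy:
    """A complete simulated sectioning study with known ground truth."""

    grid: VoxelGrid
    mask: BrainMask
    design: list[SectioningSeries]
    templates: list[FractionTemplate]
    matrix: FractionDataMatrix
    truth: pd.DataFrame  # per probe: nonuniform flag, pattern id, kind
    seed: int

    @property
    def fraction_ids(self) -> list[str]:
        return self.matrix.fraction_ids


def _pattern_params(rng: np.random.Generator, mask: BrainMask) -> dict:
    """Random non-uniform pattern spec: a gradient or an ellipsoidal region."""
    if rng.random() < 0.5:
        v = rng.normal(size=3)
        return {"kind": "gradient", "direction": tuple(v / np.linalg.norm(v))}
    inside = np.argwhere(mask.inside)
    center = mask.grid.voxel_center(inside[rng.integers(inside.shape[0])])
    half = rng.uniform(1500.0, 3500.0, size=3)
    return {"kind": "ellipsoid_region", "center": tuple(center), "half_axes": tuple(half)}


def _pattern_field(spec: dict, grid: VoxelGrid) -> DensityField:
    """Unit-amplitude multiplicative density field exp(g) for a pattern spec.

    For gradients g ramps over [-1, 1] along the direction; for ellipsoidal
    regions g is the region indicator (the region is e-fold denser than the
    surround).  The planted contrast is calibrated on the *sectioned*
    profile, not here — see :func:`synthetic_study`.
    """
    if spec["kind"] == "gradient":
        proj = grid.center_projections(np.asarray(spec["direction"]))
        g = 2.0 * (proj - proj.min()) / (proj.max() - proj.min()) - 1.0
    elif spec["kind"] == "ellipsoid_region":
        c = np.asarray(spec["center"])
        h = np.asarray(spec["half_axes"])
        cx, cy, cz = (grid.axis_centers(a) for a in range(3))
        term = (
            ((cx - c[0]) / h[0])[:, None, None] ** 2
            + ((cy - c[1]) / h[1])[None, :, None] ** 2
            + ((cz - c[2]) / h[2])[None, None, :] ** 2
        )
        g = (term <= 1.0).astype(float)
    else:
        raise ValueError(f"unknown pattern kind {spec['kind']!r}")
    return DensityField(grid=grid, value=np.exp(g))


def synthetic_study(
    n_probes: int = 2000,
    fraction_nonuniform: float = 0.5,
    effect_size: float = 0.4,
    sdlog: float = 0.1,
    seed: int = 0,
    voxel_size: float = 200.0,
    oblique_angle_deg: float = 10.0,
    n_patterns: int = 24,
) -> SyntheticStudy:
    """Simulate a full 6-series / 61-fraction expression study.

    A ``fraction_nonuniform`` share of probes carries a planted spatial
    pattern (random gradients and ellipsoidal regions); the rest are
    spatially uniform.  ``effect_size`` is the standard deviation, in
    natural-log units, of a planted probe's *measured* fraction profile —
    the same scale as the measurement noise ``sdlog`` — so the
    planted-to-noise contrast is exactly ``effect_size / sdlog`` regardless
    of how much slab averaging dilutes the underlying spatial pattern.
    Each pattern is sectioned through the design and its log fraction
    profile is standardized to sd ``effect_size``.  Per-probe baselines are
    log-normal across probes; measurement noise is multiplicative
    log-normal with log-sd ``sdlog`` per observation.  Present flags are
    true except in empty (tissue-free) fractions.  Fully deterministic
    under ``seed``.
    """
    if not (0.0 <= fraction_nonuniform <= 1.0):
        raise ValueError("fraction_nonuniform must lie in [0, 1]")
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_patterns = np.random.default_rng(streams[0])
    rng_assign = np.random.default_rng(streams[1])
    rng_baseline = np.random.default_rng(streams[2])
    rng_noise = np.random.default_rng(streams[3])

    grid = default_grid(voxel_size)
    mask = synthetic_brain_mask(grid)
    design = default_design(grid, mask, oblique_angle_deg=oblique_angle_deg)
    templates = [build_fraction_template(grid, mask, s) for s in design]
    fraction_ids = [fid for s in design for fid in s.fraction_ids]
    n_fractions = len(fraction_ids)

    n_nonuniform = int(round(n_probes * fraction_nonuniform))
    # distinct spatial patterns, reused across planted probes
    n_distinct = min(n_patterns, max(n_nonuniform, 1))
    specs = [_pattern_params(rng_patterns, mask) for _ in range(n_distinct)]
    nonempty = np.concatenate([t.fraction_volumes > 0 for t in templates])
    profiles = np.empty((n_distinct, n_fractions))
    for k, spec in enumerate(specs):
        fld = _pattern_field(spec, grid)
        raw = np.concatenate(
            [section_field(fld, t, mask, on_empty="zero").values for t in templates]
        )
        # calibrate the planted contrast on the measurement scale: the log
        # fraction profile is standardized to sd = effect_size
        logp = np.zeros(n_fractions)
        logp[nonempty] = np.log(raw[nonempty])
        sd = logp[nonempty].std()
        if sd > 0:
            logp[nonempty] = (
                (logp[nonempty] - logp[nonempty].mean()) / sd * effect_size
            )
        profiles[k] = np.where(nonempty, np.exp(logp), 0.0)

    planted = np.zeros(n_probes, dtype=bool)
    planted[rng_assign.choice(n_probes, size=n_nonuniform, replace=False)] = True
    pattern_of_probe = np.full(n_probes, -1, dtype=int)
    if n_nonuniform:
        pattern_of_probe[planted] = rng_assign.integers(0, n_distinct, size=n_nonuniform)

    baseline = 2.0 ** rng_baseline.normal(6.0, 2.0, size=n_probes)
    intensity = np.ones((n_probes, n_fractions))
    if n_nonuniform:
        intensity[planted] = profiles[pattern_of_probe[planted]]
    intensity *= baseline[:, None]
    if sdlog > 0:
        intensity *= rng_noise.lognormal(0.0, sdlog, size=intensity.shape)

    probe_ids = [f"P{i + 1:06d}" for i in range(n_probes)]
    intensity_df = pd.DataFrame(intensity, index=probe_ids, columns=fraction_ids)
    # fractions whose slab holds no tissue (oblique span ends) carry no
    # measurement: flagged absent for every probe
    empty = np.concatenate([t.fraction_volumes == 0 for t in templates])
    intensity_df.loc[:, empty] = 0.0
    present_df = pd.DataFrame(True, index=probe_ids, columns=fraction_ids)
    present_df.loc[:, empty] = False
    matrix = FractionDataMatrix(intensity=intensity_df, present=present_df)
    truth = pd.DataFrame(
        {
            "nonuniform": planted,
            "pattern": pattern_of_probe,
            "kind": [
                specs[k]["kind"] if k >= 0 else "uniform" for k in pattern_of_probe
            ],
            "baseline": baseline,
        },
        index=probe_ids,
    )
    return SyntheticStudy(
        grid=grid, mask=mask, design=design, templates=templates,
        matrix=matrix, truth=truth, seed=seed,
    )
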