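"""Quantification of expression in defined brain areas.

Areas are voxel sets: spheres around given centroids (optionally mirrored
about the mid-sagittal plane), suprathreshold regions of marker-gene maps,
or boolean combinations of such regions.  The area expression density
follows the literal definition used for the mapped data: the summed map
values at or above the cutoff threshold within the area, divided by the
area's voxel count — voxels below threshold contribute zero to the
numerator but still count in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import BrainMask, CoverageMask, VoxelGrid, sphere_voxel_mask
from .reconstruction import ExpressionMap, cutoff_filter


@dataclass
class AreaLabel:
    """A named voxel set on the grid."""

    area_id: str
    grid: VoxelGrid
    member: np.ndarray
    kind: str = "mask"

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError("area shape does not match grid")
        if not self.member.any():
            raise ValueError(f"area {self.area_id!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())


@dataclass
class AreaDensity:
    """Mean expression density of one probe in one area."""

    area_id: str
    probe_id: str | None
    density: float
    mode: str
    bilateral: bool = False


def sphere_area(
    grid: VoxelGrid,
    centroid,
    diameter: float = 500.0,
    area_id: str = "area",
    coverage: CoverageMask | None = None,
    mirror: bool = False,
    mirror_plane_x: float | None = None,
):
    """Spherical area at a centroid; optionally with its x-mirrored twin.

    When ``coverage`` is given the centroid must lie on a covered voxel and
    the area is clipped to the coverage volume.  The mirror plane defaults
    to the mid-extent of the coverage volume along x (the mid-sagittal
    plane of a bilaterally symmetric mask).
    """
    def _one(c, suffix=""):
        m = sphere_voxel_mask(grid, c, diameter)
        if coverage is not None:
            ci = np.floor(
                (np.asarray(c) - np.asarray(grid.origin)) / grid.voxel_size
            ).astype(int)
            if (ci < 0).any() or (ci >= np.asarray(grid.shape)).any() or not coverage.covered[tuple(ci)]:
                raise ValueError(f"centroid {tuple(c)} lies outside the coverage volume")
            m = m & coverage.covered
        return AreaLabel(area_id=area_id + suffix, grid=grid, member=m, kind="sphere")

    primary = _one(np.asarray(centroid, dtype=float))
    if not mirror:
        return primary
    if mirror_plane_x is None:
        if coverage is None:
            raise ValueError("mirroring needs a coverage volume or an explicit plane")
        xs = np.argwhere(coverage.covered)[:, 0]
        lo = grid.voxel_center((xs.min(), 0, 0))[0]
        hi = grid.voxel_center((xs.max(), 0, 0))[0]
        mirror_plane_x = 0.5 * (lo + hi)
    c = np.asarray(centroid, dtype=float)
    twin = c.copy()
    twin[0] = 2.0 * mirror_plane_x - c[0]
    return primary, _one(twin, suffix="_mirror")


def area_density(
    emap: ExpressionMap,
    area,
    mode: str = "suprathreshold",
) -> AreaDensity:
    """Expression density of a map in an area.

    ``mode="suprathreshold"``: sum of map values >= the map's cutoff
    threshold within the area, divided by the area voxel count (the
    threshold must have been set by the cutoff filter).  ``mode="raw"``:
    plain mean over the area.  Passing a (left, right) pair of areas
    averages the two densities (bilateral averaging).
    """
    if isinstance(area, (tuple, list)):
        parts = [area_density(emap, a, mode=mode) for a in area]
        return AreaDensity(
            area_id=parts[0].area_id,
            probe_id=emap.probe_id,
            density=float(np.mean([p.density for p in parts])),
            mode=mode,
            bilateral=True,
        )
    vals = emap.value[area.member]
    if mode == "raw":
        density = float(vals.mean())
    elif mode == "suprathreshold":
        if emap.cutoff_threshold is None:
            raise ValueError(
                "suprathreshold density needs a map with a cutoff threshold; "
                "run cutoff_filter first"
            )
        density = float(vals[vals >= emap.cutoff_threshold].sum() / area.n_voxels)
    else:
        raise ValueError(f"unknown density mode {mode!r}")
    return AreaDensity(
        area_id=area.area_id, probe_id=emap.probe_id, density=density, mode=mode
    )


def marker_area(
    emap: ExpressionMap,
    keep_fraction: float = 0.8,
    method: str = "max",
    area_id: str | None = None,
) -> AreaLabel:
    """Area defined by a marker gene: the map's suprathreshold region.

    Disconnected suprathreshold components are all retained (no
    connectivity pruning).
    """
    region = cutoff_filter(emap, keep_fraction=keep_fraction, method=method)
    return AreaLabel(
        area_id=area_id or f"{emap.probe_id or 'marker'}+",
        grid=emap.grid,
        member=region.member,
        kind="marker",
    )


def combine_masks(
    positive: list[AreaLabel],
    negative: list[AreaLabel] = (),
    area_id: str | None = None,
) -> AreaLabel:
    """Intersection of positive areas minus the union of negative areas."""
    if not positive:
        raise ValueError("need at least one positive area")
    grid = positive[0].grid
    member = np.ones(grid.shape, dtype=bool)
    for a in positive:
        member &= a.member
    for a in negative:
        member &= ~a.member
    name = area_id or (
        "".join(f"{a.area_id}(+)" for a in positive)
        + "".join(f"{a.area_id}(-)" for a in negative)
    )
    return AreaLabel(area_id=name, grid=grid, member=member, kind="combined")


def region_overlap(area: AreaLabel, atlas: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Per-region overlap of an area with an integer atlas label volume.

    For every atlas label > 0: 100 * |area ∩ label| / |label|.  Also
    returns 100 * |area| / |atlas > 0| (percent of the whole labeled
    volume).
    """
    atlas = np.asarray(atlas)
    if atlas.shape != area.grid.shape:
        raise ValueError("atlas shape does not match the area grid")
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    rows = []
    for lab in labels:
        in_label = atlas == lab
        n_label = int(in_label.sum())
        n_both = int((in_label & area.member).sum())
        rows.append(
            {"label": int(lab), "n_voxels": n_label,
             "percent_of_region": 100.0 * n_both / n_label}
        )
    whole = int((atlas > 0).sum())
    percent_of_whole = 100.0 * area.n_voxels / whole if whole else float("nan")
    return pd.DataFrame(rows), percent_of_whole


def select_top_probe(values: pd.DataFrame, probe_to_gene: pd.Series) -> pd.Index:
    """Per gene, the probe with the highest mean value across columns."""
    means = values.mean(axis=1)
    df = pd.DataFrame({"gene": probe_to_gene.reindex(values.index), "mean": means})
    order = df.sort_values("mean", ascending=False)
    top = order[~order["gene"].duplicated()].index
    return values.index[values.index.isin(top)]


def compare_datasets(
    test: pd.Series,
    ref: pd.Series,
    window: float = 0.02,
    trim: float = 0.001,
) -> dict:
    """Agreement between two (gene, area) expression tables.

    Pearson r is computed on log2(x + 1) over the shared index.  The CV
    curve takes each ``window``-quantile window of the *reference* values,
    trims ``trim`` (fraction) off both ends of the matched *test* values,
    and reports sd/mean of the untransformed trimmed values.
    """
    joined = pd.concat({"test": test, "ref": ref}, axis=1, join="inner").dropna()
    if len(joined) < 2:
        raise ValueError("fewer than 2 shared (gene, area) pairs")
    lt = np.log2(joined["test"].to_numpy() + 1.0)
    lr = np.log2(joined["ref"].to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = float(np.corrcoef(lt, lr)[0, 1])  # nan when one table is constant
    # quantile windows of the reference values
    ref_vals = joined["ref"].to_numpy()
    test_vals = joined["test"].to_numpy()
    ranks = sps.rankdata(ref_vals, method="average") / len(ref_vals)
    n_windows = int(round(1.0 / window))
    win = np.minimum((ranks * n_windows - 1e-12).astype(int), n_windows - 1)
    rows = []
    for w in range(n_windows):
        tv = test_vals[win == w]
        if tv.size == 0:
            continue
        # trim a count fraction off both ends (no-op when trim*n < 1)
        k = int(np.floor(trim * tv.size))
        kept = np.sort(tv)[k:tv.size - k]
        mean = kept.mean()
        sd = kept.std(ddof=1) if kept.size > 1 else 0.0
        cv = float(sd / mean) if mean != 0 else float("nan")
        rows.append(
            {"window": w, "quantile_lo": w * window, "quantile_hi": (w + 1) * window,
             "n": int(kept.size), "cv": cv}
        )
    return {"r": r, "n_pairs": int(len(joined)), "cv_by_quantile": pd.DataFrame(rows)}


def compare_area_densities(
    emap: ExpressionMap,
    areas: list,
    reference_id: str,
    mode: str = "suprathreshold",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-area density as percent of a reference area, with t-tests.

    The two-sided Student t-test treats voxel values in each area as
    observations; it is a descriptive contrast, not an
    independence-respecting inference (neighbouring voxels share fraction
    values by construction).
    """
    by_id = {}
    for a in areas:
        key = a[0].area_id if isinstance(a, (tuple, list)) else a.area_id
        by_id[key] = a
    if reference_id not in by_id:
        raise ValueError(f"reference area {reference_id!r} not among the areas")

    def _voxels(a):
        if isinstance(a, (tuple, list)):
            return np.concatenate([emap.value[x.member] for x in a])
        return emap.value[a.member]

    ref_density = area_density(emap, by_id[reference_id], mode=mode).density
    if ref_density == 0:
        raise ValueError("reference area has zero density")
    ref_vox = _voxels(by_id[reference_id])
    rows = []
    for key, a in by_id.items():
        d = area_density(emap, a, mode=mode)
        vox = _voxels(a)
        if key == reference_id:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(vox, ref_vox, equal_var=False)
        rows.append(
            {"area_id": key, "density": d.density,
             "percent_of_reference": 100.0 * d.density / ref_density,
             "t": float(t), "p": float(p), "significant": bool(p < alpha)}
        )
    return pd.DataFrame(rows).set_index("area_id")
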