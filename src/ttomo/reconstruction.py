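"""Pseudo-back-projection and multi-series averaging.

The reconstruction is single-pass: each fraction's measured density is
assigned to every voxel of that fraction (pseudo-back-projection, the
analogue of back-projection in transmission tomography), and the per-series
volumes are averaged voxelwise over the common coverage volume.  No
iterative or regularized inversion is performed.

The *cutoff filter* retains the high-density voxels of a map.  Its default
definition is a threshold at ``keep_fraction`` times the map maximum over
the coverage volume; a percentile-based variant (threshold at the
``keep_fraction`` quantile of covered values) is available for sensitivity
analysis via ``method="percentile"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import DensityField, FractionSeriesData
from .geometry import CoverageMask, FractionTemplate, VoxelGrid, coverage


@dataclass
class ExpressionMap:
    """Reconstructed 3D expression density of one probe.

    Values are defined on (and zero outside) the coverage volume common to
    all series.  ``cutoff_threshold`` is set by :func:`cutoff_filter`.
    """

    grid: VoxelGrid
    value: np.ndarray
    coverage: CoverageMask
    probe_id: str | None = None
    cutoff_threshold: float | None = None
    keep_fraction: float | None = None

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != self.grid.shape:
            raise ValueError("map shape does not match grid")
        if (self.value < 0).any():
            raise ValueError("map contains negative values")

    @property
    def covered_values(self) -> np.ndarray:
        return self.value[self.coverage.covered]


@dataclass
class SuprathresholdRegion:
    """Voxels of a map at or above the cutoff threshold."""

    grid: VoxelGrid
    member: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError("region shape does not match grid")

    @property
    def n_member(self) -> int:
        return int(self.member.sum())

    @property
    def volume_um3(self) -> float:
        return self.n_member * self.grid.voxel_size**3

    @property
    def equivalent_diameter_um(self) -> float:
        """Diameter of the sphere with the same volume, (6V/pi)^(1/3)."""
        return float((6.0 * self.volume_um3 / np.pi) ** (1.0 / 3.0))


def back_project(data: FractionSeriesData, template: FractionTemplate) -> DensityField:
    """Assign each fraction's value to every voxel of that fraction.

    Voxels without a fraction (outside the mask or the series span) are
    absent from the series' measurement and are set to zero; downstream
    averaging restricts to the joint coverage where every series
    contributes.
    """
    if data.values.size != template.series.n_fractions:
        raise ValueError(
            f"series {template.series.series_id!r}: {data.values.size} values for "
            f"{template.series.n_fractions} fractions"
        )
    out = np.zeros(template.grid.shape, dtype=float)
    assigned = template.assigned
    out[assigned] = data.values[template.fraction_of_voxel[assigned]]
    return DensityField(grid=template.grid, value=out)


def reconstruct(
    all_series_data: list[FractionSeriesData],
    templates: list[FractionTemplate],
    probe_id: str | None = None,
) -> ExpressionMap:
    """Average the back-projected series volumes over the joint coverage.

    The averaging is the unweighted arithmetic mean across series,
    restricted to voxels assigned a fraction in every series.
    """
    if not all_series_data:
        raise ValueError("reconstruct requires at least one series")
    if len(all_series_data) != len(templates):
        raise ValueError("number of data series does not match number of templates")
    cov = coverage(templates)
    if cov.n_covered == 0:
        raise ValueError("no common volume: joint coverage of the series is empty")
    covered = cov.covered
    acc = np.zeros(cov.n_covered, dtype=float)
    for data, template in zip(all_series_data, templates):
        if data.values.size != template.series.n_fractions:
            raise ValueError(
                f"series {template.series.series_id!r}: data length mismatch"
            )
        acc += data.values[template.fraction_of_voxel[covered]]
    acc /= len(templates)
    value = np.zeros(cov.grid.shape, dtype=float)
    value[covered] = acc
    return ExpressionMap(grid=cov.grid, value=value, coverage=cov, probe_id=probe_id)


def cutoff_filter(
    emap: ExpressionMap,
    keep_fraction: float = 0.8,
    method: str = "max",
) -> SuprathresholdRegion:
    """Threshold a map, keeping only its high-density voxels.

    ``method="max"`` (default): threshold = keep_fraction * max over the
    coverage volume.  ``method="percentile"``: threshold = the
    keep_fraction quantile of covered values.  Membership is ``value >=
    threshold`` within coverage; the threshold is recorded on the map.
    """
    if not (0.0 < keep_fraction < 1.0):
        raise ValueError("keep_fraction must lie strictly between 0 and 1")
    vals = emap.covered_values
    if vals.size == 0:
        raise ValueError("map has empty coverage")
    vmax = float(vals.max())
    if vmax <= 0:
        raise ValueError("no signal: map is zero everywhere on its coverage")
    if method == "max":
        threshold = keep_fraction * vmax
    elif method == "percentile":
        threshold = float(np.quantile(vals, keep_fraction))
    else:
        raise ValueError(f"unknown cutoff method {method!r}")
    member = emap.coverage.covered & (emap.value >= threshold)
    emap.cutoff_threshold = threshold
    emap.keep_fraction = keep_fraction
    return SuprathresholdRegion(grid=emap.grid, member=member, threshold=threshold)


def to_8bit(emap: ExpressionMap) -> np.ndarray:
    """Rescale a map to 8-bit intensity grades for export.

    value -> round(255 * value / max), rounding half away from zero, so the
    map maximum maps to 255.  For visual comparison only; quantification
    always uses the raw averaged values.
    """
    vals = emap.covered_values
    if vals.size == 0 or float(vals.max()) <= 0:
        raise ValueError("no signal: cannot scale an all-zero map to 8 bits")
    vmax = float(vals.max())
    scaled = np.floor(255.0 * emap.value / vmax + 0.5)  # half away from zero (values >= 0)
    return scaled.astype(np.uint8)
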