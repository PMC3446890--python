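"""Independent brute-force oracles: plain Python loops over voxels.

These deliberately avoid the package's vectorized code paths; they spell
out the definitions voxel by voxel and are only usable on tiny grids.
"""

import math


def slab_index_loop(point, normal, offset, width, n_fractions):
    proj = sum(p * n for p, n in zip(point, normal))
    k = math.floor((proj - offset) / width)
    return k if 0 <= k < n_fractions else -1


def voxel_center(grid, i, j, k):
    v = grid.voxel_size
    return (
        grid.origin[0] + (i + 0.5) * v,
        grid.origin[1] + (j + 0.5) * v,
        grid.origin[2] + (k + 0.5) * v,
    )


def template_loop(grid, inside, series):
    """Per-voxel fraction assignment as a dict {(i,j,k): fraction}."""
    out = {}
    nx, ny, nz = grid.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not inside[i, j, k]:
                    continue
                f = slab_index_loop(
                    voxel_center(grid, i, j, k),
                    series.normal, series.offset, series.width, series.n_fractions,
                )
                if f >= 0:
                    out[(i, j, k)] = f
    return out


def section_loop(field, assignment, n_fractions):
    """Per-fraction mean of a field over an assignment dict."""
    sums = [0.0] * n_fractions
    counts = [0] * n_fractions
    for (i, j, k), f in assignment.items():
        sums[f] += field[i, j, k]
        counts[f] += 1
    return [s / c if c else 0.0 for s, c in zip(sums, counts)]


def reconstruct_loop(grid, assignments, data):
    """Voxelwise mean of back-projected series values; None where uncovered."""
    nx, ny, nz = grid.shape
    out = {}
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                vals = []
                for assign, values in zip(assignments, data):
                    f = assign.get((i, j, k))
                    if f is None:
                        vals = None
                        break
                    vals.append(values[f])
                if vals is not None:
                    out[(i, j, k)] = sum(vals) / len(vals)
    return out


def sphere_voxels_loop(grid, center, diameter):
    r2 = (diameter / 2.0) ** 2
    nx, ny, nz = grid.shape
    out = set()
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = voxel_center(grid, i, j, k)
                d2 = sum((a - b) ** 2 for a, b in zip(c, center))
                if d2 <= r2:
                    out.add((i, j, k))
    return out
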