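"""Watershed segmentation of supra-threshold density.

Each segment is the set of voxels at or above the threshold whose
steepest-ascent path (26-connectivity) terminates at a common local
maximum, i.e. a watershed-by-local-maximum partition with no grouping.
Within each segment the density maximum is refined off-grid by ascent on
the trilinearly interpolated gradient field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .map_io import DensityMap, interpolate_density

__all__ = ["Segment", "segment_map", "locate_segment_maximum"]

# all 26 neighbor offsets
_OFFSETS = np.array([
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
], dtype=int)


@dataclass
class Segment:
    voxel_ids: np.ndarray        # (n, 3) integer voxel indices
    volume: float                # voxel count x voxel volume (A^3)
    p_max: np.ndarray            # A position of highest interpolated density
    peak_value: float            # density at p_max (map units)
    converged: bool = True

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)


def _steepest_ascent_labels(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Label each masked voxel by the local maximum its ascent path reaches.

    Returns a flat int array over the full grid: -1 outside the mask,
    otherwise the flat index of the terminating local maximum. The parent
    of a voxel is its strictly-greater-valued 26-neighbor of maximal
    value inside the mask; voxels with no such neighbor are local maxima.
    """
    shape = values.shape
    coords = np.argwhere(mask)
    flat = np.ravel_multi_index(coords.T, shape)
    own = values[mask]

    best_val = np.full(len(coords), -np.inf)
    best_flat = flat.copy()  # default parent: self (local maximum)
    for off in _OFFSETS:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        if not ok.any():
            continue
        nb_flat = np.ravel_multi_index(nb[ok].T, shape)
        in_mask = mask.reshape(-1)[nb_flat]
        vals = np.full(len(coords), -np.inf)
        sel = np.flatnonzero(ok)[in_mask]
        vals[sel] = values.reshape(-1)[nb_flat[in_mask]]
        better = vals > best_val
        best_val[better] = vals[better]
        best_flat[better] = -1  # placeholder, fixed below
        # store neighbor flat index where it improved
        tmp = np.full(len(coords), -1, dtype=np.int64)
        tmp[sel] = nb_flat[in_mask]
        best_flat[better] = tmp[better]

    # a parent only counts if strictly greater than the voxel itself
    parent_flat = np.where(best_val > own, best_flat, flat)

    parent = np.full(values.size, -1, dtype=np.int64)
    parent[flat] = parent_flat
    # pointer jumping until every path reaches its fixed point
    while True:
        nxt = parent[parent[flat]]
        if np.array_equal(nxt, parent[flat]):
            break
        parent[flat] = nxt
    return parent


def segment_map(dmap: DensityMap, threshold: float) -> list[Segment]:
    """Partition voxels >= threshold into watershed segments.

    Segments are sorted by decreasing volume, ties broken by descending
    peak value then lexicographically smallest voxel index, so the order
    is deterministic.
    """
    mask = dmap.values >= threshold
    if not mask.any():
        return []
    labels = _steepest_ascent_labels(dmap.values, mask)
    coords = np.argwhere(mask)
    flat = np.ravel_multi_index(coords.T, dmap.values.shape)
    roots = labels[flat]

    voxel_volume = float(np.prod(dmap.voxel_size))
    grads = _gradient_maps(dmap)
    segments = []
    order = np.argsort(roots, kind="stable")
    roots_sorted = roots[order]
    bounds = np.flatnonzero(np.diff(roots_sorted)) + 1
    for chunk in np.split(order, bounds):
        vox = coords[chunk]
        seg = Segment(
            voxel_ids=vox,
            volume=len(vox) * voxel_volume,
            p_max=np.zeros(3),
            peak_value=0.0,
        )
        locate_segment_maximum(dmap, seg, grads=grads)
        segments.append(seg)
    segments.sort(key=lambda s: (-s.n_voxels, -s.peak_value,
                                 tuple(s.voxel_ids.min(axis=0))))
    return segments


def _gradient_maps(dmap: DensityMap) -> list[DensityMap]:
    return [dmap.copy(values=g)
            for g in np.gradient(dmap.values, *dmap.voxel_size)]


def _interp_gradient(grads, position) -> np.ndarray:
    g = np.empty(3)
    for axis in range(3):
        g[axis] = interpolate_density(grads[axis], position)
    return g


def locate_segment_maximum(dmap: DensityMap, segment: Segment,
                           step_tol: float = 0.01,
                           max_steps: int = 1000,
                           grads: list[DensityMap] | None = None) -> np.ndarray:
    """Refine the segment's density maximum off-grid.

    Starting from the best member voxel, damped ascent follows the
    trilinearly interpolated central-difference gradient field to its
    stationary point (a plain trilinear value ascent would terminate on
    a voxel center, since a multilinear function is maximized at cell
    corners). Steps are capped at a quarter voxel; the step is halved
    whenever the gradient norm fails to decrease, and convergence is a
    step below ``step_tol`` Angstrom. The reported peak value is the
    larger of the interpolated density at the refined point and the best
    member voxel value, so peak_value >= max member voxel always holds.
    """
    vox = segment.voxel_ids
    vals = dmap.values[vox[:, 0], vox[:, 1], vox[:, 2]]
    best = vox[np.argmax(vals)]
    start_val = float(vals.max())
    pos = dmap.index_to_position(best)

    if grads is None:
        grads = _gradient_maps(dmap)
    cap = 0.25 * float(dmap.voxel_size.min())
    # the refined maximum stays inside the segment's bounding region
    # (and the grid): the ascent must not drift into a neighbor segment
    lo = np.maximum(dmap.index_to_position(vox.min(axis=0)),
                    dmap.index_to_position([0, 0, 0]))
    hi = np.minimum(dmap.index_to_position(vox.max(axis=0)),
                    dmap.index_to_position(np.asarray(dmap.shape) - 1))

    step_len = cap
    prev_gnorm = np.inf
    converged = False
    for _ in range(max_steps):
        g = _interp_gradient(grads, pos)
        gnorm = float(np.linalg.norm(g))
        if gnorm == 0.0:
            converged = True
            break
        if gnorm >= prev_gnorm:
            step_len *= 0.5  # damping near the stationary point
        prev_gnorm = gnorm
        if step_len < step_tol:
            converged = True
            break
        pos = np.clip(pos + g * (step_len / gnorm), lo, hi)

    cur_val = max(float(interpolate_density(dmap, pos)), start_val)
    segment.p_max = pos
    segment.peak_value = cur_val
    segment.converged = converged
    return pos
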