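"""Q-score atomic resolvability.

The Q score of a point is the normalized cross-correlation (about the
mean) between map values sampled on concentric spherical shells around
the point and a reference Gaussian profile evaluated at the same radii.
A perfectly resolved atom in a map rendered at the reference width gives
Q = 1; pure noise gives Q near 0. Because the correlation is computed
about the mean, Q is independent of the map's scale and offset and of
the contour level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .map_io import DensityMap, interpolate_density
from .model_io import StructureModel

__all__ = [
    "QScoreParams",
    "AtomQ",
    "point_q_score",
    "atom_q_scores",
    "residue_q_table",
    "UNDEFINED_Q",
]

#: sentinel for positions where too few usable sample points remain;
#: compares False against any threshold, so it fails every Q criterion
UNDEFINED_Q = float("nan")

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class QScoreParams:
    ref_sigma: float = 0.6        # reference Gaussian width (A)
    max_radius: float = 2.0       # outer sampling radius (A)
    radial_step: float = 0.1      # shell spacing (A)
    points_per_shell: int = 8
    exclusion: bool = True        # drop points nearer another atom
    min_points: int = 8           # minimum usable samples for a defined Q

    def __post_init__(self):
        if not (0 < self.radial_step <= self.max_radius):
            raise ValueError("require 0 < radial_step <= max_radius")
        if self.ref_sigma <= 0:
            raise ValueError("ref_sigma must be positive")


@dataclass(frozen=True)
class AtomQ:
    q_full: float
    q_half1: float = UNDEFINED_Q
    q_half2: float = UNDEFINED_Q

    @property
    def triplet(self) -> tuple[float, float, float]:
        return (self.q_full, self.q_half1, self.q_half2)

    def min_q(self) -> float:
        t = np.asarray(self.triplet, dtype=float)
        return UNDEFINED_Q if np.any(np.isnan(t)) else float(t.min())


def shell_sample_points(params: QScoreParams) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic quasi-uniform sample directions per radial shell.

    Returns (offsets, radii): unit-sphere Fibonacci points scaled by each
    shell radius, rotated azimuthally per shell so consecutive shells do
    not reuse directions; radius 0 contributes the center point itself.
    """
    radii_levels = np.arange(0.0, params.max_radius + 1e-9, params.radial_step)
    offsets = [np.zeros((1, 3))]
    radii = [np.zeros(1)]
    n = params.points_per_shell
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    for s, r in enumerate(radii_levels[1:], start=1):
        phi = _GOLDEN_ANGLE * k + 0.61803398875 * s  # per-shell twist
        dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
        offsets.append(r * dirs)
        radii.append(np.full(n, r))
    return np.vstack(offsets), np.concatenate(radii)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return UNDEFINED_Q
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def point_q_score(dmap: DensityMap, position, neighbors=None,
                  params: QScoreParams | None = None) -> float:
    """Q score of an arbitrary point against a density map.

    ``neighbors`` are positions of other atoms; when exclusion is on,
    sample points nearer to any neighbor than to the query position are
    discarded so each atom is scored against its own density only.
    Returns the undefined-Q sentinel (NaN) when fewer than
    ``params.min_points`` usable samples remain.
    """
    params = params or QScoreParams()
    position = np.asarray(position, dtype=float)
    offsets, radii = shell_sample_points(params)
    pts = position + offsets

    keep = dmap.contains(pts)
    if params.exclusion and neighbors is not None and len(neighbors) > 0:
        tree = neighbors if isinstance(neighbors, cKDTree) else cKDTree(
            np.atleast_2d(np.asarray(neighbors, dtype=float)))
        nearest, _ = tree.query(pts)
        keep &= nearest > radii
    if keep.sum() < params.min_points or len(np.unique(radii[keep])) < 3:
        return UNDEFINED_Q

    values = interpolate_density(dmap, pts[keep])
    reference = np.exp(-(radii[keep] ** 2) / (2.0 * params.ref_sigma ** 2))
    return _pearson(values, reference)


def atom_q_scores(dmap: DensityMap, model: StructureModel,
                  params: QScoreParams | None = None,
                  half1: DensityMap | None = None,
                  half2: DensityMap | None = None) -> list[AtomQ]:
    """Per-atom Q with all other atoms as exclusion neighbors.

    Also applicable to maps rendered from coordinates ("simulated" maps),
    in which case the result is the simulated-map resolvability (simQ).
    Atoms outside a map receive the undefined-Q sentinel for that map.
    """
    params = params or QScoreParams()
    out = []
    all_idx = np.arange(len(model))
    for i, atom in enumerate(model.atoms):
        neigh = model.coords[all_idx != i]
        qs = []
        for m in (dmap, half1, half2):
            if m is None:
                qs.append(UNDEFINED_Q)
            elif not m.contains(atom.position):
                qs.append(UNDEFINED_Q)
            else:
                qs.append(point_q_score(m, atom.position, neigh, params))
        out.append(AtomQ(*qs))
    return out


def residue_q_table(model: StructureModel, atom_q: list[AtomQ]) -> dict:
    """Unweighted per-residue mean of full-map atom Q scores.

    Residues whose atoms all carry undefined Q map to the sentinel.
    """
    table: dict[tuple[str, int], float] = {}
    for rid in model.residue_ids:
        idx = model.residue_atom_indices(rid)
        vals = np.array([atom_q[i].q_full for i in idx], dtype=float)
        vals = vals[~np.isnan(vals)]
        table[rid] = float(vals.mean()) if len(vals) else UNDEFINED_Q
    return table


def write_residue_q_tsv(table: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tresidue\tQ\n")
        for (chain, seq), q in table.items():
            fh.write(f"{chain}\t{seq}\t{q:.4f}\n")
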