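"""Cross-validation of solvent placements between two independent maps.

A placement is "consensus" when a counterpart of the same kind in the
other map/model pair passes two criteria concurrently: the two positions
superimpose within 1 A after a least-squares rigid alignment of the
local RNA (all heavy atoms of nucleotides with any atom within 10 A of
either solvent position), and both bind the same RNA atoms — each
close binder of one placement must lie within an expanded distance
window of the other placement, and vice versa. Waters use a close-binder
window of 2.5-3.2 A (expanded to 3.5 A); Mg2+ uses 1.8-2.2 A (expanded
to 2.5 A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import StructureModel, residues_near

__all__ = [
    "ConsensusPair",
    "ConsensusWindows",
    "WATER_WINDOWS",
    "MG_WINDOWS",
    "local_alignment",
    "binding_site_atoms",
    "same_binding_site",
    "consensus_classify",
    "consensus_fraction_percent",
]


class AlignmentError(ValueError):
    """Raised when too few common atoms exist for a local alignment."""


@dataclass(frozen=True)
class ConsensusWindows:
    close_lo: float
    close_hi: float
    expanded_hi: float
    expand_step: float = 0.3

    @property
    def expanded_lo(self) -> float:
        return self.close_lo


#: close binders 2.5-3.2 A, expanded window 2.5-3.5 A
WATER_WINDOWS = ConsensusWindows(2.5, 3.2, 3.5)
#: close binders 1.8-2.2 A, expanded window 1.8-2.5 A
MG_WINDOWS = ConsensusWindows(1.8, 2.2, 2.5)


@dataclass
class ConsensusPair:
    index_a: int
    index_b: int
    post_alignment_distance: float
    site_match: bool

    @property
    def consensus(self) -> bool:
        return self.post_alignment_distance <= 1.0 and self.site_match


def _kabsch(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid superposition (rotation + translation).

    Returns (R, t) such that moving @ R.T + t best fits fixed.
    """
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cf - r @ cm
    return r, t


def _common_atoms(model_a: StructureModel, model_b: StructureModel,
                  residue_ids: set):
    """Coordinates of atoms matched by (residue_id, atom name)."""
    index_b = {
        (a.residue_id, a.name): a.position
        for a in model_b.atoms if a.residue_id in residue_ids
    }
    pa, pb = [], []
    for a in model_a.atoms:
        key = (a.residue_id, a.name)
        if a.residue_id in residue_ids and key in index_b:
            pa.append(a.position)
            pb.append(index_b[key])
    return np.asarray(pa, dtype=float), np.asarray(pb, dtype=float)


def local_alignment(model_a: StructureModel, model_b: StructureModel,
                    pos_a, pos_b, radius: float = 10.0):
    """Rigid transform aligning model_b's local RNA onto model_a's.

    The local RNA is every nucleotide with any heavy atom within
    ``radius`` of either solvent position (measured in its own model).
    Returns (R, t, rmsd): apply as ``x @ R.T + t`` to model_b-frame
    coordinates. Raises AlignmentError with fewer than 3 common atoms.
    """
    rids = residues_near(model_a, pos_a, radius) \
        | residues_near(model_b, pos_b, radius)
    pa, pb = _common_atoms(model_a, model_b, rids)
    if len(pa) < 3:
        raise AlignmentError(
            f"only {len(pa)} common heavy atoms in the 10 A neighborhoods")
    r, t = _kabsch(pb, pa)
    moved = pb @ r.T + t
    rmsd = float(np.sqrt(((moved - pa) ** 2).sum(axis=1).mean()))
    return r, t, rmsd


def binding_site_atoms(model: StructureModel, position,
                       windows: ConsensusWindows) -> list:
    """RNA heavy atoms in the close-binder window around a position.

    If the window is empty, its outer radius grows once by the expansion
    step (e.g. waters 2.5-3.2 -> 2.5-3.5 A); a still-empty result is
    returned as an empty list and the pair will fail the site match.
    """
    pos = np.asarray(position, dtype=float)
    polymer = model.is_polymer_atom()

    def in_window(hi):
        idx = model.tree.query_ball_point(pos, hi)
        out = []
        for i in idx:
            if not polymer[i]:
                continue
            d = np.linalg.norm(model.coords[i] - pos)
            if windows.close_lo <= d <= hi:
                out.append(model.atoms[i])
        return out

    atoms = in_window(windows.close_hi)
    if not atoms:
        atoms = in_window(windows.close_hi + windows.expand_step)
    return atoms


def same_binding_site(site_a, site_b, model_a: StructureModel,
                      model_b: StructureModel, pos_a, pos_b,
                      windows: ConsensusWindows) -> bool:
    """True iff the two placements share the same close RNA atoms.

    Every close binder of a must lie within the expanded window of pos_b
    (located in model_b by residue_id + atom name) and vice versa.
    """
    if not site_a or not site_b:
        return False
    lookup_a = {(a.residue_id, a.name): a.position for a in model_a.atoms}
    lookup_b = {(a.residue_id, a.name): a.position for a in model_b.atoms}

    def all_within(site, lookup, pos):
        for atom in site:
            other = lookup.get((atom.residue_id, atom.name))
            if other is None:
                return False
            d = np.linalg.norm(other - np.asarray(pos, dtype=float))
            if not windows.expanded_lo <= d <= windows.expanded_hi:
                return False
        return True

    return all_within(site_a, lookup_b, pos_b) \
        and all_within(site_b, lookup_a, pos_a)


def consensus_classify(placements_a, placements_b,
                       model_a: StructureModel, model_b: StructureModel,
                       kind: str = "water",
                       windows: ConsensusWindows | None = None,
                       prefilter: float = 5.0):
    """Label placements of one kind as consensus between two models.

    Candidate pairs (same kind, unaligned distance below ``prefilter``)
    are evaluated for superposability (<= 1 A after local alignment) and
    binding-site identity; qualifying pairs are matched greedily one to
    one by ascending post-alignment distance. Returns
    (labels_a, labels_b, pairs) where the labels are boolean arrays.
    """
    if windows is None:
        windows = WATER_WINDOWS if kind == "water" else MG_WINDOWS
    idx_a = [i for i, p in enumerate(placements_a) if p.kind == kind]
    idx_b = [i for i, p in enumerate(placements_b) if p.kind == kind]

    candidates = []
    for i in idx_a:
        pa = np.asarray(placements_a[i].position, dtype=float)
        for j in idx_b:
            pb = np.asarray(placements_b[j].position, dtype=float)
            if np.linalg.norm(pa - pb) > prefilter:
                continue
            try:
                r, t, _ = local_alignment(model_a, model_b, pa, pb)
            except AlignmentError:
                continue
            dist = float(np.linalg.norm(pb @ r.T + t - pa))
            if dist > 1.0:
                continue
            # sites and cross-distances are measured in each model's own
            # frame; only the superposability test uses the alignment
            site_a = binding_site_atoms(model_a, pa, windows)
            site_b = binding_site_atoms(model_b, pb, windows)
            if same_binding_site(site_a, site_b, model_a, model_b,
                                 pa, pb, windows):
                candidates.append(ConsensusPair(i, j, dist, True))

    # a placement is consensus when at least one counterpart qualifies;
    # the returned pairs additionally resolve multiplicities one-to-one
    # (greedy by distance) so the consensus tally never double-counts
    labels_a = np.zeros(len(placements_a), dtype=bool)
    labels_b = np.zeros(len(placements_b), dtype=bool)
    for c in candidates:
        labels_a[c.index_a] = True
        labels_b[c.index_b] = True
    candidates.sort(key=lambda c: c.post_alignment_distance)
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for c in candidates:
        if c.index_a in used_a or c.index_b in used_b:
            continue
        used_a.add(c.index_a)
        used_b.add(c.index_b)
        pairs.append(c)
    return labels_a, labels_b, pairs


def consensus_fraction_percent(n_consensus: int, n_total: int) -> float:
    """Percentage of modelled placements that are consensus."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_consensus / n_total
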