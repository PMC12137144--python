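"""Segmentation-guided water and ion modelling (SWIM).

The modelling loop segments the full map at 3 sigma above the mean,
visits segments in decreasing-volume order, and applies an ordered rule
cascade at each segment's interpolated density maximum (P_max):

(i)    Q score at P_max >= q_peak_min (default 0.7) in the full map and
       in both half-maps — the peak must be resolvable in independent
       reconstructions, not just in the average;
(ii)   the nearest RNA atom's residue must itself be well resolved
       (residue Q >= q_res_min, default 0.6);
(iii)  interpolated density at P_max >= avgD + 5 sigma;
(iv)   clash: a non-polar atom (C or P) within 3.2 A vetoes water, and a
       carbon within 3.0 A vetoes an ion;
(v)    Mg2+ is modelled when an electronegative atom (O or acceptor N)
       lies 1.8-2.5 A away and no protonated (donor) nitrogen lies
       1.8-3.4 A away;
(vi)   otherwise a water is modelled when any N/O lies 2.5-3.4 A away,
       or a previously placed Mg2+ lies 1.8-2.5 A away;
(vii)  a new water within minWaterD (2.5 A) of an accepted water, or a
       new ion within minIonD (4.5 A) of an accepted ion, is discarded.

Passes repeat until a pass adds nothing: a Mg2+ accepted in an earlier
pass becomes an eligible water binder under rule (vi) in later passes.
Only water and Mg2+ bound directly to the RNA are ever assigned;
monovalent ions are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .map_io import DensityMap, GridStats, interpolate_density, map_stats
from .model_io import StructureModel, annotate_chemistry
from .qscore import (AtomQ, QScoreParams, atom_q_scores, point_q_score,
                     residue_q_table)
from .segmentation import segment_map

__all__ = ["SwimParams", "SolventPlacement", "RuleContext", "evaluate_peak", "run_swim",
           "check_placements"]


@dataclass(frozen=True)
class SwimParams:
    seg_sigma: float = 3.0      # segmentation threshold, multiples of sigma
    peak_sigma: float = 5.0     # minimum peak density, multiples of sigma
    q_peak_min: float = 0.7     # minimum Q at P_max, full and both half maps
    q_res_min: float = 0.6      # minimum residue Q of the nearest nucleotide
    water_clash: float = 3.2    # non-polar clash radius vetoing water (A)
    ion_clash: float = 3.0      # carbon clash radius vetoing an ion (A)
    ion_bind_lo: float = 1.8    # electronegative window for Mg2+ (A)
    ion_bind_hi: float = 2.5
    repel_lo: float = 1.8       # protonated-N window that vetoes Mg2+ (A)
    repel_hi: float = 3.4
    water_bind_lo: float = 2.5  # N/O hydrogen-bond window for water (A)
    water_bind_hi: float = 3.4
    water_mg_lo: float = 1.8    # placed-Mg2+ binder window for water (A)
    water_mg_hi: float = 2.5
    min_water_d: float = 2.5    # minimum water-water distance (minWaterD)
    min_ion_d: float = 4.5      # minimum ion-ion distance (minIonD)
    overlap_min: float = 1.8    # a peak nearer than this to any modelled
    max_iterations: int = 10    # atom is that atom's own density, not solvent

    def __post_init__(self):
        for lo, hi in ((self.ion_bind_lo, self.ion_bind_hi),
                       (self.repel_lo, self.repel_hi),
                       (self.water_bind_lo, self.water_bind_hi),
                       (self.water_mg_lo, self.water_mg_hi)):
            if not lo < hi:
                raise ValueError("distance windows require lo < hi")


@dataclass
class SolventPlacement:
    kind: str                    # "water" | "magnesium"
    position: np.ndarray
    peak_density_sigma: float    # (value - avgD) / sigma
    q: AtomQ
    bound_atoms: list = field(default_factory=list)
    iteration: int = 0
    rejected_reason: str = ""    # empty for accepted

    @property
    def accepted(self) -> bool:
        return self.rejected_reason == ""


class RuleContext:
    """Static (placement-independent) data shared across passes."""

    def __init__(self, full_map, half1, half2, model, params, qparams):
        self.full_map, self.half1, self.half2 = full_map, half1, half2
        self.params = params
        self.qparams = qparams or QScoreParams()
        self.stats: GridStats = map_stats(full_map)
        if self.stats.is_degenerate:
            raise ValueError("constant full map: sigma thresholds undefined")
        self.rna = model.polymer()
        if not np.any(full_map.contains(self.rna.coords)):
            raise ValueError("no model atoms inside the map bounds")
        flags = annotate_chemistry(self.rna)
        cats = np.array([f.category for f in flags])
        self.nonpolar = cKDTree(self.rna.coords[cats == "nonpolar"])
        self.carbon = cKDTree(self.rna.coords[self.rna.elements == "C"])
        en = cats == "electronegative"
        self.electro_idx = np.flatnonzero(en)
        self.electro = cKDTree(self.rna.coords[en]) if en.any() else None
        pn = cats == "protonated_n"
        self.proton = cKDTree(self.rna.coords[pn]) if pn.any() else None
        on = np.isin(self.rna.elements, ["O", "N"])
        self.on_idx = np.flatnonzero(on)
        self.on = cKDTree(self.rna.coords[on])
        aq = atom_q_scores(full_map, self.rna, self.qparams)
        self.residue_q = residue_q_table(self.rna, aq)

    def q_triplet(self, position) -> AtomQ:
        qs = []
        for m in (self.full_map, self.half1, self.half2):
            if m is None or not m.contains(position):
                qs.append(float("nan"))
            else:
                qs.append(point_q_score(m, position, self.rna.coords,
                                        self.qparams))
        return AtomQ(*qs)

    def _in_window(self, tree_idx, tree, position, lo, hi):
        if tree is None:
            return np.array([], dtype=int)
        hits = tree.query_ball_point(position, hi)
        if not hits:
            return np.array([], dtype=int)
        d = np.linalg.norm(self.rna.coords[tree_idx[hits]] - position, axis=1)
        return tree_idx[np.asarray(hits, dtype=int)[d >= lo]]


def evaluate_peak(p_max, model_ctx: "RuleContext", placed: list,
                  iteration: int = 0) -> SolventPlacement:
    """Apply rules (i)-(vii) at one density peak; first failure wins."""
    ctx = model_ctx
    p = ctx.params
    pos = np.asarray(p_max, dtype=float)

    def rejected(reason, kind="", q=None, dens=np.nan, bound=None):
        return SolventPlacement(kind, pos, dens, q or AtomQ(float("nan")),
                                bound or [], iteration, reason)

    # (i) resolvability of the peak in full map and both half-maps
    q = ctx.q_triplet(pos)
    min_q = q.min_q()
    if np.isnan(min_q) or min_q < p.q_peak_min:
        return rejected("(i) Q at peak below q_peak_min", q=q)

    # (ii) nearest nucleotide must be well resolved
    _, nearest = ctx.rna.tree.query(pos)
    res_q = ctx.residue_q[ctx.rna.atoms[int(nearest)].residue_id]
    if np.isnan(res_q) or res_q < p.q_res_min:
        return rejected("(ii) nearest nucleotide poorly resolved", q=q)

    # (iii) peak density in sigma units
    dens = (interpolate_density(ctx.full_map, pos) - ctx.stats.avgD) \
        / ctx.stats.sigma
    if dens < p.peak_sigma:
        return rejected("(iii) peak density below threshold", q=q, dens=dens)

    # (iv) clash checks. A peak essentially coinciding with a modelled
    # atom (or an accepted placement) is that atom's own density: every
    # binding window in the cascade starts at 1.8 A, so anything closer
    # cannot be a distinct solvent site.
    d_nearest, _ = ctx.rna.tree.query(pos)
    if d_nearest < p.overlap_min or any(
            np.linalg.norm(pl.position - pos) < p.overlap_min
            for pl in placed):
        return rejected("(iv) overlaps a modelled atom", q=q, dens=dens)
    water_clash = bool(ctx.nonpolar.query_ball_point(pos, p.water_clash))
    ion_clash = bool(ctx.carbon.query_ball_point(pos, p.ion_clash))
    if water_clash and ion_clash:
        return rejected("(iv) clash with non-polar atoms", q=q, dens=dens)

    # (v) Mg2+: electronegative contact, no repelling protonated nitrogen
    if not ion_clash:
        en_hits = ctx._in_window(ctx.electro_idx, ctx.electro, pos,
                                 p.ion_bind_lo, p.ion_bind_hi)
        if len(en_hits) and not _has_in_window(ctx, ctx.proton, pos,
                                               p.repel_lo, p.repel_hi):
            ions = [pl for pl in placed if pl.kind == "magnesium"]
            if any(np.linalg.norm(pl.position - pos) < p.min_ion_d
                   for pl in ions):
                return rejected("(vii) too close to an accepted ion",
                                kind="magnesium", q=q, dens=dens)
            bound = [ctx.rna.atoms[i] for i in en_hits]
            return SolventPlacement("magnesium", pos, dens, q, bound,
                                    iteration, "")

    # (vi) water: N/O hydrogen-bond partner, or a previously placed Mg2+
    if not water_clash:
        on_hits = ctx._in_window(ctx.on_idx, ctx.on, pos,
                                 p.water_bind_lo, p.water_bind_hi)
        mg_binder = any(
            pl.kind == "magnesium"
            and p.water_mg_lo <= np.linalg.norm(pl.position - pos)
            <= p.water_mg_hi
            for pl in placed
        )
        if len(on_hits) or mg_binder:
            waters = [pl for pl in placed if pl.kind == "water"]
            if any(np.linalg.norm(pl.position - pos) < p.min_water_d
                   for pl in waters):
                return rejected("(vii) too close to an accepted water",
                                kind="water", q=q, dens=dens)
            bound = [ctx.rna.atoms[i] for i in on_hits]
            return SolventPlacement("water", pos, dens, q, bound,
                                    iteration, "")

    if water_clash or ion_clash:
        return rejected("(iv) clash with non-polar atoms", q=q, dens=dens)
    return rejected("(v)/(vi) no binder in range", q=q, dens=dens)


def _has_in_window(ctx, tree, pos, lo, hi) -> bool:
    if tree is None:
        return False
    hits = tree.query_ball_point(pos, hi)
    if not hits:
        return False
    pts = tree.data[hits]
    d = np.linalg.norm(pts - pos, axis=1)
    return bool(np.any((d >= lo) & (d <= hi)))


def run_swim(full_map: DensityMap, half1: DensityMap, half2: DensityMap,
             model: StructureModel, params: SwimParams | None = None,
             qparams: QScoreParams | None = None,
             return_log: bool = False):
    """Run the full SWIM loop until a pass adds no placement.

    Returns the list of accepted placements (with their pass index);
    with ``return_log=True`` also returns every evaluation, including the
    final rejection reason of segments that were never accepted.
    """
    params = params or SwimParams()
    ctx = RuleContext(full_map, half1, half2, model, params, qparams)
    threshold = ctx.stats.threshold(params.seg_sigma)
    segments = segment_map(full_map, threshold)

    accepted: list[SolventPlacement] = []
    accepted_for: dict[int, SolventPlacement] = {}
    last_eval: dict[int, SolventPlacement] = {}
    for iteration in range(1, params.max_iterations + 1):
        added = 0
        for si, seg in enumerate(segments):
            if si in accepted_for:
                continue
            if not (full_map.contains(seg.p_max)
                    and (half1 is None or half1.contains(seg.p_max))
                    and (half2 is None or half2.contains(seg.p_max))):
                last_eval[si] = SolventPlacement(
                    "", seg.p_max, np.nan, AtomQ(float("nan")), [],
                    iteration, "peak outside half-map bounds")
                continue
            result = evaluate_peak(seg.p_max, ctx, accepted, iteration)
            last_eval[si] = result
            if result.accepted:
                accepted.append(result)
                accepted_for[si] = result
                added += 1
        if added == 0:
            break

    if return_log:
        log = [(segments[si], last_eval[si]) for si in sorted(last_eval)]
        return accepted, log
    return accepted


def check_placements(placements: list[SolventPlacement],
                     params: SwimParams | None = None) -> list[str]:
    """Independent post-hoc verification of accepted-placement invariants.

    Returns a list of violation messages (empty when all hold): peak
    density and Q thresholds, and pairwise minimum distances within each
    solvent kind.
    """
    params = params or SwimParams()
    problems = []
    acc = [p for p in placements if p.accepted]
    for i, p in enumerate(acc):
        if p.peak_density_sigma < params.peak_sigma:
            problems.append(f"placement {i}: peak density below threshold")
        mq = p.q.min_q()
        if np.isnan(mq) or mq < params.q_peak_min:
            problems.append(f"placement {i}: Q below q_peak_min")
    for kind, dmin in (("water", params.min_water_d),
                       ("magnesium", params.min_ion_d)):
        pts = np.array([p.position for p in acc if p.kind == kind])
        if len(pts) > 1:
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < dmin:
                problems.append(f"{kind} pair closer than {dmin} A")
    return problems
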