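"""Self-contained synthetic fixtures for solvent-modelling experiments.

Generates (1) a procedural A-form RNA duplex built from rigid nucleotide
templates on fixed fiber geometry (rise 2.81 A, twist 32.7 deg/bp);
(2) planted ground-truth solvent — waters at hydrogen-bonding distance
from polar atoms, Mg2+ at inner-sphere distance from phosphate oxygens —
whose geometry satisfies the SWIM placement rules by construction;
(3) rendered full and half maps, the half-maps carrying independent
Gaussian noise so their voxelwise mean is exactly the full map; and
(4) solvent-coordinate ensembles with planted per-site occupancy and
positional spread. Identical spec + seed reproduces the fixture bitwise.

The nucleotide templates are simplified idealized geometries: correct
atom names, elements, bonded topology distances and planarity for the
chemistry rules, not refined stereochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import Atom, StructureModel, annotate_chemistry
from .qscore import AtomQ
from .shell_metrics import render_model_map
from .solvent_dynamics import SolventFrame
from .swim import SolventPlacement, SwimParams

__all__ = [
    "FixtureSpec",
    "TEMPLATES",
    "generate_rna_fragment",
    "place_solvent",
    "model_with_solvent",
    "render_synthetic_maps",
    "generate_water_ensemble",
    "make_fixture",
    "HELIX_RISE",
    "HELIX_TWIST_DEG",
]

HELIX_RISE = 2.81        # A per base pair
HELIX_TWIST_DEG = 32.7   # degrees per base pair
_BASE_RADIUS = 4.5       # A, base-center distance from the helix axis
_DYAD_OFFSET_DEG = 210.0  # azimuthal offset of the second strand

# Rigid nucleotide templates (local frame, A). Base ring in the z=0
# plane; sugar-phosphate arm extends toward -y / +z.
TEMPLATES = {
    "A": {
        "N1": (0.000, 1.380, 0.000),
        "C2": (1.195, 0.690, 0.000),
        "N3": (1.195, -0.690, 0.000),
        "C4": (0.000, -1.380, 0.000),
        "C5": (-1.195, -0.690, 0.000),
        "C6": (-1.195, 0.690, 0.000),
        "N7": (-2.161, -1.483, 0.000),
        "C8": (-1.558, -2.698, 0.000),
        "N9": (-0.204, -2.613, 0.000),
        "N6": (-2.356, 1.360, 0.000),
        "C1'": (-0.318, -4.079, 0.000),
        "O4'": (-0.109, -5.329, 0.840),
        "C4'": (-0.510, -6.531, -0.000),
        "C3'": (-0.967, -6.025, -1.359),
        "C2'": (-0.849, -4.506, -1.199),
        "O2'": (-1.629, -3.617, -1.950),
        "O3'": (-0.697, -6.853, -2.488),
        "C5'": (-0.057, -7.833, 0.571),
        "O5'": (0.724, -8.566, -0.359),
        "P": (1.284, -9.126, -1.751),
        "OP1": (2.616, -9.777, -1.100),
        "OP2": (0.400, -10.223, -2.296),
    },
    "C": {
        "N1": (0.000, 1.380, 0.000),
        "C2": (1.195, 0.690, 0.000),
        "N3": (1.195, -0.690, 0.000),
        "C4": (0.000, -1.380, 0.000),
        "C5": (-1.195, -0.690, 0.000),
        "C6": (-1.195, 0.690, 0.000),
        "O2": (2.269, 1.310, 0.000),
        "N4": (0.000, -2.720, 0.000),
        "C1'": (0.000, 2.850, 0.000),
        "O4'": (-0.209, 4.100, 0.840),
        "C4'": (0.192, 5.302, -0.000),
        "C3'": (0.649, 4.796, -1.359),
        "C2'": (0.531, 3.277, -1.199),
        "O2'": (1.311, 2.388, -1.950),
        "O3'": (0.379, 5.624, -2.488),
        "C5'": (-0.261, 6.604, 0.571),
        "O5'": (-1.042, 7.337, -0.359),
        "P": (-1.602, 7.897, -1.751),
        "OP1": (-2.934, 8.548, -1.100),
        "OP2": (-0.718, 8.994, -2.296),
    },
    "G": {
        "N1": (0.000, 1.380, 0.000),
        "C2": (1.195, 0.690, 0.000),
        "N3": (1.195, -0.690, 0.000),
        "C4": (0.000, -1.380, 0.000),
        "C5": (-1.195, -0.690, 0.000),
        "C6": (-1.195, 0.690, 0.000),
        "N7": (-2.161, -1.483, 0.000),
        "C8": (-1.558, -2.698, 0.000),
        "N9": (-0.204, -2.613, 0.000),
        "O6": (-2.269, 1.310, 0.000),
        "N2": (2.364, 1.365, 0.000),
        "C1'": (-0.318, -4.079, 0.000),
        "O4'": (-0.109, -5.329, 0.840),
        "C4'": (-0.510, -6.531, -0.000),
        "C3'": (-0.967, -6.025, -1.359),
        "C2'": (-0.849, -4.506, -1.199),
        "O2'": (-1.629, -3.617, -1.950),
        "O3'": (-0.697, -6.853, -2.488),
        "C5'": (-0.057, -7.833, 0.571),
        "O5'": (0.724, -8.566, -0.359),
        "P": (1.284, -9.126, -1.751),
        "OP1": (2.616, -9.777, -1.100),
        "OP2": (0.400, -10.223, -2.296),
    },
    "U": {
        "N1": (0.000, 1.380, 0.000),
        "C2": (1.195, 0.690, 0.000),
        "N3": (1.195, -0.690, 0.000),
        "C4": (0.000, -1.380, 0.000),
        "C5": (-1.195, -0.690, 0.000),
        "C6": (-1.195, 0.690, 0.000),
        "O2": (2.269, 1.310, 0.000),
        "O4": (0.000, -2.604, 0.000),
        "C1'": (0.000, 2.850, 0.000),
        "O4'": (-0.209, 4.100, 0.840),
        "C4'": (0.192, 5.302, -0.000),
        "C3'": (0.649, 4.796, -1.359),
        "C2'": (0.531, 3.277, -1.199),
        "O2'": (1.311, 2.388, -1.950),
        "O3'": (0.379, 5.624, -2.488),
        "C5'": (-0.261, 6.604, 0.571),
        "O5'": (-1.042, 7.337, -0.359),
        "P": (-1.602, 7.897, -1.751),
        "OP1": (-2.934, 8.548, -1.100),
        "OP2": (-0.718, 8.994, -2.296),
    },
}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class FixtureSpec:
    n_base_pairs: int = 12
    n_waters: int = 12
    n_mg: int = 2
    resolution: float = 2.2      # nominal rendering resolution (A)
    noise_sd: float = 0.02       # half-map noise, fraction of peak signal
    voxel_size: float = 0.8      # A per voxel
    padding: float = 19.2        # A of empty space around the model
    seed: int = 0


def _rz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _element(name: str) -> str:
    return name[0]


def generate_rna_fragment(n_bp: int, seed: int = 0) -> StructureModel:
    """Ideal A-form-like duplex with a seed-determined random sequence.

    Strand A is chain "A" residues 1..n_bp (5'->3' along +z); strand B is
    chain "B" with the complementary sequence, related by the duplex dyad.
    """
    if n_bp < 2:
        raise ValueError("need at least 2 base pairs")
    rng = np.random.default_rng(seed)
    seq = [str(b) for b in rng.choice(list("ACGU"), size=n_bp)]
    twist = np.deg2rad(HELIX_TWIST_DEG)
    dyad = np.deg2rad(_DYAD_OFFSET_DEG)
    # per-kind pre-rotation puts the sugar-phosphate arm on the outward
    # (+x) side: the glycosidic nitrogen points -y in purine templates
    # and +y in pyrimidine templates
    pre = {k: _rz(np.pi / 2 if k in "AG" else -np.pi / 2) for k in "ACGU"}
    flip = np.diag([1.0, -1.0, -1.0])   # rotation by pi about x (strand 2)
    shift = np.array([_BASE_RADIUS, 0.0, 0.0])

    atoms = []
    for i, base in enumerate(seq):
        comp = _COMPLEMENT[base]
        z = np.array([0.0, 0.0, i * HELIX_RISE])
        r1 = _rz(i * twist)
        r2 = _rz(i * twist + dyad)
        for chain, kind, rot, extra in (
                ("A", base, r1, np.eye(3)),
                ("B", comp, r2, flip)):
            seqnum = i + 1 if chain == "A" else n_bp - i
            for name, xyz in TEMPLATES[kind].items():
                local = extra @ (pre[kind] @ np.asarray(xyz)) + shift
                atoms.append(Atom(
                    name=name, element=_element(name), residue_name=kind,
                    chain=chain, residue_seq=seqnum,
                    position=rot @ local + z,
                ))
    atoms.sort(key=lambda a: (a.chain, a.residue_seq))
    return StructureModel(atoms)


_FIB_N = 48


def _sphere_directions(n: int = _FIB_N) -> np.ndarray:
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def place_solvent(model: StructureModel, n_waters: int, n_mg: int,
                  seed: int = 0,
                  params: SwimParams | None = None) -> list[SolventPlacement]:
    """Plant ground-truth waters and Mg2+ with rule-valid geometry.

    Mg2+ sites sit 2.0-2.1 A from a phosphate oxygen with no protonated
    nitrogen within the repulsion window; waters sit 2.6-3.2 A from a
    polar O/N along an outward direction, clash-free. Mutual minimum
    distances (minWaterD, minIonD) are respected. If the model offers
    fewer valid sites than requested, the shorter list is returned.
    """
    params = params or SwimParams()
    rng = np.random.default_rng(seed)
    flags = annotate_chemistry(model)
    cats = np.array([f.category for f in flags])
    nonpolar = model.coords[cats == "nonpolar"]
    electro = model.coords[cats == "electronegative"]
    proton = model.coords[cats == "protonated_n"]
    on_coords = model.coords[np.isin(model.elements, ["O", "N"])]
    dirs = _sphere_directions()

    def min_dist(point, coords):
        if len(coords) == 0:
            return np.inf
        return float(np.linalg.norm(coords - point, axis=1).min())

    placements: list[SolventPlacement] = []

    def positions(kind):
        return np.array([p.position for p in placements if p.kind == kind]) \
            if any(p.kind == kind for p in placements) else np.zeros((0, 3))

    # --- Mg2+ at phosphate oxygens ------------------------------------
    op_idx = np.flatnonzero(np.isin(model.names, ["OP1", "OP2"]))
    rng.shuffle(op_idx)
    for ai in op_idx:
        if sum(p.kind == "magnesium" for p in placements) >= n_mg:
            break
        anchor = model.coords[ai]
        for direction in dirs[rng.permutation(_FIB_N)]:
            pos = anchor + 2.05 * direction
            if min_dist(pos, model.coords) < 2.0:
                continue
            if not params.ion_bind_lo <= min_dist(pos, electro) \
                    <= params.ion_bind_hi:
                continue
            if min_dist(pos, proton) <= params.repel_hi:
                continue
            if min_dist(pos, model.coords[model.elements == "C"]) \
                    <= params.ion_clash:
                continue
            if min_dist(pos, positions("magnesium")) < params.min_ion_d:
                continue
            placements.append(SolventPlacement(
                "magnesium", pos, np.inf, AtomQ(1.0, 1.0, 1.0),
                [model.atoms[ai]], 0, ""))
            break

    # --- waters at polar atoms ----------------------------------------
    polar_idx = np.flatnonzero(
        (cats == "electronegative") | (cats == "protonated_n"))
    rng.shuffle(polar_idx)
    for ai in polar_idx:
        if sum(p.kind == "water" for p in placements) >= n_waters:
            break
        anchor = model.coords[ai]
        for direction in dirs[rng.permutation(_FIB_N)]:
            pos = anchor + 2.9 * direction
            d_model = min_dist(pos, model.coords)
            if not 2.6 <= d_model <= 3.2:
                continue
            if min_dist(pos, nonpolar) <= params.water_clash:
                continue
            # must stay unambiguously water even if the refined map peak
            # drifts ~0.3 A: keep electronegatives well beyond the Mg
            # inner-sphere window
            if min_dist(pos, electro) <= params.ion_bind_hi + 0.4:
                continue
            if min_dist(pos, positions("water")) < params.min_water_d:
                continue
            if min_dist(pos, positions("magnesium")) < params.min_water_d:
                continue
            placements.append(SolventPlacement(
                "water", pos, np.inf, AtomQ(1.0, 1.0, 1.0),
                [model.atoms[ai]], 0, ""))
            break
    return placements


def model_with_solvent(model: StructureModel,
                       placements: list[SolventPlacement]) -> StructureModel:
    """Combined model: RNA plus HOH/MG residues for the placements."""
    atoms = list(model.atoms)
    for i, p in enumerate(placements, start=1):
        if p.kind == "water":
            atoms.append(Atom("O", "O", "HOH", "W", i,
                              np.asarray(p.position, dtype=float)))
        else:
            atoms.append(Atom("MG", "Mg", "MG", "I", i,
                              np.asarray(p.position, dtype=float)))
    return StructureModel(atoms)


def render_synthetic_maps(solvated: StructureModel, resolution: float,
                          noise_sd: float, seed: int,
                          voxel_size: float = 0.8, padding: float = 19.2):
    """Render signal and return (full, half1, half2) maps.

    The half-maps are signal plus independent voxelwise Gaussian noise of
    standard deviation ``noise_sd x max(signal)``; the full map is their
    exact voxelwise mean, as for two independent reconstructions of the
    same particle set.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    signal = render_model_map(solvated, resolution, voxel_size=voxel_size,
                              padding=padding)
    rng = np.random.default_rng(seed)
    scale = noise_sd * float(signal.values.max())
    n1 = rng.normal(0.0, scale, signal.shape) if scale > 0 else 0.0
    n2 = rng.normal(0.0, scale, signal.shape) if scale > 0 else 0.0
    half1 = signal.copy(values=signal.values + n1)
    half2 = signal.copy(values=signal.values + n2)
    full = signal.copy(values=(half1.values + half2.values) / 2.0)
    full.label, half1.label, half2.label = "full", "half1", "half2"
    return full, half1, half2


def generate_water_ensemble(sites, n_frames: int, seed: int = 0,
                            model: StructureModel | None = None,
                            rna_rmsd: np.ndarray | None = None,
                            species: str = "water",
                            binder_window=(2.5, 3.5)) -> list[SolventFrame]:
    """Solvent-coordinate frames with planted occupancy and spread.

    Each site is (peak_position, occupancy p, spread s) or a BindingSite
    carrying those attributes. Per frame, each site is occupied with
    probability p; the occupied position is the peak plus isotropic
    Gaussian displacement of per-axis SD s/sqrt(3), so the positional
    RMSF converges to s. Binder annotations are computed from the model
    when one is given, otherwise inherited from the site definition.
    """
    rng = np.random.default_rng(seed)
    parsed = []
    for s in sites:
        if isinstance(s, tuple):
            peak, p, spread = s
            binders = frozenset()
        else:
            peak, p, spread = s.peak_position, s.occupancy, s.rmsf
            binders = s.binder_set
        if not 0.0 <= p <= 1.0 or spread < 0:
            raise ValueError("need occupancy in [0,1] and spread >= 0")
        parsed.append((np.asarray(peak, dtype=float), p, spread, binders))

    frames = []
    for fi in range(n_frames):
        species_l, pos_l, binders_l, mid_l = [], [], [], []
        for si, (peak, p, spread, binders) in enumerate(parsed):
            if rng.random() >= p:
                continue
            pos = peak + rng.normal(0.0, spread / np.sqrt(3.0), 3)
            if model is not None:
                d = np.linalg.norm(model.coords - pos, axis=1)
                sel = (d >= binder_window[0]) & (d <= binder_window[1])
                classes = model.binder_class()
                binders = frozenset(
                    f"{model.chains[i]}.{model.residue_seqs[i]}.{classes[i]}"
                    for i in np.flatnonzero(sel))
            species_l.append(species)
            pos_l.append(pos)
            binders_l.append(binders)
            mid_l.append(si)
        frames.append(SolventFrame(
            frame_index=fi,
            species=np.array(species_l, dtype=object),
            positions=np.array(pos_l, dtype=float).reshape(-1, 3),
            binders=binders_l,
            molecule_ids=np.array(mid_l, dtype=int),
            rna_rmsd=0.0 if rna_rmsd is None else float(rna_rmsd[fi]),
        ))
    return frames


def make_fixture(spec: FixtureSpec | None = None) -> dict:
    """Build the standard end-to-end fixture from one seed.

    Returns a dict with the RNA model, ground-truth placements, the
    solvated model, and the full/half maps.
    """
    spec = spec or FixtureSpec()
    model = generate_rna_fragment(spec.n_base_pairs, spec.seed)
    truth = place_solvent(model, spec.n_waters, spec.n_mg, spec.seed + 1)
    solvated = model_with_solvent(model, truth)
    full, half1, half2 = render_synthetic_maps(
        solvated, spec.resolution, spec.noise_sd, spec.seed + 2,
        voxel_size=spec.voxel_size, padding=spec.padding)
    return {"spec": spec, "model": model, "truth": truth,
            "solvated": solvated, "full": full,
            "half1": half1, "half2": half2}
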