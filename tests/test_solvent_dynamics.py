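import numpy as np
import pytest

from rnaswim.map_io import DensityMap, interpolate_density
from rnaswim.solvent_dynamics import (BindingSite, SolventFrame,
                                      assign_frame_solvent,
                                      find_binding_sites, ion_residence_times,
                                      local_aligned_composite,
                                      molarity_to_number_density,
                                      number_density_to_molarity,
                                      read_frames_tsv,
                                      render_coordinate_density, site_occupancy,
                                      site_rmsf, write_frames_tsv)
from rnaswim.synthetic import generate_water_ensemble


def frame(fi, positions, species="water", ids=None, binders=None, rmsd=0.0):
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    return SolventFrame(
        fi, np.array([species] * n, dtype=object), positions,
        binders if binders is not None else [frozenset()] * n,
        np.asarray(ids if ids is not None else range(n)), rmsd)


class TestUnitConversion:
    def test_printed_reference_pairs(self):
        # bulk water and the mean density at modelled water sites
        assert molarity_to_number_density(55) == pytest.approx(0.033,
                                                               abs=5e-4)
        assert molarity_to_number_density(90) == pytest.approx(0.054,
                                                               abs=5e-4)

    def test_zero_and_round_trip(self):
        assert molarity_to_number_density(0) == 0
        assert number_density_to_molarity(
            molarity_to_number_density(12.3)) == pytest.approx(12.3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            molarity_to_number_density(-1)
        with pytest.raises(ValueError):
            number_density_to_molarity(-1)


class TestCoordinateDensity:
    def test_single_stationary_water_integrates_to_one(self):
        frames = [frame(i, [[8.0, 8.0, 8.0]]) for i in range(20)]
        m = render_coordinate_density(frames, "water", (0, 0, 0),
                                      (40, 40, 40), 0.4)
        assert m.values.sum() * 0.4 ** 3 == pytest.approx(1.0, rel=0.01)

    def test_duplicated_frames_leave_average_unchanged(self):
        f = [frame(0, [[8.0, 8.0, 8.0], [4.0, 4.0, 4.0]])]
        one = render_coordinate_density(f, "water", (0, 0, 0), (32, 32, 32),
                                        0.5)
        double = render_coordinate_density(f + [frame(1, f[0].positions)],
                                           "water", (0, 0, 0), (32, 32, 32),
                                           0.5)
        np.testing.assert_allclose(one.values, double.values, atol=1e-12)

    def test_bulk_density_recovers_55M(self):
        # waters scattered uniformly at bulk number density
        rng = np.random.default_rng(40)
        box = 24.0
        n_per_frame = int(round(molarity_to_number_density(55) * box ** 3))
        frames = [frame(i, rng.uniform(0, box, (n_per_frame, 3)))
                  for i in range(40)]
        m = render_coordinate_density(frames, "water", (0, 0, 0),
                                      (25, 25, 25), 1.0)
        interior = m.values[6:19, 6:19, 6:19]
        assert interior.mean() == pytest.approx(0.033, rel=0.1)

    def test_species_filter(self):
        f = [SolventFrame(0, np.array(["water", "magnesium"], dtype=object),
                          np.array([[8.0, 8.0, 8.0], [4.0, 4.0, 4.0]]),
                          [frozenset(), frozenset()], np.array([0, 1]))]
        m = render_coordinate_density(f, "magnesium", (0, 0, 0),
                                      (32, 32, 32), 0.5)
        peak = np.unravel_index(np.argmax(m.values), m.shape)
        np.testing.assert_allclose(m.index_to_position(peak), [4, 4, 4],
                                   atol=0.5)

    def test_no_frames_rejected(self):
        with pytest.raises(ValueError):
            render_coordinate_density([], "water", (0, 0, 0), (8, 8, 8), 1.0)


class TestBindingSites:
    def test_close_peaks_deduplicated_keeping_denser(self):
        vals = np.zeros((30, 30, 30))
        # two peaks 0.8 A apart (2 voxels at 0.4 A), densities 5 and 3
        vals[10, 10, 10] = 5.0
        vals[12, 10, 10] = 3.0
        m = DensityMap(vals, 0.4, (0, 0, 0))
        sites = find_binding_sites(m, threshold_sigma=3.0)
        assert len(sites) == 1
        np.testing.assert_allclose(sites[0].peak_position,
                                   [4.0, 4.0, 4.0], atol=0.2)

    def test_distant_peaks_both_kept(self):
        vals = np.zeros((30, 30, 30))
        vals[10, 10, 10] = 5.0
        vals[15, 10, 10] = 3.0  # 2 A away
        m = DensityMap(vals, 0.4, (0, 0, 0))
        sites = find_binding_sites(m, threshold_sigma=3.0)
        assert len(sites) == 2
        assert sites[0].peak_density > sites[1].peak_density


class TestAssignment:
    def test_distance_and_binder_requirements(self):
        site = BindingSite(np.array([10.0, 10.0, 10.0]),
                           frozenset({"A.1.O2'"}), "water")
        frames = [
            frame(0, [[11.5, 10.0, 10.0]],
                  binders=[frozenset({"A.1.O2'"})]),      # 1.5 A, same
            frame(1, [[11.5, 10.0, 10.0]],
                  binders=[frozenset({"A.2.OP"})]),       # 1.5 A, different
            frame(2, [[12.5, 10.0, 10.0]],
                  binders=[frozenset({"A.1.O2'"})]),      # 2.5 A away
        ]
        asn = assign_frame_solvent(frames, [site])
        assert [fi for fi, _, _ in asn[0]] == [0]

    def test_species_must_match(self):
        site = BindingSite(np.array([10.0, 10.0, 10.0]), frozenset(),
                           "magnesium")
        frames = [frame(0, [[10.0, 10.0, 10.0]], species="water")]
        asn = assign_frame_solvent(frames, [site])
        assert asn[0] == []


class TestOccupancy:
    def test_definition(self):
        site = BindingSite(np.zeros(3), frozenset(), "water")
        frames = [frame(i, [[0.0, 0.0, 0.0]] if i < 30 else
                        np.zeros((0, 3))) for i in range(100)]
        asn = assign_frame_solvent(frames, [site])
        assert site_occupancy(asn[0], frames) == pytest.approx(0.30)

    def test_rmsd_filter_excludes_frames(self):
        site = BindingSite(np.zeros(3), frozenset(), "water")
        frames = [frame(i, [[0.0, 0.0, 0.0]],
                        rmsd=5.0 if i % 2 else 1.0) for i in range(10)]
        asn = assign_frame_solvent(frames, [site])
        # odd frames are ineligible (RNA deviated > 3.4 A); occupancy is
        # computed over the 5 eligible frames only
        assert site_occupancy(asn[0], frames, rna_rmsd_max=3.4) == 1.0

    def test_no_eligible_frames_is_undefined(self):
        site = BindingSite(np.zeros(3), frozenset(), "water")
        frames = [frame(0, [[0.0, 0.0, 0.0]], rmsd=9.0)]
        asn = assign_frame_solvent(frames, [site])
        assert np.isnan(site_occupancy(asn[0], frames))

    def test_generator_recovery(self):
        frames = generate_water_ensemble(
            [(np.array([5.0, 5.0, 5.0]), 0.6, 0.2)], n_frames=4000, seed=41)
        site = BindingSite(np.array([5.0, 5.0, 5.0]), frozenset(), "water")
        asn = assign_frame_solvent(frames, [site])
        occ = site_occupancy(asn[0], frames)
        assert occ == pytest.approx(0.6, abs=3 * np.sqrt(0.6 * 0.4 / 4000))


class TestRmsf:
    def test_identical_members_zero(self):
        asn = [(i, 0, np.array([1.0, 2.0, 3.0])) for i in range(5)]
        assert site_rmsf(asn) == 0.0

    def test_symmetric_displacement_closed_form(self):
        asn = [(0, 0, np.array([1.0, 0.0, 0.0])),
               (1, 0, np.array([-1.0, 0.0, 0.0]))] * 3
        assert site_rmsf(asn) == pytest.approx(1.0)

    def test_isotropic_gaussian_converges_to_s(self):
        rng = np.random.default_rng(42)
        s = 0.6
        pts = rng.normal(0, s / np.sqrt(3), (20000, 3))
        asn = [(i, 0, p) for i, p in enumerate(pts)]
        assert site_rmsf(asn) == pytest.approx(s, abs=0.01)

    def test_single_member_undefined(self):
        assert np.isnan(site_rmsf([(0, 0, np.zeros(3))]))


class TestResidence:
    def _pattern(self, bits, ion=7):
        asn = []
        for fi, b in enumerate(bits):
            if b:
                asn.append((fi, ion, np.zeros(3)))
        return asn

    def test_single_frame_gap_bridged(self):
        asn = self._pattern([1, 1, 1, 0, 1, 1, 1])
        assert ion_residence_times(asn, 7) == [7]

    def test_two_frame_gap_breaks_run(self):
        asn = self._pattern([1, 1, 0, 0, 1, 1, 1])
        assert ion_residence_times(asn, 7) == [3, 2]

    def test_different_ions_tracked_separately(self):
        asn = [(0, 1, np.zeros(3)), (1, 2, np.zeros(3)), (2, 1, np.zeros(3))]
        assert ion_residence_times(asn, 3) == [3, 1]

    def test_matches_brute_force_scanner(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            bits = rng.random(30) < 0.5
            asn = self._pattern(bits)
            got = ion_residence_times(asn, 30)
            # brute force: split the sorted presence frames wherever the
            # gap exceeds skip+1, duration = span of each group
            present = np.flatnonzero(bits)
            runs = []
            if len(present):
                group = [present[0]]
                for f in present[1:]:
                    if f - group[-1] > 2:
                        runs.append(group[-1] - group[0] + 1)
                        group = [f]
                    else:
                        group.append(f)
                runs.append(group[-1] - group[0] + 1)
            assert got == sorted(runs, reverse=True)


class TestComposite:
    def _const_map(self, value, origin=(0, 0, 0)):
        return DensityMap(np.full((20, 20, 20), float(value)), 1.0, origin)

    def test_identical_submaps_reproduced(self):
        sub = [self._const_map(3.0), self._const_map(3.0)]
        centers = [(5.0, 5.0, 5.0), (12.0, 12.0, 12.0)]
        comp = local_aligned_composite(sub, centers, (0, 0, 0), (20, 20, 20),
                                       1.0)
        covered = ~np.isnan(comp.values)
        assert covered.any()
        np.testing.assert_allclose(comp.values[covered], 3.0, atol=1e-12)

    def test_equidistant_voxel_averages_equally(self):
        sub = [self._const_map(1.0), self._const_map(5.0)]
        centers = np.array([[6.0, 10.0, 10.0], [14.0, 10.0, 10.0]])
        comp = local_aligned_composite(sub, centers, (0, 0, 0), (20, 20, 20),
                                       1.0)
        mid = comp.values[10, 10, 10]  # 4 A from both centers
        assert mid == pytest.approx(3.0)

    def test_uncovered_voxels_are_missing_not_zero(self):
        sub = [self._const_map(2.0)]
        comp = local_aligned_composite(sub, [(5.0, 5.0, 5.0)], (0, 0, 0),
                                       (30, 30, 30), 1.0, radius=4.0)
        assert np.isnan(comp.values[29, 29, 29])
        assert comp.values[5, 5, 5] == pytest.approx(2.0)

    def test_matches_brute_force_weighted_average(self):
        rng = np.random.default_rng(44)
        subs, centers = [], []
        for _ in range(3):
            subs.append(DensityMap(rng.normal(0, 1, (20, 20, 20)), 1.0,
                                   (0, 0, 0)))
            centers.append(rng.uniform(6, 14, 3))
        comp = local_aligned_composite(subs, centers, (0, 0, 0),
                                       (20, 20, 20), 1.0, radius=6.0)
        for _ in range(10):
            idx = tuple(rng.integers(2, 18, 3))
            pos = np.asarray(idx, dtype=float)
            num = den = 0.0
            for s, c in zip(subs, centers):
                d = np.linalg.norm(pos - c)
                if d <= 6.0:
                    w = 1.0 / max(d, 0.1)
                    num += w * interpolate_density(s, pos)
                    den += w
            if den == 0:
                assert np.isnan(comp.values[idx])
            else:
                assert comp.values[idx] == pytest.approx(num / den)


class TestFramesTsv:
    def test_round_trip_preserves_everything(self, tmp_path):
        frames = generate_water_ensemble(
            [(np.array([5.0, 5.0, 5.0]), 0.5, 0.4)], n_frames=50, seed=45)
        path = tmp_path / "frames.tsv"
        write_frames_tsv(frames, path)
        back = read_frames_tsv(path)
        assert len(back) == len(frames)
        for a, b in zip(frames, back):
            assert a.frame_index == b.frame_index
            assert list(a.species) == list(b.species)
            np.testing.assert_allclose(a.positions, b.positions, atol=1e-4)
            assert a.binders == b.binders
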