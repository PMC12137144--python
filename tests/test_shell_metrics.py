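import numpy as np
import pytest

from rnaswim.map_io import (DensityMap, map_stats, shuffle_within_mask,
                            zscore_normalize)
from rnaswim.model_io import Atom, StructureModel
from rnaswim.shell_metrics import (ShellMask, classification_curves,
                                   compare_densities, criteria_pass_rate,
                                   normalized_nucleotide_auprc,
                                   render_model_map, sample_shell_grid,
                                   solvent_shell_mask)


def single_atom_model(pos=(10.0, 10.0, 10.0), name="O2'", res="U"):
    return StructureModel([
        Atom(name, name[0], res, "A", 1, np.asarray(pos, dtype=float))])


class TestShellMask:
    def test_matches_analytic_shell_volume(self):
        model = single_atom_model()
        grid = DensityMap(np.zeros((80, 80, 80)), 0.25, (0, 0, 0))
        mask = solvent_shell_mask(grid, model, {("A", 1): 0.9},
                                  r_min=1.0, r_max=2.0)
        analytic = 4 / 3 * np.pi * (2.0 ** 3 - 1.0 ** 3)
        measured = mask.n_voxels * 0.25 ** 3
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_member_distances_in_range(self, fixture):
        model = fixture["model"]
        rq = {rid: 0.9 for rid in model.residue_ids}
        mask = solvent_shell_mask(fixture["full"], model, rq)
        idx = np.argwhere(mask.mask)
        centers = fixture["full"].origin + idx * fixture["full"].voxel_size
        from scipy.spatial import cKDTree
        d, _ = cKDTree(model.coords).query(centers)
        assert d.min() >= 1.8 and d.max() <= 3.5

    def test_q_filter_can_empty_the_mask(self):
        model = single_atom_model()
        grid = DensityMap(np.zeros((40, 40, 40)), 0.5, (0, 0, 0))
        with pytest.raises(ValueError):
            solvent_shell_mask(grid, model, {("A", 1): 0.5}, q_min=0.6)

    def test_narrower_shell_is_nested(self):
        model = single_atom_model()
        grid = DensityMap(np.zeros((60, 60, 60)), 0.4, (0, 0, 0))
        rq = {("A", 1): 0.9}
        wide = solvent_shell_mask(grid, model, rq, r_min=1.8, r_max=3.5)
        narrow = solvent_shell_mask(grid, model, rq, r_min=2.0, r_max=3.0)
        assert not (narrow.mask & ~wide.mask).any()


class TestShellGrid:
    def test_kept_points_respect_distance_window(self):
        model = single_atom_model()
        pts = sample_shell_grid(model, {("A", 1): 0.9}, spacing=0.8)
        d = np.linalg.norm(pts - model.coords[0], axis=1)
        assert d.min() >= 1.5 and d.max() <= 3.5

    def test_halving_spacing_octuples_count(self, fixture):
        model = fixture["model"]
        rq = {rid: 0.9 for rid in model.residue_ids}
        coarse = sample_shell_grid(model, rq, spacing=1.67)
        fine = sample_shell_grid(model, rq, spacing=1.67 / 2)
        assert len(fine) == pytest.approx(8 * len(coarse), rel=0.2)

    def test_matches_brute_force_filter(self):
        model = single_atom_model()
        pts = sample_shell_grid(model, {("A", 1): 0.9}, spacing=1.0)
        lo = model.coords.min(axis=0) - 3.5
        hi = model.coords.max(axis=0) + 3.5
        axes = [np.arange(lo[i], hi[i] + 1.0, 1.0) for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"),
                        axis=-1).reshape(-1, 3)
        d = np.linalg.norm(grid - model.coords[0], axis=1)
        assert len(pts) == int(((d >= 1.5) & (d <= 3.5)).sum())


class TestCriteriaPassRate:
    def test_planted_positions_all_pass(self, fixture, swim_placements):
        pts = np.array([p.position for p in swim_placements])
        full_rate, half_rate = criteria_pass_rate(
            pts, fixture["full"], fixture["half1"], fixture["half2"],
            fixture["model"])
        assert full_rate == 1.0 and half_rate == 1.0

    def test_empty_solvent_fails_everywhere(self, fixture):
        # positions far from any atom in a noise-free render
        from rnaswim.synthetic import render_synthetic_maps
        full, h1, h2 = render_synthetic_maps(fixture["solvated"], 2.2,
                                             noise_sd=0.0, seed=0)
        corner = full.origin + 3.0
        pts = corner + np.arange(5)[:, None] * np.array([1.0, 0.5, 0.25])
        full_rate, half_rate = criteria_pass_rate(
            pts, full, h1, h2, fixture["model"])
        assert full_rate == 0.0 and half_rate == 0.0

    def test_empty_point_list_rejected(self, fixture):
        with pytest.raises(ValueError):
            criteria_pass_rate(np.zeros((0, 3)), fixture["full"],
                               fixture["half1"], fixture["half2"],
                               fixture["model"])


class TestRenderModelMap:
    def test_total_mass_equals_weight(self):
        water = StructureModel([
            Atom("O", "O", "HOH", "W", 1, np.array([8.0, 8.0, 8.0]))])
        m = render_model_map(water, resolution=2.2, voxel_size=0.4)
        mass = m.values.sum() * 0.4 ** 3
        assert mass == pytest.approx(1.0, rel=0.01)

    def test_magnesium_weighs_1_5x_water(self):
        pos = np.array([8.0, 8.0, 8.0])
        w = render_model_map(StructureModel(
            [Atom("O", "O", "HOH", "W", 1, pos)]), 2.2, voxel_size=0.4)
        mg = render_model_map(StructureModel(
            [Atom("MG", "Mg", "MG", "I", 1, pos)]), 2.2, voxel_size=0.4)
        assert mg.values.max() / w.values.max() == pytest.approx(1.5,
                                                                 abs=1e-6)

    def test_superposed_atoms_add_linearly(self):
        pos = np.array([8.0, 8.0, 8.0])
        one = render_model_map(StructureModel(
            [Atom("O", "O", "HOH", "W", 1, pos)]), 2.2, voxel_size=0.4)
        two = render_model_map(StructureModel(
            [Atom("O", "O", "HOH", "W", 1, pos),
             Atom("O", "O", "HOH", "W", 2, pos)]), 2.2, voxel_size=0.4)
        np.testing.assert_allclose(two.values, 2 * one.values, atol=1e-12)

    def test_sodium_weight(self):
        pos = np.array([8.0, 8.0, 8.0])
        w = render_model_map(StructureModel(
            [Atom("O", "O", "HOH", "W", 1, pos)]), 2.2, voxel_size=0.4)
        na = render_model_map(StructureModel(
            [Atom("NA", "Na", "NA", "I", 1, pos)]), 2.2, voxel_size=0.4)
        assert na.values.max() / w.values.max() == pytest.approx(1.3,
                                                                 abs=1e-6)


@pytest.fixture(scope="module")
def crafted():
    """Small crafted reference/comparison pair with a known shell mask."""
    rng = np.random.default_rng(30)
    ref = DensityMap(rng.normal(0, 1, (24, 24, 24)), 0.5, (0, 0, 0))
    mask = np.zeros(ref.shape, dtype=bool)
    mask[4:20, 4:20, 4:20] = True
    return ref, ShellMask(mask, 1.8, 3.5)


class TestCompareDensities:
    def test_self_correlation_is_one(self, crafted):
        ref, shell = crafted
        sim = compare_densities(ref, ref, shell)
        assert sim.ccc == pytest.approx(1.0, abs=1e-12)

    def test_shuffled_self_decorrelates(self, crafted):
        ref, shell = crafted
        shuf = shuffle_within_mask(ref, shell.mask, seed=31)
        sim = compare_densities(ref, shuf, shell)
        assert abs(sim.ccc) < 3 / np.sqrt(shell.n_voxels)

    def test_mi_matches_small_sample_bias_floor(self):
        # independent noise: plug-in MI ~ (B-1)^2 / (2 N ln 2)
        rng = np.random.default_rng(32)
        shape = (40, 40, 40)
        a = DensityMap(rng.uniform(0, 1, shape), 0.5, (0, 0, 0))
        b = DensityMap(rng.uniform(0, 1, shape), 0.5, (0, 0, 0))
        mask = np.ones(shape, dtype=bool)
        shell = ShellMask(mask, 1.8, 3.5)
        mi = compare_densities(a, b, shell).mi
        n = mask.sum()
        bias = (20 - 1) ** 2 / (2 * n * np.log(2))
        assert mi == pytest.approx(bias, rel=0.5)

    def test_affine_rescaling_invariance(self, crafted):
        ref, shell = crafted
        comp = ref.copy(values=ref.values * 0.5 + 3.0)
        a = compare_densities(ref, comp, shell)
        assert a.ccc == pytest.approx(1.0, abs=1e-9)


class TestClassificationCurves:
    def test_matches_hand_counted_confusion_matrices(self):
        # 4x4x4 crafted values, confusion matrices counted explicitly
        rng = np.random.default_rng(33)
        ref = DensityMap(rng.normal(0, 1, (4, 4, 4)), 1.0, (0, 0, 0))
        comp = DensityMap(rng.normal(0, 1, (4, 4, 4)), 1.0, (0, 0, 0))
        mask = np.ones((4, 4, 4), dtype=bool)
        shell = ShellMask(mask, 1.8, 3.5)
        curves = classification_curves(ref, comp, shell, pos_k=0.5,
                                       n_thresholds=16)
        stats = map_stats(ref)
        truth = ref.values[mask] > stats.threshold(0.5)
        comp_z = zscore_normalize(comp).values[mask]
        for i, thr in enumerate(curves.thresholds):
            pred = comp_z > thr
            tp = int((pred & truth).sum())
            fp = int((pred & ~truth).sum())
            fn = int((~pred & truth).sum())
            tn = int((~pred & ~truth).sum())
            expect_prec = tp / (tp + fp) if tp + fp else 1.0
            assert curves.precision[i] == pytest.approx(expect_prec)
            assert curves.recall[i] == pytest.approx(tp / (tp + fn))
            assert curves.fpr[i] == pytest.approx(fp / (fp + tn))

    def test_perfect_comparison(self, crafted):
        ref, shell = crafted
        curves = classification_curves(ref, ref, shell)
        assert curves.auroc > 0.999
        assert curves.auprc > 0.99
        assert curves.max_mcc > 0.99
        # at the positive-defining threshold: recall and precision are 1
        stats = map_stats(ref)
        z_thr = (stats.threshold(3.0) - stats.avgD) / stats.sigma
        i = np.argmin(np.abs(curves.thresholds - z_thr))
        assert curves.recall[i] >= 0.99 or curves.recall[i + 1] >= 0.99

    def test_shuffled_comparison_auprc_near_prevalence(self, crafted):
        ref, shell = crafted
        shuf = shuffle_within_mask(ref, shell.mask, seed=34)
        curves = classification_curves(ref, shuf, shell)
        stats = map_stats(ref)
        prevalence = float(
            (ref.values[shell.mask] > stats.threshold(3.0)).mean())
        assert curves.auprc == pytest.approx(prevalence,
                                             abs=3 * prevalence)
        assert 0.4 < curves.auroc < 0.6

    def test_recall_non_increasing_with_threshold(self, crafted):
        ref, shell = crafted
        rng = np.random.default_rng(35)
        comp = ref.copy(values=ref.values + rng.normal(0, 0.5, ref.shape))
        curves = classification_curves(ref, comp, shell)
        assert np.all(np.diff(curves.recall) <= 1e-12)
        assert 0 <= curves.auprc <= 1 and 0 <= curves.auroc <= 1
        assert -1 <= curves.max_mcc <= 1

    def test_all_one_class_rejected(self):
        ref = DensityMap(np.zeros((4, 4, 4)), 1.0, (0, 0, 0))
        ref.values[0, 0, 0] = 1.0
        mask = np.ones((4, 4, 4), dtype=bool)
        comp = DensityMap(np.random.default_rng(0).normal(0, 1, (4, 4, 4)),
                          1.0, (0, 0, 0))
        with pytest.raises(ValueError):
            classification_curves(ref, comp, ShellMask(mask, 1.8, 3.5),
                                  pos_k=100.0)


class TestNormalizedAuprc:
    @pytest.mark.parametrize("comp,exp,rand,expected", [
        (0.8, 0.8, 0.1, 1.0),    # comparison equals the experimental ceiling
        (0.1, 0.8, 0.1, 0.0),    # comparison no better than shuffled
        (0.45, 0.8, 0.1, 0.5),
        (0.9, 0.15, 0.05, 0.0),  # exp below the 0.2 uncertainty floor
        (0.5, 0.3, 0.4, 0.0),    # degenerate ceiling
        (1.0, 0.6, 0.1, 1.0),    # clipped at 1
    ])
    def test_min_max_normalization(self, comp, exp, rand, expected):
        assert normalized_nucleotide_auprc(comp, exp, rand) == \
            pytest.approx(expected)
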