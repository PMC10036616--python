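"""Element profiling: top patches, heatmaps, colocalization, morphology,
compositions, differential abundance, covariate associations, overlays."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tmenet as tm
from tmenet.graphs import build_patch_graph
from tmenet.interpret import (area_composition, benjamini_hochberg,
                              colocalization_matrix, covariate_association,
                              differential_abundance,
                              marker_intensity_heatmap, morphology_features,
                              neighborhood_composition,
                              render_assignment_overlay, segment_nuclei,
                              top_confidence_patches)

from conftest import grid_patchset


class TestTopConfidencePatches:
    def test_one_hot_returns_k_full_confidence(self):
        S = np.zeros((150, 3))
        S[:, 1] = 1.0
        idx, conf = top_confidence_patches(S, 1, k=100)
        assert len(idx) == 100
        assert np.all(conf == 1.0)

    def test_k1_is_argmax(self):
        rng = np.random.default_rng(0)
        S = rng.dirichlet(np.ones(4), size=30)
        idx, _ = top_confidence_patches(S, 2, k=1)
        assert idx[0] == np.argmax(S[:, 2])

    def test_confidences_non_increasing(self):
        rng = np.random.default_rng(1)
        S = rng.dirichlet(np.ones(4), size=50)
        _, conf = top_confidence_patches(S, 0, k=50)
        assert np.all(np.diff(conf) <= 0)

    def test_ties_break_by_patch_index(self):
        S = np.tile([[0.5, 0.5]], (6, 1))
        idx, _ = top_confidence_patches(S, 0, k=3)
        assert list(idx) == [0, 1, 2]

    def test_fewer_than_k_warns_and_returns_all(self):
        S = np.ones((5, 2)) / 2
        with pytest.warns(UserWarning, match="only 5"):
            idx, _ = top_confidence_patches(S, 0, k=100)
        assert len(idx) == 5

    def test_element_out_of_range(self):
        with pytest.raises(IndexError):
            top_confidence_patches(np.ones((5, 2)) / 2, 7, k=1)


class TestMarkerHeatmap:
    def test_column_maxima_equal_one(self):
        rng = np.random.default_rng(2)
        tensors = [[rng.gamma(2, 5, size=(20, 20, 7)) for _ in range(4)]
                   for _ in range(3)]
        M = marker_intensity_heatmap(tensors)
        assert np.allclose(M.max(axis=0), 1.0)

    def test_zero_channel_yields_zero_entry(self):
        rng = np.random.default_rng(3)
        a = [rng.gamma(2, 5, size=(20, 20, 7)) for _ in range(3)]
        b = [rng.gamma(2, 5, size=(20, 20, 7)) for _ in range(3)]
        for t in a:
            t[:, :, 2] = 0.0
        M = marker_intensity_heatmap([a, b])
        assert M[0, 2] == 0.0 and M[1, 2] == 1.0

    def test_empty_element_warns_with_zero_row(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="no top patches"):
            M = marker_intensity_heatmap(
                [[rng.gamma(2, 5, size=(20, 20, 7))], []])
        assert np.allclose(M[1], 0.0)

    def test_planted_cd8_phenotype_attains_cd8_maximum(self, small_cohort):
        """Ground-truth one-hot assignments recover the planted profile."""
        _, cores, table, gt = small_cohort
        cd8 = tm.DEFAULT_PANEL.index("CD8")
        by_phen = {e: [] for e in range(3)}
        for core in cores:
            patches = tm.extract_patches(core)
            labels = gt.patch_phenotype[core.core_id]
            for p in patches:
                by_phen[labels[p.row, p.col]].append(p.tensor)
        M = marker_intensity_heatmap([by_phen[e] for e in range(3)])
        # planted phenotype 1 is the CD8 T cell
        assert M[1, cd8] == 1.0


class TestColocalization:
    def test_identical_channels_correlate_perfectly(self):
        rng = np.random.default_rng(5)
        t = rng.gamma(2, 5, size=(20, 20, 7))
        t[:, :, 1] = t[:, :, 0]
        M = colocalization_matrix([t])
        assert M[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(M) == 1.0)

    def test_reversed_ranks_give_minus_one(self):
        t = np.zeros((20, 20, 7))
        vals = np.arange(400, dtype=float).reshape(20, 20)
        t[:, :, 0] = vals
        t[:, :, 1] = -vals
        assert colocalization_matrix([t])[0, 1] == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(6)
        patches = [rng.normal(size=(20, 20, 7)) for _ in range(100)]
        M = colocalization_matrix(patches)
        off = M[~np.eye(7, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_constant_channel_contributes_zero(self):
        t = np.random.default_rng(7).gamma(2, 5, size=(20, 20, 7))
        t[:, :, 3] = 4.2
        M = colocalization_matrix([t])
        assert np.all(M[3, :3] == 0.0)

    def test_no_patches_rejected(self):
        with pytest.raises(ValueError):
            colocalization_matrix([])


def _disk(center, radius, shape=(40, 40), height=50.0):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    img = np.zeros(shape)
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2] = height
    return img


class TestSegmentation:
    def test_single_disk_single_label(self):
        mask = segment_nuclei(_disk((20, 20), 5))
        assert mask.max() == 1

    def test_two_separated_disks_two_labels(self):
        img = _disk((20, 12), 5) + _disk((20, 27), 5)
        mask = segment_nuclei(img)
        assert mask.max() == 2

    def test_blank_image_zero_labels(self):
        assert segment_nuclei(np.zeros((20, 20))).max() == 0

    def test_deterministic(self):
        img = _disk((20, 12), 5) + _disk((20, 27), 5)
        assert np.array_equal(segment_nuclei(img), segment_nuclei(img))


class TestMorphology:
    def test_square_circularity_near_pi_over_four(self):
        mask = np.zeros((30, 30), dtype=int)
        mask[5:25, 5:25] = 1
        area, n, circ = morphology_features(mask)
        assert n == 1 and area == 400
        assert circ == pytest.approx(np.pi / 4, abs=0.12)

    def test_digital_disk_is_nearly_circular(self):
        mask = (_disk((20, 20), 8) > 0).astype(int)
        _, _, circ = morphology_features(mask)
        assert circ >= 0.85

    def test_three_labels_density_three(self):
        mask = np.zeros((40, 40), dtype=int)
        mask[2:6, 2:6] = 1
        mask[12:16, 12:16] = 2
        mask[30:35, 30:35] = 3
        _, n, _ = morphology_features(mask)
        assert n == 3

    def test_empty_mask_zeros(self):
        assert morphology_features(np.zeros((10, 10), dtype=int)) == (0.0, 0, 0.0)


class TestCompositions:
    def test_counts_bounded_by_closed_neighborhood(self):
        ps = grid_patchset(7, 7, d=4, seed=8)
        g = build_patch_graph(ps)
        rng = np.random.default_rng(9)
        S_P = rng.dirichlet(np.ones(3), size=49)
        S_N = rng.dirichlet(np.ones(2), size=49)
        counts = neighborhood_composition(S_P, S_N, g, k=1, scheme="counts")
        assert counts.sum(axis=1).max() <= 13

    def test_pure_block_concentrates_mass(self):
        """A neighborhood sitting on one phenotype block counts only it."""
        ps = grid_patchset(6, 6, d=4, seed=10)
        g = build_patch_graph(ps)
        phen = np.zeros(36, dtype=int)
        phen[18:] = 1  # bottom half is phenotype 1
        S_P = np.eye(2)[phen]
        neigh = np.zeros(36, dtype=int)
        neigh[18:] = 1
        S_N = np.eye(2)[neigh]
        counts = neighborhood_composition(S_P, S_N, g, k=9, scheme="counts")
        # neighborhood 0 top patches lie in the top half: phenotype 0 dominates
        assert counts[0, 0] > counts[0, 1]
        assert counts[1, 1] > counts[1, 0]

    def test_uniform_assignments_give_roughly_equal_rows(self):
        rng = np.random.default_rng(11)
        ps = grid_patchset(10, 10, d=4, seed=12)
        g = build_patch_graph(ps)
        S_P = rng.dirichlet(np.ones(4) * 50, size=100)  # near-uniform
        S_P = S_P[np.argsort(rng.random(100))]
        S_N = rng.dirichlet(np.ones(2), size=100)
        counts = neighborhood_composition(S_P, S_N, g, k=100, scheme="counts")
        frac = counts / counts.sum(axis=1, keepdims=True)
        assert np.all(np.abs(frac - 0.25) < 0.1)

    def test_zscored_rows_have_zero_mean(self):
        rng = np.random.default_rng(13)
        S_N = rng.dirichlet(np.ones(3), size=60)
        S_A = rng.dirichlet(np.ones(2), size=3)
        Z = area_composition(S_N, S_A, scheme="zscore")
        assert np.allclose(Z.mean(axis=1), 0.0, atol=1e-9)

    def test_one_hot_area_counts_are_partition_sizes(self):
        labels = np.array([0, 0, 0, 1, 1, 2])
        S_N = np.eye(3)[np.array([0, 0, 1, 1, 2, 2])]
        S_A = np.eye(2)[np.array([0, 0, 1])]
        counts = area_composition(S_N, S_A, scheme="counts")
        assert counts[0, 0] == 2 and counts[0, 1] == 2 and counts[1, 2] == 2


def exact_mww_pvalue(a, b):
    """Two-sided exact permutation p-value for the Mann-Whitney U."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = stats.rankdata(pooled)
    observed = ranks[:n].sum()
    total = 0
    as_extreme = 0
    mean_stat = ranks.sum() * n / len(pooled)
    for combo in itertools.combinations(range(len(pooled)), n):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean_stat) >= abs(observed - mean_stat) - 1e-12:
            as_extreme += 1
    return as_extreme / total


class TestDifferentialAbundance:
    def test_identical_groups_p_one(self):
        enr = pd.DataFrame({"A1": np.concatenate([np.arange(5.0),
                                                  np.arange(5.0)])})
        labels = np.array([0] * 5 + [1] * 5)
        out = differential_abundance(enr, labels)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_is_m_times_p_capped(self):
        rng = np.random.default_rng(14)
        enr = pd.DataFrame(rng.normal(size=(16, 22)),
                           columns=[f"e{i}" for i in range(22)])
        labels = np.array([0, 1] * 8)
        out = differential_abundance(enr, labels)
        expect = np.minimum(1.0, 22 * out["p"])
        assert np.allclose(out["p_adj"], expect)

    def test_matches_exact_permutation_null_at_small_n(self):
        """Oracle: full enumeration of rank-sum permutations, n = 4+4."""
        rng = np.random.default_rng(15)
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(size=4) + rng.normal() * 0.5
            enr = pd.DataFrame({"x": np.concatenate([a, b])})
            labels = np.array([1] * 4 + [0] * 4)
            p_ours = differential_abundance(enr, labels)["p"].iloc[0]
            p_exact = exact_mww_pvalue(a, b)
            assert p_ours == pytest.approx(p_exact, abs=1e-3)

    def test_planted_area_difference_is_detected(self):
        """Cold-area fractions of hot vs cold patients differ (n=20/20)."""
        cfg = tm.two_class_config(n_patients=40, core_size=512, seed=21)
        _, table, gt = tm.generate_cohort(cfg, render_images=False)
        rows = {}
        for pid in table.patient_ids:
            fracs = [np.mean(gt.patch_area[cid] == 0)
                     for cid in table.cores_of(pid)]
            rows[pid] = {"cold_area": np.mean(fracs)}
        enr = pd.DataFrame.from_dict(rows, orient="index")
        out = differential_abundance(enr, table.labels)
        assert out["p_adj"].iloc[0] < 0.05
        assert out["direction"].iloc[0] > 0  # recurrence is cold-enriched

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            differential_abundance(pd.DataFrame({"x": [1.0, 2.0]}),
                                   np.array([1, 1]))

    def test_false_positive_rate_controlled_under_permutation(self):
        rng = np.random.default_rng(16)
        enr = pd.DataFrame(rng.normal(size=(30, 22)),
                           columns=[f"e{i}" for i in range(22)])
        hits = 0
        trials = 30
        for t in range(trials):
            labels = rng.permutation([0] * 15 + [1] * 15)
            out = differential_abundance(enr, labels)
            hits += int((out["p_adj"] < 0.05).any())
        assert hits / trials <= 0.05 + 0.07  # small-sample slack


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(17)
        p = rng.uniform(size=40)
        ours = benjamini_hochberg(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)


class TestCovariateAssociation:
    def test_identical_covariate_has_rho_one(self):
        enr = pd.DataFrame({"A1": np.arange(10.0)},
                           index=[f"p{i}" for i in range(10)])
        cov = pd.DataFrame({"figo_stage": np.arange(10.0)},
                           index=enr.index)
        out = covariate_association(enr, cov, {"figo_stage": "ordinal"})
        assert out["statistic"].iloc[0] == pytest.approx(1.0)

    def test_null_fdr_is_controlled(self):
        rng = np.random.default_rng(18)
        n = 40
        enr = pd.DataFrame(rng.normal(size=(n, 22)),
                           columns=[f"e{i}" for i in range(22)],
                           index=[f"p{i}" for i in range(n)])
        cov = pd.DataFrame(
            {f"c{j}": rng.permutation(n).astype(float) for j in range(5)},
            index=enr.index)
        out = covariate_association(enr, cov,
                                    {f"c{j}": "ordinal" for j in range(5)})
        assert (out["q"] < 0.05).mean() < 0.05

    def test_planted_figo_cold_area_dependence_detected(self):
        """FIGO stage is simulated to track cold-area fraction."""
        cfg = tm.two_class_config(n_patients=80, core_size=512, seed=22)
        _, table, gt = tm.generate_cohort(cfg, render_images=False)
        rows = {}
        for pid in table.patient_ids:
            fracs = [np.mean(gt.patch_area[cid] == 0)
                     for cid in table.cores_of(pid)]
            rows[pid] = {"cold_area": np.mean(fracs)}
        enr = pd.DataFrame.from_dict(rows, orient="index")
        cov = table.covariates()[["figo_stage", "age"]]
        out = covariate_association(enr, cov, {"figo_stage": "ordinal",
                                               "age": "ordinal"})
        row = out[(out["element"] == "cold_area")
                  & (out["covariate"] == "figo_stage")].iloc[0]
        assert row["q"] < 0.05 and row["statistic"] > 0

    def test_binary_covariate_uses_t_test(self):
        rng = np.random.default_rng(19)
        enr = pd.DataFrame({"A1": np.concatenate([rng.normal(0, 1, 15),
                                                  rng.normal(3, 1, 15)])},
                           index=[f"p{i}" for i in range(30)])
        cov = pd.DataFrame({"lvi": [0.0] * 15 + [1.0] * 15},
                           index=enr.index)
        out = covariate_association(enr, cov, {"lvi": "binary"})
        assert out["p"].iloc[0] < 1e-4

    def test_constant_covariate_gives_na_with_warning(self):
        enr = pd.DataFrame({"A1": [1.0, 2.0, 3.0]},
                           index=["a", "b", "c"])
        cov = pd.DataFrame({"grade": [1.0, 1.0, 1.0]}, index=enr.index)
        with pytest.warns(UserWarning, match="constant"):
            out = covariate_association(enr, cov, {"grade": "binary"})
        assert np.isnan(out["p"].iloc[0])


class TestElementProfiles:
    def test_profiles_from_ground_truth_assignments(self, small_cohort):
        """One-hot planted assignments produce coherent phenotype profiles."""
        from tmenet.interpret import profile_phenotypes
        _, cores, table, gt = small_cohort
        by_core = {c.core_id: c for c in cores}
        bundles, patch_tensors = {}, {}
        rows = {}
        for pid in table.patient_ids:
            phen, tensors = [], []
            for cid in table.cores_of(pid):
                patches = tm.extract_patches(by_core[cid])
                labels_map = gt.patch_phenotype[cid]
                tensors.extend(p.tensor for p in patches)
                phen.extend(labels_map[p.row, p.col] for p in patches)
            S_P = np.eye(3)[np.array(phen)]

            class FakeBundle:
                pass

            b = FakeBundle()
            b.S_P = S_P
            bundles[pid] = b
            patch_tensors[pid] = tensors
            frac = np.bincount(phen, minlength=3) / len(phen)
            rows[pid] = {f"P{e + 1}": frac[e] for e in range(3)}
        enr = pd.DataFrame.from_dict(rows, orient="index")
        labels = np.array(table.labels)
        profiles = profile_phenotypes(bundles, patch_tensors, enr, labels,
                                      dapi_index=0, k=50)
        assert len(profiles) == 3
        cd8 = tm.DEFAULT_PANEL.index("CD8")
        ck = tm.DEFAULT_PANEL.index("CK")
        heat = np.stack([p.mean_intensity for p in profiles])
        assert np.argmax(heat[:, cd8]) == 1  # CD8 T-cell phenotype
        assert np.argmax(heat[:, ck]) == 0   # tumor phenotype
        for p in profiles:
            assert np.all(np.diff(p.confidences) <= 0)
            assert p.morphology[1] > 0  # nuclei found in top patches


class TestOverlay:
    def test_uniform_confidence_gives_uniform_top_color(self):
        pixels = np.random.default_rng(20).gamma(2, 5, size=(64, 64, 7))
        img = render_assignment_overlay(pixels, np.ones(9), (3, 3))
        assert img.shape == (60, 60, 3)
        # every patch block shows the same colormap position
        flat = img.reshape(-1, 3)
        base = pixels[:60, :60].mean(axis=2)
        # remove the grayscale component: difference between two pixels with
        # equal gray must be zero
        gray = (base / base.max()).ravel()
        same = np.isclose(gray, gray[0])
        assert np.allclose(flat[same], flat[same][0])

    def test_output_cropped_to_patch_tiling(self):
        pixels = np.zeros((130, 70, 7))
        img = render_assignment_overlay(pixels, np.ones(18), (6, 3))
        assert img.shape == (120, 60, 3)

    def test_monotone_confidence_monotone_color(self):
        import matplotlib.pyplot as plt
        cmap = plt.get_cmap("cividis")
        pixels = np.zeros((40, 40, 7))
        img = render_assignment_overlay(pixels, [0.0, 0.5, 1.0, 0.2], (2, 2),
                                        alpha=1.0)
        expected = cmap([0.0, 0.5, 1.0, 0.2])[:, :3]
        got = np.stack([img[0, 0], img[0, 20], img[20, 0], img[20, 20]])
        assert np.allclose(got, expected, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            render_assignment_overlay(np.zeros((40, 40, 7)), np.ones(5),
                                      (2, 2))
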