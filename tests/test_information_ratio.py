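"""Per-gene two-group p-values and the information-ratio statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import residualscope as rs
from residualscope.information_ratio import P_FLOOR, _two_sample_pvalues

from conftest import make_matrix, random_matrix


def annotate(groups: dict[str, list[str]]) -> rs.SampleAnnotation:
    rows = [(s, g, "other") for g, members in groups.items() for s in members]
    return rs.SampleAnnotation(
        pd.DataFrame(rows, columns=["sample_id", "group", "large_scale_group"])
    )


class TestGroupPvalues:
    def test_matches_scipy_welch_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(30, 6)), rng.normal(0.5, 1.3, size=(30, 9))
        ours = _two_sample_pvalues(a, b, "welch")
        ref = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_matches_scipy_pooled_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(20, 5)), rng.normal(size=(20, 7))
        ours = _two_sample_pvalues(a, b, "pooled")
        ref = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
        np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_identical_value_sets_give_p_one(self):
        x = make_matrix(np.tile([[1.0, 2.0, 1.0, 2.0]], (5, 1)))
        p = rs.group_pvalues(x, ["s0", "s1"], ["s2", "s3"])
        np.testing.assert_array_equal(p, 1.0)

    def test_near_step_gene_matches_closed_form_welch(self):
        # values a=(0,0)+jitter, b=(1,1)+jitter with a known tiny jitter
        a = np.array([[0.0, 1e-3]])
        b = np.array([[1.0, 1.0 + 1e-3]])
        p = _two_sample_pvalues(a, b, "welch")[0]
        va = vb = np.var([0.0, 1e-3], ddof=1)
        se2 = va / 2 + vb / 2
        t = 1.0 / np.sqrt(se2)
        df = se2**2 / ((va / 2) ** 2 + (vb / 2) ** 2)
        expected = 2 * stats.t.sf(t, df)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_constant_unequal_groups_hit_floor(self):
        x = make_matrix([[0.0, 0.0, 1.0, 1.0]])
        p = rs.group_pvalues(x, ["s0", "s1"], ["s2", "s3"])
        assert p[0] == P_FLOOR

    def test_group_of_one_is_an_error(self):
        x = random_matrix(4, 5)
        with pytest.raises(ValueError, match="at least 2"):
            rs.group_pvalues(x, ["s0"], ["s1", "s2"])

    def test_overlapping_groups_are_an_error(self):
        x = random_matrix(4, 5)
        with pytest.raises(ValueError, match="disjoint"):
            rs.group_pvalues(x, ["s0", "s1"], ["s1", "s2"])


class TestInformationRatio:
    def test_direct_arithmetic(self):
        # -log10 p: projected (1,2,3), residual (2,4,6) -> IR = 12/18
        p_proj = 10.0 ** -np.array([1.0, 2.0, 3.0])
        p_res = 10.0 ** -np.array([2.0, 4.0, 6.0])
        assert rs.information_ratio(p_proj, p_res) == pytest.approx(12 / 18)

    def test_symmetry_and_extremes(self):
        p = np.array([0.5, 1e-4, 0.9])
        assert rs.information_ratio(p, p) == pytest.approx(0.5)
        assert rs.information_ratio(np.ones(3), p) == pytest.approx(1.0)
        assert rs.information_ratio(p, np.ones(3)) == pytest.approx(0.0)
        assert rs.information_ratio(np.ones(3), np.ones(3)) == pytest.approx(0.5)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="equal length"):
            rs.information_ratio(np.ones(3), np.ones(4))


def planted_compendium(signal_in_pc1: bool, seed=0, contrast_mix=None):
    """Two groups whose mean difference lies along PC1 or orthogonal to PCs 1-3.

    Three strong background directions pin down PCs 1-3 over a small noise
    floor. The A-vs-B contrast is planted either along the strongest
    background direction (so the leading components capture it) or on a
    sparse gene set with per-gene shifts far above the noise but with total
    energy far below the background spikes (so only the residual sees it).
    ``contrast_mix=(w_pc1, w_sparse)`` blends the two with those amplitudes.
    """
    rng = np.random.default_rng(seed)
    g, n = 200, 80
    dirs = np.linalg.qr(rng.normal(size=(g, 4)))[0]
    x = rng.normal(scale=0.01, size=(g, n))
    # background structure: random sample weights on three strong directions
    for j, scale in enumerate((1.2, 0.8, 0.7)):
        x += np.outer(dirs[:, j], rng.normal(scale=scale, size=n))
    support = rng.choice(g, 60, replace=False)
    sparse = np.zeros(g)
    sparse[support] = rng.choice([-1.0, 1.0], 60)
    if contrast_mix is None:
        contrast_mix = (3.0, 0.0) if signal_in_pc1 else (0.0, 0.08)
    contrast = contrast_mix[0] * dirs[:, 0] + contrast_mix[1] * sparse
    x[:, 0:20] += contrast[:, None]
    members_a = [f"s{i}" for i in range(0, 20)]
    members_b = [f"s{i}" for i in range(20, 40)]
    return make_matrix(x), annotate({"A": members_a, "B": members_b})


class TestIRForGroups:
    def test_signal_along_pc1_gives_low_ir(self):
        x, ann = planted_compendium(signal_in_pc1=True)
        model = rs.fit_pca(x, 3)
        res = rs.ir_for_groups(x, model, 3, ann, "A", "B")
        assert res.ir < 0.1

    def test_signal_orthogonal_to_top3_gives_high_ir(self):
        x, ann = planted_compendium(signal_in_pc1=False)
        model = rs.fit_pca(x, 3)
        res = rs.ir_for_groups(x, model, 3, ann, "A", "B")
        assert res.ir > 0.9

    def test_k_zero_gives_ir_one_when_signal_exists(self):
        x, ann = planted_compendium(signal_in_pc1=True)
        model = rs.fit_pca(x, 3)
        assert rs.ir_for_groups(x, model, 0, ann, "A", "B").ir == pytest.approx(1.0)

    def test_unknown_label_is_an_error(self):
        x, ann = planted_compendium(signal_in_pc1=True)
        model = rs.fit_pca(x, 3)
        with pytest.raises(KeyError, match="unknown"):
            rs.ir_for_groups(x, model, 3, ann, "A", "no_such_group")

    def test_result_vectors_are_consistent(self):
        x, ann = planted_compendium(signal_in_pc1=False)
        model = rs.fit_pca(x, 3)
        res = rs.ir_for_groups(x, model, 3, ann, "A", "B")
        assert len(res.p_original) == x.n_genes
        assert res.n_a == res.n_b == 20
        for vec in (res.p_original, res.p_projected, res.p_residual):
            assert np.all((vec > 0) & (vec <= 1))
        assert res.ir == pytest.approx(
            rs.information_ratio(res.p_projected, res.p_residual)
        )


class TestIRDimensionScan:
    def test_full_rank_kills_the_residual(self):
        x, ann = planted_compendium(signal_in_pc1=False)
        k_full = x.n_samples - 1
        model = rs.fit_pca(x, k_full)
        scan = dict(rs.ir_dimension_scan(x, model, ann, "A", "B", [0, k_full]))
        assert scan[0] == pytest.approx(1.0)
        assert scan[k_full] == pytest.approx(0.0, abs=1e-6)

    def test_single_direction_signal_collapses_the_scan_at_k_one(self):
        """A contrast concentrated on PC1 drives IR from 1 to ~0 as soon as
        that component enters the projected space, and it never recovers.

        (A rank-1 projected space slightly overstates every gene's evidence,
        so tiny upward wiggles after the drop are numerical, not signal.)
        """
        x, ann = planted_compendium(signal_in_pc1=True)
        model = rs.fit_pca(x, 6)
        irs = [ir for _, ir in rs.ir_dimension_scan(x, model, ann, "A", "B", range(7))]
        assert irs[0] == pytest.approx(1.0)
        assert all(ir < 0.1 for ir in irs[1:])
        assert all(a >= b - 0.05 for a, b in zip(irs[1:], irs[2:]))

    def test_subspace_energy_split_is_monotone_in_alpha(self):
        # blend a fixed-energy contrast between PC1 and the sparse residual
        # direction; the IR must increase with the residual share alpha
        irs = []
        for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
            mix = (3.0 * np.sqrt(1 - alpha), 0.08 * np.sqrt(alpha))
            x, ann = planted_compendium(False, contrast_mix=mix)
            model = rs.fit_pca(x, 3)
            irs.append(rs.ir_for_groups(x, model, 3, ann, "A", "B").ir)
        assert all(a < b for a, b in zip(irs, irs[1:]))

    def test_permuted_labels_give_uniformish_pvalues(self):
        rng = np.random.default_rng(9)
        x = make_matrix(rng.normal(size=(500, 40)))
        ann = annotate(
            {"A": [f"s{i}" for i in range(20)], "B": [f"s{i}" for i in range(20, 40)]}
        )
        model = rs.fit_pca(x, 3)
        res = rs.ir_for_groups(x, model, 3, ann, "A", "B")
        # no planted signal: original-space p-values look uniform
        ks = stats.kstest(res.p_original, "uniform").pvalue
        assert ks > 0.01
        assert 0.3 < res.ir < 0.7


class TestPairwiseIRMatrix:
    def test_symmetric_with_nan_diagonal(self):
        x, ann = planted_compendium(signal_in_pc1=True)
        model = rs.fit_pca(x, 3)
        m = rs.pairwise_ir_matrix(x, model, 3, ann, min_group_size=10)
        assert list(m.index) == ["A", "B"]
        assert np.isnan(m.values.diagonal()).all()
        assert m.loc["A", "B"] == m.loc["B", "A"]
        assert 0.0 <= m.loc["A", "B"] <= 1.0

    def test_projected_space_contrast_gives_low_offdiagonal(self):
        x, ann = planted_compendium(signal_in_pc1=True)
        model = rs.fit_pca(x, 3)
        m = rs.pairwise_ir_matrix(x, model, 3, ann, min_group_size=10)
        assert m.loc["A", "B"] < 0.1

    def test_oversized_filter_is_an_error(self):
        x, ann = planted_compendium(signal_in_pc1=True)
        model = rs.fit_pca(x, 3)
        with pytest.raises(ValueError, match="fewer than 2"):
            rs.pairwise_ir_matrix(x, model, 3, ann, min_group_size=1000)
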