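import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prizenet import differential as d
from prizenet.errors import FormatError, ParameterError
from prizenet.omics_io import ClusterDEMatrix, Layer, OmicsMeasurement


def meas(fid, fc, padj, layer=Layer.PROTEIN, parent=""):
    return OmicsMeasurement(fid, layer, fc, min(padj, 1.0), padj, parent)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p_in, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.05], [0.05]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_step_up_examples(self, p_in, expected):
        assert d.bh_adjust(p_in) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            d.bh_adjust([0.5, 0.0])

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 40)))
            ours = d.bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(ours - ref)) < 1e-12

    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=30
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_input(self, p):
        adj = d.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestNormalizeTotalSignal:
    def test_formula(self):
        table = pd.DataFrame({"c1": [10.0, 90.0], "c2": [50.0, 150.0]})
        out = d.normalize_total_signal(table)
        assert out.loc[0, "c1"] == pytest.approx(15.0)  # 10/100*150
        assert out.sum(axis=0).nunique() == 1

    def test_equal_totals_fixed_point(self):
        table = pd.DataFrame({"c1": [10.0, 90.0], "c2": [40.0, 60.0]})
        pd.testing.assert_frame_equal(d.normalize_total_signal(table), table)

    def test_zero_channel_named(self):
        table = pd.DataFrame({"good": [1.0], "dead": [0.0]})
        with pytest.raises(FormatError, match="dead"):
            d.normalize_total_signal(table)


class TestClusterDETest:
    def test_identical_groups_p_one(self):
        assert d.cluster_de_test([1, 2, 3], [1, 2, 3]) == 1.0
        assert d.cluster_de_test([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_complete_separation_exact(self):
        # 2 of C(6,3)=20 labelings are as extreme
        assert d.cluster_de_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            d.cluster_de_test([1], [2, 3])

    def test_exact_and_approx_agree_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.5, 1, 8)
            exact = d.cluster_de_test(a, b, method="exact")
            approx = d.cluster_de_test(a, b, method="approx")
            assert abs(exact - approx) < 0.02

    def test_exact_matches_scipy_without_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.8, 1, 5)
            ref = mannwhitneyu(a, b, alternative="two-sided",
                               method="exact").pvalue
            assert d.cluster_de_test(a, b) == pytest.approx(ref)


class TestModeratedT:
    def test_homogeneous_noise_recovers_pooled_power(self):
        rng = np.random.default_rng(3)
        mut = rng.normal(1.0, 0.25, size=(200, 4))
        ctrl = rng.normal(0.0, 0.25, size=(200, 4))
        p = d.moderated_t_test_matrix(mut, ctrl)
        # a 4-sigma shift with shared variance should be overwhelmingly small
        assert np.median(p) < 1e-6

    def test_null_uniformity(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, size=(2000, 4))
        b = rng.normal(0, 1, size=(2000, 4))
        p = d.moderated_t_test_matrix(a, b)
        assert 0.4 < np.mean(p) < 0.6
        assert np.mean(p < 0.05) < 0.08

    def test_zero_variance_cases(self):
        p = d.moderated_t_test_matrix(
            np.array([[1.0, 1.0, 1.0]]), np.array([[1.0, 1.0, 1.0]])
        )
        assert p[0] == 1.0
        p = d.moderated_t_test_matrix(
            np.array([[2.0, 2.0, 2.0]]), np.array([[1.0, 1.0, 1.0]])
        )
        assert 0 < p[0] < 1e-100


class TestFilterDE:
    def test_boundary_retained(self):
        m = meas("g", np.log2(1.25), 0.049)
        summary = d.filter_de([m], 1.25, 0.05)
        assert summary.retained_flags == (True,)
        assert summary.directions == ("up",)

    def test_alpha_boundary_is_strict(self):
        m = meas("g", 0.5, 0.05)
        assert d.filter_de([m], 1.25, 0.05).retained_flags == (False,)

    def test_downregulation_retained(self):
        m = meas("g", -1.0, 0.001)
        summary = d.filter_de([m], 1.25, 0.05)
        assert summary.retained_flags == (True,)
        assert summary.n_down == 1

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(11)
        ms = [
            meas(f"g{i}", float(rng.normal(0, 1)), float(rng.uniform(1e-4, 1)))
            for i in range(50)
        ]
        tight = {m.feature_id for m in d.filter_de(ms, 1.5, 0.01).retained}
        loose = {m.feature_id for m in d.filter_de(ms, 1.25, 0.05).retained}
        assert tight <= loose


class TestCollapseSites:
    def site(self, fid, parent, fc, padj):
        return meas(fid, fc, padj, Layer.UBIQUITIN_SITE, parent)

    def test_one_record_per_protein(self):
        sites = [
            self.site("s1", "P1", 1.0, 0.1),
            self.site("s2", "P1", 2.0, 0.2),
            self.site("s3", "P2", 1.0, 0.3),
            self.site("s4", "P3", 1.0, 0.4),
            self.site("s5", "P3", -1.0, 0.05),
        ]
        out = d.collapse_sites(sites)
        assert [m.feature_id for m in out] == ["P1", "P2", "P3"]
        assert all(m.layer is Layer.PROTEIN for m in out)

    def test_min_p_rule(self):
        sites = [
            self.site("s1", "P", 1.5, 0.01),
            self.site("s2", "P", -1.2, 0.2),
        ]
        (rec,) = d.collapse_sites(sites)
        assert (rec.p_adjusted, rec.log2_fold_change) == (0.01, 1.5)

    def test_tie_broken_by_fold_change(self):
        sites = [
            self.site("s1", "P", 1.0, 0.05),
            self.site("s2", "P", 2.0, 0.05),
        ]
        (rec,) = d.collapse_sites(sites)
        assert rec.log2_fold_change == 2.0

    def test_protein_layer_rejected(self):
        with pytest.raises(FormatError):
            d.collapse_sites([meas("p", 1.0, 0.1)])


class TestCountClusters:
    def _matrix(self, fc_rows, padj_rows, genes, clusters):
        return ClusterDEMatrix(
            pd.DataFrame(fc_rows, index=genes, columns=clusters),
            pd.DataFrame(padj_rows, index=genes, columns=clusters),
        )

    def test_counts_and_top_list(self):
        n_clusters = 24
        fc = np.zeros((2, n_clusters))
        padj = np.ones((2, n_clusters))
        fc[0, :11] = 1.0
        padj[0, :11] = 0.01
        m = self._matrix(
            fc, padj, ["hot", "cold"], [f"C{j}" for j in range(n_clusters)]
        )
        counts = d.count_clusters_per_gene(m, 1.25, 0.05)
        assert counts.n_total("hot") == 11
        assert "hot" in counts.top_genes  # > 10 clusters
        assert counts.n_total("cold") == 0
        assert "cold" not in counts.top_genes
        assert counts.mean_clusters == 11.0  # zero-count genes excluded

    def test_mixed_directions(self):
        fc = np.array([[1.0, 1.0, 1.0, -1.0, -1.0, 0.0]])
        padj = np.array([[0.01] * 5 + [0.01]])
        m = self._matrix(fc, padj, ["g"], list("abcdef"))
        counts = d.count_clusters_per_gene(m, 1.25, 0.05)
        row = counts.table.loc["g"]
        assert (row.n_up, row.n_down, row.n_total) == (3, 2, 5)
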