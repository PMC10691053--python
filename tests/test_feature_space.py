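"""Feature-space construction: binning, counting, QC, TF-IDF/LSA, trees,
cut statistics, peak calling and merging."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

from cladespace.embedding import drop_depth_component, tfidf_lsa, tfidf_transform
from cladespace.fragments import FragmentSet
from cladespace.genome import FeatureSet, GenomeModel, bin_genome, merge_intervals
from cladespace.matrix import CellFeatureMatrix, binarize, count_matrix, qc_filter
from cladespace.metrics import mean_silhouette
from cladespace.peaks import call_clade_peaks, merge_peaks
from cladespace.tree import (build_clade_tree, cosine_distances, cut_statistics,
                             select_cut)


def frags(sample, rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
    return FragmentSet(df, sample=sample)


def simple_matrix(X, features=None, samples=None):
    X = sp.csr_matrix(np.asarray(X, dtype=float))
    n, m = X.shape
    if features is None:
        features = FeatureSet(np.array(["chr1"] * m, dtype=object),
                              np.arange(m) * 100, np.arange(m) * 100 + 50)
    obs = pd.DataFrame({"sample": samples or ["s"] * n,
                        "total_fragments": np.asarray(X.sum(axis=1)).ravel()},
                       index=pd.Index([f"c{i}" for i in range(n)], name="barcode"))
    return CellFeatureMatrix(X, obs, features)


class TestBinGenome:
    def test_truncated_last_window(self):
        g = GenomeModel({"chr1": 12_000})
        fs = bin_genome(g, 5000)
        assert list(zip(fs.start, fs.end)) == [(0, 5000), (5000, 10000), (10000, 12000)]

    def test_exact_fit_single_window(self):
        fs = bin_genome(GenomeModel({"chr1": 5000}), 5000)
        assert len(fs) == 1 and (fs.start[0], fs.end[0]) == (0, 5000)

    def test_window_count_matches_enumeration(self, rng):
        for _ in range(20):
            chroms = {f"chr{i}": int(rng.integers(1, 40_000))
                      for i in range(int(rng.integers(1, 4)))}
            width = int(rng.integers(1, 9_000))
            fs = bin_genome(GenomeModel(chroms), width)
            want = sum(-(-length // width) for length in chroms.values())
            assert len(fs) == want
            # brute-force enumeration of every window
            for c, length in chroms.items():
                m = fs.chrom == c
                assert fs.start[m].tolist() == list(range(0, length, width))

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            bin_genome(GenomeModel({"chr1": 100}), 0)


class TestCountMatrix:
    def test_fragment_spanning_two_windows_counts_in_both(self):
        g = GenomeModel({"chr1": 10_000})
        bins = bin_genome(g, 5000)
        m = count_matrix([frags("s", [("chr1", 4990, 5010, "bc1", 1)])], bins)
        assert m.X.toarray().tolist() == [[1.0, 1.0]]

    def test_no_fragments_zero_matrix(self):
        bins = bin_genome(GenomeModel({"chr1": 10_000}), 5000)
        m = count_matrix([frags("s", [])], bins)
        assert m.X.shape == (0, 2)

    def test_additivity_and_count_field(self):
        bins = bin_genome(GenomeModel({"chr1": 10_000}), 5000)
        m = count_matrix([frags("s", [("chr1", 100, 200, "bc1", 1),
                                      ("chr1", 300, 400, "bc1", 1),
                                      ("chr1", 6000, 6100, "bc1", 3)])], bins)
        assert m.X.toarray().tolist() == [[2.0, 3.0]]
        assert m.obs["total_fragments"].tolist() == [5.0]

    def test_barcode_collision_suffixed(self):
        bins = bin_genome(GenomeModel({"chr1": 10_000}), 5000)
        m = count_matrix([frags("a", [("chr1", 0, 100, "bc1", 1)]),
                          frags("b", [("chr1", 0, 100, "bc1", 1)])], bins)
        assert sorted(m.obs.index) == ["bc1:a", "bc1:b"]

    def test_counts_match_brute_force(self, rng):
        g = GenomeModel({"chr1": 30_000, "chr2": 20_000})
        bins = bin_genome(g, 5000)
        rows = []
        for i in range(300):
            c = "chr1" if rng.random() < 0.6 else "chr2"
            s = int(rng.integers(0, g.chromosomes[c] - 200))
            rows.append((c, s, s + int(rng.integers(1, 200)),
                         f"bc{int(rng.integers(0, 5))}", int(rng.integers(1, 3))))
        m = count_matrix([frags("s", rows)], bins)
        X = m.X.toarray()
        for bi in range(len(bins)):
            for cj, bc in enumerate(m.obs.index):
                want = sum(cnt for (c, s, e, b, cnt) in rows
                           if b == bc and c == bins.chrom[bi]
                           and s < bins.end[bi] and e > bins.start[bi])
                assert X[cj, bi] == want


class TestQcFilter:
    def test_feature_fraction_inclusive_bound(self):
        # 200 cells; feature open in 1 cell (0.5%) dropped, in 2 (1.0%) kept
        X = np.zeros((200, 3))
        X[:, 0] = 1          # keeps cells alive
        X[0, 1] = 1          # 0.5%
        X[0, 2] = 1
        X[1, 2] = 1          # 1.0%
        m = qc_filter(simple_matrix(X), cell_min_frac=0.0, cell_max_frac=1.0,
                      feat_min_frac=0.01, feat_max_frac=1.0)
        assert m.n_features == 2  # the 0.5% feature dropped, 1.0% kept

    def test_cell_open_everywhere_dropped(self):
        X = np.ones((4, 10))
        X[1:, 0] = 0
        m = qc_filter(simple_matrix(X), cell_min_frac=0.0, cell_max_frac=0.975,
                      feat_min_frac=0.0, feat_max_frac=1.0)
        assert "c0" not in m.obs.index and m.n_cells == 3

    def test_noop_bounds_identity(self):
        X = np.eye(5)
        m = qc_filter(simple_matrix(X), 0, 1, 0, 1)
        assert m.X.shape == (5, 5)

    def test_cells_filtered_before_features(self):
        # the all-open cell is removed first, which drops feature 2 below
        # the feature threshold; feature-first ordering would keep it
        X = np.array([[1, 1, 1, 1],
                      [1, 1, 0, 0],
                      [1, 0, 0, 0],
                      [1, 1, 0, 0]])
        m = qc_filter(simple_matrix(X), cell_min_frac=0.0, cell_max_frac=0.9,
                      feat_min_frac=0.35, feat_max_frac=1.0)
        assert m.n_cells == 3
        assert m.n_features == 2

    def test_all_cells_removed_is_hard_error(self):
        X = np.ones((3, 4))
        with pytest.raises(ValueError, match="QC removed all"):
            qc_filter(simple_matrix(X), cell_min_frac=0.0, cell_max_frac=0.5,
                      feat_min_frac=0.0, feat_max_frac=1.0)


class TestBinarize:
    def test_binarize_values_and_idempotence(self):
        m = simple_matrix([[0, 3], [1, 0]])
        b = binarize(m)
        assert b.X.toarray().tolist() == [[0, 1], [1, 0]]
        assert binarize(b).X.toarray().tolist() == b.X.toarray().tolist()
        assert b.obs["total_fragments"].tolist() == [3.0, 1.0]

    def test_row_sums_count_accessible_features(self):
        b = binarize(simple_matrix([[0, 2, 5], [7, 0, 0]]))
        assert np.asarray(b.X.sum(axis=1)).ravel().tolist() == [2.0, 1.0]


class TestTfidfLsa:
    def test_tfidf_worked_example(self):
        m = simple_matrix([[1, 0], [1, 1]])
        W = tfidf_transform(m).toarray()
        tfidf = np.expm1(W) / 1e4
        want = np.array([[np.log(2), 0.0], [np.log(2) / 2, np.log(3) / 2]])
        np.testing.assert_allclose(tfidf, want, atol=1e-12)

    def test_identical_cells_identical_rows(self):
        m = simple_matrix([[1, 0, 1], [1, 0, 1], [0, 1, 1]])
        emb = tfidf_lsa(m, n_components=2)
        np.testing.assert_allclose(emb.components[0], emb.components[1], atol=1e-9)

    def test_full_rank_reconstruction(self, rng):
        X = (rng.random((6, 5)) < 0.5).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        m = simple_matrix(X)
        W = tfidf_transform(m).toarray()
        U, s, Vt = np.linalg.svd(W, full_matrices=False)
        np.testing.assert_allclose(U @ np.diag(s) @ Vt, W, atol=1e-8)

    def test_all_zero_row_names_barcode(self):
        m = simple_matrix([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            tfidf_lsa(m, n_components=1)


class TestDropDepthComponent:
    def test_depth_driven_component_flagged(self, rng):
        # cells differing mainly in depth: component 1 tracks log depth
        depth = np.exp(rng.normal(5, 1, size=60))
        X = (rng.random((60, 120)) < np.clip(depth[:, None] / 800, 0.02, 0.98))
        X = X.astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        m = simple_matrix(X)
        emb = tfidf_lsa(m, n_components=6)
        out = drop_depth_component(emb, m, threshold_abs_corr=0.7)
        assert 1 in out.dropped_components
        assert out.retained().shape[1] == 6 - len(out.dropped_components)

    def test_constant_depth_drops_nothing(self):
        m = simple_matrix([[1, 0, 1], [0, 1, 1], [1, 1, 0]])
        emb = tfidf_lsa(m, n_components=2)
        out = drop_depth_component(emb, m)
        assert out.dropped_components == []

    def test_unreachable_threshold(self, rng):
        X = (rng.random((20, 30)) < 0.4).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        m = simple_matrix(X)
        emb = tfidf_lsa(m, n_components=4)
        out = drop_depth_component(emb, m, threshold_abs_corr=1.01)
        assert out.dropped_components == []


class TestCladeTree:
    def test_two_cells_merge_at_cosine_distance(self):
        pts = np.array([[1.0, 0.0], [1.0, 1.0]])
        tree = build_clade_tree(pts)
        want = 1 - 1 / np.sqrt(2)
        assert tree.heights[0] == pytest.approx(want, abs=1e-12)

    def test_two_tight_groups_merge_last(self):
        pts = np.array([[1, 0.01], [1, 0.0], [0.01, 1], [0.0, 1.0]])
        tree = build_clade_tree(pts)
        assert tree.heights[-1] > 10 * tree.heights[0]
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_row_scaling_invariance(self, rng):
        pts = rng.normal(size=(12, 4))
        scale = rng.uniform(0.5, 3.0, size=12)
        t1 = build_clade_tree(pts)
        t2 = build_clade_tree(pts * scale[:, None])
        np.testing.assert_allclose(t1.Z, t2.Z, atol=1e-9)


class TestCutStatistics:
    def make_1d_tree(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        D = squareform(pdist(pts))
        from scipy.cluster.hierarchy import linkage
        from cladespace.tree import CladeTree
        Z = linkage(pdist(pts), method="ward")
        return CladeTree(Z, 4), D

    def test_hand_computed_example(self):
        tree, D = self.make_1d_tree()
        stats = cut_statistics(tree, D)
        row = stats.table[stats.table["n_clades"] == 2].iloc[0]
        # silhouette: (10.05-0.1)/10.05 for the inner points etc.
        want_sil = np.mean([(10.05 - 0.1) / 10.05, (9.95 - 0.1) / 9.95,
                            (9.95 - 0.1) / 9.95, (10.05 - 0.1) / 10.05])
        assert row["silhouette"] == pytest.approx(want_sil, abs=1e-9)
        assert row["silhouette"] == pytest.approx(0.990, abs=1e-3)
        assert row["dunn2"] == pytest.approx(100.0, abs=1e-9)

    def test_identical_points_silhouette_zero(self):
        D = np.zeros((4, 4))
        assert mean_silhouette(D, [0, 0, 1, 1]) == 0.0

    def test_single_clade_height_recorded_missing(self):
        tree, D = self.make_1d_tree()
        stats = cut_statistics(tree, D, heights=[1e9])
        assert np.isnan(stats.table["silhouette"].iloc[0])


class TestSelectCut:
    def test_unique_max_and_tie_rules(self):
        from cladespace.tree import CladeTree, CutStatistics
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        from scipy.cluster.hierarchy import linkage
        tree = CladeTree(linkage(pdist(pts), method="ward"), 4)
        t = pd.DataFrame({"height": [1.0, 2.0, 3.0],
                          "n_clades": [3, 2, 2],
                          "dunn2": [5.0, 9.0, 1.0],
                          "silhouette": [0.5, 0.8, 0.8]})
        h, labels = select_cut(CutStatistics(t), tree)
        assert h == 2.0  # silhouette tie at 0.8 -> higher Dunn2 wins

    def test_no_valid_height_errors(self):
        from cladespace.tree import CladeTree, CutStatistics
        tree = CladeTree(np.array([[0, 1, 1.0, 2]]), 2)
        with pytest.raises(ValueError):
            select_cut(CutStatistics(pd.DataFrame(
                {"height": [1.0], "n_clades": [1],
                 "dunn2": [np.nan], "silhouette": [np.nan]})), tree)


class TestPeaks:
    def test_no_fragments_no_peaks(self):
        g = GenomeModel({"chr1": 1_000_000})
        out = call_clade_peaks([frags("s", [])], ["bc1"], g)
        assert len(out) == 0

    def test_single_stack_one_peak(self):
        g = GenomeModel({"chr1": 1_000_000})
        rows = [("chr1", 1000, 1200, "bc1", 1)] * 5
        out = call_clade_peaks([frags("s", rows)], ["bc1"], g, clade_id=3)
        assert len(out) == 1
        assert out.start[0] <= 1000 and out.end[0] >= 1200
        assert out.source[0] == frozenset([3])

    def test_uniform_coverage_no_peaks(self):
        g = GenomeModel({"chr1": 10_000})
        rows = [("chr1", s, s + 100, "bc1", 1) for s in range(0, 9_900, 100)]
        out = call_clade_peaks([frags("s", rows)], ["bc1"], g)
        assert len(out) == 0

    def test_brute_force_pileup(self, rng):
        g = GenomeModel({"chr1": 50_000})
        rows = []
        for _ in range(40):
            s = int(rng.integers(0, 4)) * 500 + 1000
            rows.append(("chr1", s, s + int(rng.integers(50, 200)), "bc1", 1))
        out = call_clade_peaks([frags("s", rows)], ["bc1"], g, merge_gap=0,
                               min_width=1)
        cov = np.zeros(50_000)
        for (_, s, e, _, cnt) in rows:
            cov[s:e] += cnt
        lam = cov.sum() / 50_000
        from scipy.stats import poisson
        k = 0
        while poisson.sf(k - 1, lam) >= 0.05:
            k += 1
        mask = (cov >= 4 * lam) & (cov >= k)
        inside = np.zeros(50_000, dtype=bool)
        for c, s, e in zip(out.chrom, out.start, out.end):
            inside[s:e] = True
        assert (mask == inside).all()


class TestMergePeaks:
    def test_overlap_union(self):
        a = FeatureSet(np.array(["chr1"], dtype=object), [100], [200], [frozenset([0])])
        b = FeatureSet(np.array(["chr1"], dtype=object), [150], [250], [frozenset([1])])
        out = merge_peaks([a, b])
        assert (out.start.tolist(), out.end.tolist()) == ([100], [250])
        assert out.source[0] == frozenset([0, 1])

    def test_disjoint_retained_book_ended_merged(self):
        a = FeatureSet(np.array(["chr1", "chr1"], dtype=object), [0, 100], [50, 150])
        out = merge_peaks([a])
        assert len(out) == 2
        b = FeatureSet(np.array(["chr1", "chr1"], dtype=object), [0, 50], [50, 150])
        assert len(merge_peaks([b])) == 1

    def test_idempotent_and_order_independent(self, rng):
        sets = []
        for i in range(4):
            starts = rng.integers(0, 2_000, size=8)
            sets.append(FeatureSet(np.array(["chr1"] * 8, dtype=object),
                                   starts, starts + rng.integers(1, 300, size=8),
                                   [frozenset([i])] * 8))
        merged = merge_peaks(sets)
        again = merge_peaks([merged])
        assert merged.to_dataframe().equals(again.to_dataframe())
        perm = merge_peaks([sets[2], sets[0], sets[3], sets[1]])
        assert merged.to_dataframe().equals(perm.to_dataframe())


class TestRescoreAndRecovery:
    def test_totals_match_brute_force_on_merged_features(self, rng, tiny_world):
        _, genome, fragments, _, _ = tiny_world
        starts = np.sort(rng.choice(200_000, size=20, replace=False))
        feats = merge_intervals(FeatureSet(
            np.array(["chr1"] * 20, dtype=object), starts, starts + 400), genome)
        from cladespace.matrix import rescore
        m = rescore(fragments[:1], feats)
        totals = np.asarray(m.X.sum(axis=0)).ravel()
        r = fragments[0].records
        for i in range(len(feats)):
            want = r[(r["chrom"] == feats.chrom[i]) & (r["start"] < feats.end[i])
                     & (r["end"] > feats.start[i])]["count"].sum()
            assert totals[i] == want

    def test_planted_sites_recovered_by_merged_features(self, tiny_world):
        """>=90% of planted sites covered >=80% by a merged feature."""
        from cladespace.pipeline import run_feature_pipeline
        spec, genome, fragments, truth, _ = tiny_world
        res = run_feature_pipeline(fragments, genome, seed=0, cluster=False)
        feats = res.features
        sites = truth.sites
        covered = 0
        for s in sites.itertuples(index=False):
            m = (feats.chrom == s.chrom) & (feats.start < s.end) & (feats.end > s.start)
            ov = sum(min(s.end, e) - max(s.start, st)
                     for st, e in zip(feats.start[m], feats.end[m]))
            if ov >= 0.8 * (s.end - s.start):
                covered += 1
        assert covered / len(sites) >= 0.9

    def test_single_sample_features_nest_in_joint(self, tiny_world):
        """Features called from one sample mostly overlap the joint set."""
        from cladespace.annotation import overlap_sets
        from cladespace.pipeline import run_feature_pipeline
        spec, genome, fragments, truth, _ = tiny_world
        joint = run_feature_pipeline(fragments, genome, seed=0, cluster=False).features
        single = run_feature_pipeline(fragments[:1], genome, seed=0,
                                      cluster=False).features
        venn = overlap_sets(single, joint, min_overlap_bp=1)
        assert venn.a_both / len(single) >= 0.9

    def test_label_free_null_supports_single_clade(self):
        """One planted type: no cut height shows clear multi-clade support."""
        from conftest import tiny_spec
        from cladespace.pipeline import run_feature_pipeline
        from cladespace.synthetic import make_genome, simulate_fragments
        spec = tiny_spec(n_cell_types=1, n_cells_per_type=60, seed=11)
        genome = make_genome(spec)
        fragments, _ = simulate_fragments(genome, spec)
        from cladespace.genome import bin_genome
        from cladespace.matrix import binarize, count_matrix, qc_filter
        from cladespace.pipeline import embed_binary_matrix
        from cladespace.tree import build_clade_tree, cosine_distances, cut_statistics
        binary = binarize(qc_filter(count_matrix(fragments, bin_genome(genome, 5000))))
        emb = embed_binary_matrix(binary, seed=11)
        tree = build_clade_tree(emb)
        D = cosine_distances(emb.retained())
        stats = cut_statistics(tree, D, tree.candidate_heights(max_clades=10))
        assert stats.valid()["silhouette"].max() < 0.25
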