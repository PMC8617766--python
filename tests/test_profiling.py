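"""Metabolite profiling: normalization, composition, clustering, PCA."""

import numpy as np
import pandas as pd
import pytest

from nutrascreen import datasets, profiling
from nutrascreen.errors import NormalizationError, SizeError, VocabularyError
from nutrascreen.profiling import AbundanceMatrix
from nutrascreen.synth import GeneratorSpec, gen_metabolite_matrix


def _matrix(values, compounds=None, samples=None):
    values = np.asarray(values, dtype=float)
    compounds = compounds or [f"c{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(pd.DataFrame(values, index=compounds, columns=samples))


class TestInternalStandardNormalization:
    def test_equal_is_preserves_proportions(self):
        m = _matrix([[2, 4], [6, 8], [5, 5]], compounds=["a", "b", "IS"])
        out = profiling.normalize_by_internal_standard(m, ["IS"])
        assert np.allclose(out.data.to_numpy(), np.array([[2, 4], [6, 8]]) / 5.0)
        assert "IS" not in out.data.index

    def test_doubled_is_halves_abundances(self):
        m = _matrix([[2, 2], [1, 2]], compounds=["a", "IS"])
        out = profiling.normalize_by_internal_standard(m, ["IS"])
        assert out.data.loc["a", "s1"] == pytest.approx(out.data.loc["a", "s0"] / 2)

    def test_geometric_mean_of_two_standards(self):
        m = _matrix([[12.0], [4.0], [9.0]], compounds=["a", "IS1", "IS2"])
        out = profiling.normalize_by_internal_standard(m, ["IS1", "IS2"])
        assert out.data.loc["a", "s0"] == pytest.approx(12.0 / 6.0)  # gm(4, 9) = 6

    def test_zero_is_names_sample(self):
        m = _matrix([[1, 1], [1, 0]], compounds=["a", "IS"])
        with pytest.raises(NormalizationError, match="s1"):
            profiling.normalize_by_internal_standard(m, ["IS"])

    def test_column_scale_invariance(self, rng):
        vals = rng.lognormal(2, 0.5, size=(5, 3))
        m = _matrix(vals, compounds=["a", "b", "c", "d", "IS"])
        scaled = m.data.copy()
        scaled["s1"] *= 7.3
        out1 = profiling.normalize_by_internal_standard(m, ["IS"])
        out2 = profiling.normalize_by_internal_standard(AbundanceMatrix(scaled), ["IS"])
        assert np.allclose(out1.data.to_numpy(), out2.data.to_numpy())


class TestClassComposition:
    def test_packaged_table_percentages(self):
        pct, counts, sub = profiling.class_composition(datasets.load_metabolites())
        assert pct["phenolic acid"] == 26
        assert pct["other polyphenol"] == 9
        assert counts["phenolic acid"] == 14 + 7 + 3 + 2
        assert int(pct.sum()) in (99, 100, 101)  # integer rounding

    def test_single_class_is_100(self):
        table = pd.DataFrame(
            {"name": ["x", "y"], "compound_class": "flavonoid", "subclass": "flavonol"}
        )
        pct, _, _ = profiling.class_composition(table)
        assert pct["flavonoid"] == 100

    def test_unknown_class_rejected(self):
        table = pd.DataFrame(
            {"name": ["x"], "compound_class": ["terpene"], "subclass": ["?"]}
        )
        with pytest.raises(VocabularyError):
            profiling.class_composition(table)


class TestPresenceSummary:
    def test_packaged_counts(self):
        summary = profiling.genotype_presence_summary(datasets.load_metabolites())
        assert summary.counts == {"KA": 70, "CH": 68, "KU": 71}
        assert len(summary.unique["KU"]) == 5
        assert "epigallocatechin" in summary.unique["KU"]
        assert "isoxanthohumol" in summary.unique["KA"]

    def test_against_set_arithmetic_oracle(self):
        membership = {
            "m1": {"A"}, "m2": {"A", "B"}, "m3": {"A", "B", "C"},
            "m4": {"C"}, "m5": {"B", "C"},
        }
        genotypes = ["A", "B", "C"]
        table = pd.DataFrame(
            [
                {"name": name, **{f"present_{g}": g in mem for g in genotypes}}
                for name, mem in membership.items()
            ]
        )
        summary = profiling.genotype_presence_summary(table)
        for g in genotypes:
            assert summary.counts[g] == sum(g in mem for mem in membership.values())
            assert summary.unique[g] == sorted(
                n for n, mem in membership.items() if mem == {g}
            )
        assert summary.core == sorted(
            n for n, mem in membership.items() if mem == set(genotypes)
        )

    def test_core_compound_not_unique(self):
        table = pd.DataFrame(
            [{"name": "x", "present_A": True, "present_B": True}]
        )
        summary = profiling.genotype_presence_summary(table)
        assert summary.core == ["x"]
        assert summary.unique == {"A": [], "B": []}


class TestSelectTopN:
    def test_identity_when_n_equals_rows(self):
        m = _matrix([[1, 2], [3, 4]])
        out = profiling.select_top_n(m, 2)
        assert set(out.data.index) == set(m.data.index)

    def test_constant_matrix_ties_break_lexicographically(self):
        m = _matrix(np.ones((4, 3)), compounds=["d", "b", "a", "c"])
        out = profiling.select_top_n(m, 2, criterion="variance")
        assert list(out.data.index) == ["a", "b"]

    def test_high_variance_row_ranked_first(self, rng):
        vals = np.ones((5, 4))
        vals[2] = [0, 10, 0, 10]
        m = _matrix(vals)
        out = profiling.select_top_n(m, 1, criterion="variance")
        assert list(out.data.index) == ["c2"]

    def test_n_too_large(self):
        with pytest.raises(SizeError):
            profiling.select_top_n(_matrix([[1, 2]]), 5)


def _ward_oracle(points):
    """Exhaustive Lance-Williams Ward agglomeration for small inputs."""
    clusters = {i: [i] for i in range(len(points))}
    sizes = {i: 1 for i in clusters}
    centroids = {i: np.asarray(points[i], dtype=float) for i in clusters}
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                na, nb = sizes[a], sizes[b]
                d2 = np.sum((centroids[a] - centroids[b]) ** 2)
                cost = np.sqrt(2.0 * na * nb / (na + nb) * d2)
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        cost, a, b = best
        merges.append((a, b, cost))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        centroids[next_id] = (sizes[a] * centroids[a] + sizes[b] * centroids[b]) / (
            sizes[a] + sizes[b]
        )
        sizes[next_id] = sizes[a] + sizes[b]
        next_id += 1
    return merges


class TestWardCluster:
    def test_identical_profiles_merge_first_at_zero(self):
        m = _matrix([[1, 2, 3], [1, 2, 3], [9, 9, 9]])
        result = profiling.ward_cluster(m)
        first = result.merges[0]
        assert {first[0], first[1]} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_four_item_agreement_with_exhaustive_oracle(self, rng):
        points = rng.lognormal(1, 0.5, size=(4, 3))
        m = _matrix(points)
        result = profiling.ward_cluster(m)
        oracle = _ward_oracle(points)
        for (ia, ib, h), (oa, ob, oh) in zip(result.merges, oracle):
            assert {ia, ib} == {oa, ob}
            assert h == pytest.approx(oh)

    def test_heights_nondecreasing_and_permutation_invariant(self, rng):
        vals = rng.lognormal(1, 0.6, size=(8, 4))
        m = _matrix(vals)
        res = profiling.ward_cluster(m)
        heights = [h for _, _, h in res.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))
        perm = rng.permutation(8)
        m2 = AbundanceMatrix(m.data.iloc[perm])
        res2 = profiling.ward_cluster(m2)
        assert np.allclose([h for _, _, h in res2.merges], heights)
        assert set(res2.leaf_order) == set(res.leaf_order)

    def test_planted_blocks_recovered_at_k3(self):
        matrix, truth = gen_metabolite_matrix(
            30, {"g1": 3, "g2": 3, "g3": 3}, n_markers=10, fold_change=8.0,
            spec=GeneratorSpec(seed=7),
        )
        result = profiling.ward_cluster(matrix, axis="samples")
        cut = result.cut(3)
        clusters_by_group = {}
        for sample, cluster in cut.items():
            clusters_by_group.setdefault(truth["sample_groups"][sample], set()).add(cluster)
        assert all(len(c) == 1 for c in clusters_by_group.values())
        assert len(set.union(*clusters_by_group.values())) == 3

    def test_too_few_items(self):
        with pytest.raises(SizeError):
            profiling.ward_cluster(_matrix([[1, 2]]), axis="compounds")


class TestPca:
    def test_closed_form_variance_fractions(self):
        # 4 samples whose sample covariance is exactly diag(2, 1)
        a, b = np.sqrt(3), np.sqrt(1.5)
        data = np.array([[a, 0], [-a, 0], [0, b], [0, -b]]).T  # compounds x samples
        res = profiling.pca(_matrix(data - data.min() + 1.0), scaling="center_only")
        assert res.variance_fractions[0] == pytest.approx(2 / 3)
        assert res.variance_fractions[1] == pytest.approx(1 / 3)

    def test_rotation_invariance_of_variance_fractions(self, rng):
        X = rng.normal(0, 1, size=(6, 5))  # samples x compounds
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        m1 = AbundanceMatrix(pd.DataFrame(X.T - X.min() + 1))
        m2 = AbundanceMatrix(pd.DataFrame((X @ q).T - (X @ q).min() + 1))
        f1 = profiling.pca(m1, scaling="center_only").variance_fractions
        f2 = profiling.pca(m2, scaling="center_only").variance_fractions
        assert np.allclose(f1, f2, atol=1e-10)

    def test_full_reconstruction(self, rng):
        vals = rng.lognormal(2, 0.7, size=(12, 5))
        m = _matrix(vals)
        res = profiling.pca(m, scaling="autoscale")
        X = m.data.T
        scaled = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, scaled.to_numpy(), atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        m = _matrix(rng.lognormal(2, 0.7, size=(10, 6)))
        L = profiling.pca(m).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_genotype_groups_separate_in_score_space(self):
        matrix, truth = gen_metabolite_matrix(
            40, {"g1": 3, "g2": 3, "g3": 3}, n_markers=10, fold_change=8.0,
            spec=GeneratorSpec(seed=11),
        )
        res = profiling.pca(matrix)
        scores = res.scores.iloc[:, :2]
        groups = {}
        for sample in scores.index:
            groups.setdefault(truth["sample_groups"][sample], []).append(
                scores.loc[sample].to_numpy()
            )
        centroids = {g: np.mean(v, axis=0) for g, v in groups.items()}
        spreads = [
            np.linalg.norm(np.asarray(v) - centroids[g], axis=1).max()
            for g, v in groups.items()
        ]
        names = list(centroids)
        for i, gi in enumerate(names):
            for gj in names[i + 1:]:
                dist = np.linalg.norm(centroids[gi] - centroids[gj])
                assert dist > max(spreads)

    def test_zero_variance_compounds_dropped_with_warning(self):
        vals = np.array([[1.0, 1.0, 1.0], [1, 2, 3], [4, 1, 2]])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = profiling.pca(_matrix(vals))
        assert res.dropped_compounds == ["c0"]
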