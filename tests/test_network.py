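"""Module detection, eigengenes and meta-module grouping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stressmem.network import (
    EigengeneSet,
    cluster_and_cut,
    compute_eigengenes,
    gene_dissimilarity,
    group_metamodules,
    variation_filter,
)
from stressmem.simulate import ModulePlan, SimulationSpec, simulate_expression

from conftest import make_study


def tom_oracle(a):
    """Direct triple-sum evaluation of the topological-overlap formula."""
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                w[i, j] = 1.0
                continue
            s = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            w[i, j] = (s + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return 1.0 - w


class TestVariationFilter:
    def test_boundary_is_strict(self, six_sample_stages):
        # exactly representable binary fractions avoid float-boundary noise
        fpkm = np.array(
            [
                [1.0, 1.0, 1.0, 1.0, 1.0, 1.5625],  # range 0.5625 -> kept
                [1.0, 1.0, 1.0, 1.0, 1.0, 1.5],  # range exactly 0.5 -> removed
                [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],  # constant -> removed
            ]
        )
        study = make_study(fpkm, six_sample_stages)
        kept = variation_filter(study, 0.5)
        assert list(kept.genes) == ["g0"]

    def test_matches_brute_force_scan(self, six_sample_stages):
        rng = np.random.default_rng(5)
        fpkm = rng.uniform(0, 10, (50, 6))
        study = make_study(fpkm, six_sample_stages)
        kept = variation_filter(study, 3.0)
        expected = [
            f"g{i}" for i in range(50) if fpkm[i].max() - fpkm[i].min() > 3.0
        ]
        assert list(kept.genes) == expected


class TestDissimilarity:
    def test_duplicated_gene_distance_zero(self, six_sample_stages):
        rng = np.random.default_rng(0)
        row = rng.uniform(1, 50, 6)
        study = make_study([row, row, rng.uniform(1, 50, 6)], six_sample_stages)
        d = gene_dissimilarity(study, "cor")
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.diag(d), 0.0)

    def test_tom_matches_triple_sum_oracle(self, six_sample_stages):
        rng = np.random.default_rng(2)
        study = make_study(rng.uniform(1, 100, (4, 6)), six_sample_stages)
        d = gene_dissimilarity(study, "tom", power=6.0)
        X = np.log2(study.fpkm.to_numpy() + 1)
        a = np.abs(np.corrcoef(X)) ** 6.0
        np.fill_diagonal(a, 0.0)
        np.testing.assert_allclose(d.to_numpy(), tom_oracle(a), atol=1e-12)

    def test_uncorrelated_noise_near_one_at_power_one(self):
        rng = np.random.default_rng(8)
        # long profiles so the sample correlation is close to zero
        stages = ["W"] * 20 + ["S1"] * 20 + ["S3"] * 20
        study = make_study(rng.uniform(1, 100, (2, 60)), stages)
        d = gene_dissimilarity(study, "cor", power=1.0)
        X = np.log2(study.fpkm.to_numpy() + 1)
        r = np.corrcoef(X)[0, 1]
        assert d.iloc[0, 1] == pytest.approx(1 - abs(r), abs=1e-12)
        assert d.iloc[0, 1] > 0.7

    def test_zero_variance_gene_rejected(self, six_sample_stages):
        study = make_study([[1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6]], six_sample_stages)
        with pytest.raises(ValueError, match="zero-variance"):
            gene_dissimilarity(study)

    def test_symmetry_and_range(self, six_sample_stages):
        rng = np.random.default_rng(4)
        study = make_study(rng.uniform(0, 100, (30, 6)), six_sample_stages)
        for method in ("cor", "tom"):
            d = gene_dissimilarity(study, method).to_numpy()
            assert np.allclose(d, d.T)
            assert d.min() >= 0 and d.max() <= 1
            assert np.allclose(np.diag(d), 0)


class TestClusterAndCut:
    def test_two_zero_noise_blocks(self):
        spec = SimulationSpec(
            n_genes=80,
            modules=(
                ModulePlan(40, (6.0, 8.0, 10.0), "[+/+]"),
                ModulePlan(40, (6.0, 6.0, 8.0), "[=/+]"),
            ),
            replicate_sd=0.0,
            loading_sd=0.0,
            seed=1,
        )
        study, truth = simulate_expression(spec)
        d = gene_dissimilarity(study, "cor")
        part = cluster_and_cut(d, min_module_size=30)
        assert len(part.module_ids) == 2
        assert adjusted_rand_score(truth.gene_module, part.assignment) == 1.0

    def test_too_few_genes_all_unassigned(self, six_sample_stages):
        rng = np.random.default_rng(1)
        study = make_study(rng.uniform(1, 50, (20, 6)), six_sample_stages)
        d = gene_dissimilarity(study)
        part = cluster_and_cut(d, min_module_size=30)
        assert (part.assignment == 0).all()
        assert part.module_ids == []

    def test_planted_partition_recovered_at_low_noise(self, small_sim):
        spec, study, truth = small_sim
        filt = variation_filter(study, 0.05)
        d = gene_dissimilarity(filt, "cor")
        part = cluster_and_cut(d, min_module_size=30)
        ari = adjusted_rand_score(truth.gene_module.loc[filt.genes], part.assignment)
        assert len(part.module_ids) == 3
        assert ari >= 0.9

    def test_determinism(self, small_sim):
        _, study, _ = small_sim
        d = gene_dissimilarity(study, "cor")
        p1 = cluster_and_cut(d, 30)
        p2 = cluster_and_cut(d, 30)
        assert p1.assignment.equals(p2.assignment)

    def test_size_floor_enforced(self, small_sim):
        _, study, _ = small_sim
        d = gene_dissimilarity(study, "cor")
        part = cluster_and_cut(d, 30)
        for m, size in part.sizes().items():
            if m != 0:
                assert size >= 30


class TestEigengenes:
    def test_identical_genes_explained_variance_one(self):
        row = np.array([1.0, 2.0, 8.0, 9.0, 30.0, 31.0])
        study = make_study([row, row, row], ["W", "W", "S1", "S1", "S3", "S3"])
        part_labels = pd.Series([1, 1, 1], index=study.genes)
        from stressmem.network import ModulePartition

        part = ModulePartition(part_labels, None, {})
        eigs = compute_eigengenes(study, part)
        assert eigs.explained_variance[1] == pytest.approx(1.0)
        prof = (np.log2(row + 1) - np.log2(row + 1).mean())
        prof = prof / np.linalg.norm(prof)
        np.testing.assert_allclose(np.abs(eigs.eigengenes.loc[1]), np.abs(prof), atol=1e-12)

    def test_matches_gram_eigendecomposition_oracle(self, six_sample_stages):
        """First PC equals the leading eigenvector of the sample-space Gram
        matrix, an independent route to the same subspace."""
        rng = np.random.default_rng(10)
        study = make_study(rng.uniform(1, 100, (10, 6)), six_sample_stages)
        from stressmem.network import ModulePartition

        part = ModulePartition(pd.Series(1, index=study.genes), None, {})
        eigs = compute_eigengenes(study, part)
        X = np.log2(study.fpkm.to_numpy() + 1)
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        evals, evecs = np.linalg.eigh(Xs.T @ Xs)
        lead = evecs[:, -1]
        got = eigs.eigengenes.loc[1].to_numpy()
        cosine = abs(np.dot(got, lead)) / np.linalg.norm(lead)
        assert cosine == pytest.approx(1.0, abs=1e-9)

    def test_orientation_contract(self, six_sample_stages):
        rng = np.random.default_rng(11)
        from stressmem.network import ModulePartition

        for seed in range(5):
            study = make_study(
                np.random.default_rng(seed).uniform(1, 100, (8, 6)), six_sample_stages
            )
            part = ModulePartition(pd.Series(1, index=study.genes), None, {})
            eigs = compute_eigengenes(study, part)
            X = np.log2(study.fpkm.to_numpy() + 1)
            Xs = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
            c = np.corrcoef(eigs.eigengenes.loc[1], Xs.mean(0))[0, 1]
            assert c >= 0

    def test_unit_norm(self, small_sim):
        _, study, _ = small_sim
        filt = variation_filter(study, 0.05)
        d = gene_dissimilarity(filt)
        part = cluster_and_cut(d, 30)
        eigs = compute_eigengenes(filt, part)
        norms = np.linalg.norm(eigs.eigengenes.to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)


class TestMetaModules:
    @staticmethod
    def _eigset(rows):
        eg = pd.DataFrame(rows)
        eg.index = range(1, len(rows) + 1)
        eg.columns = [f"W_r{i}" for i in range(eg.shape[1])]
        ids = list(eg.index)
        return EigengeneSet(eg, pd.Series(1.0, index=ids), pd.Series(1.0, index=ids))

    def test_perfectly_correlated_modules_merge(self):
        v = np.array([0.1, 0.2, 0.3, 0.5, 0.6, 0.9])
        eigs = self._eigset([v, 2 * v - 0.1])
        grouping = group_metamodules(eigs, cut=0.2)
        assert grouping.labels[1] == grouping.labels[2]

    def test_anticorrelated_module_stays_solo(self):
        v = np.array([0.1, 0.2, 0.3, 0.5, 0.6, 0.9])
        w = np.array([0.15, 0.18, 0.33, 0.48, 0.62, 0.88])
        eigs = self._eigset([v, w, -v])
        grouping = group_metamodules(eigs, cut=0.2)
        assert grouping.labels[1] == grouping.labels[2]
        assert grouping.labels[3] != grouping.labels[1]
        assert 3 in grouping.solo_modules()

    def test_hand_computed_average_linkage_merges(self):
        """Four eigengenes with known pairwise correlations: (1,2) merge at
        1-r=0.02; (3) joins them only above the cut; 4 is anti-correlated."""
        t = np.linspace(0, 1, 6)
        e1 = np.sin(2 * np.pi * t)
        e2 = np.sin(2 * np.pi * t + 0.05)
        e3 = np.cos(2 * np.pi * t)
        e4 = -e1
        eigs = self._eigset([e1, e2, e3, e4])
        grouping = group_metamodules(eigs, cut=0.2)
        d = grouping.dissimilarity
        # hand check: d12 small, d13 ~ 1, d14 ~ 2
        assert d.loc[1, 2] < 0.2
        assert d.loc[1, 3] > 0.5
        assert d.loc[1, 4] > 1.5
        assert grouping.labels[1] == grouping.labels[2]
        assert len(set(grouping.labels)) == 3

    def test_single_module(self):
        v = np.array([0.1, 0.2, 0.3, 0.5, 0.6, 0.9])
        eigs = self._eigset([v])
        grouping = group_metamodules(eigs, cut=0.2)
        assert grouping.labels.to_dict() == {1: "A"}
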