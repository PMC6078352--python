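import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_landscape
from ubscan.landscape import difference_map
from ubscan.multivariate import (
    ConditionMatrix,
    build_condition_matrix,
    flat_clusters,
    loading_percent_of_max,
    pca_difference,
    position_mean_loading,
    tree_to_newick,
    ward_cluster,
)


def matrix_from_array(X, conditions=None, mutants=None):
    n, p = X.shape
    conditions = conditions or [f"c{i}" for i in range(n)]
    mutants = mutants or [f"A{j + 2}G" for j in range(p)]
    df = pd.DataFrame(X, index=conditions, columns=mutants)
    return ConditionMatrix(values=df, complete_case=True, stops_excluded=True)


# ---------------------------------------------------------------- build

class TestBuildConditionMatrix:
    def make_inputs(self):
        a = make_landscape({2: {"G": -0.2, "W": -0.1, "*": -1.0}}, condition="a")
        b = make_landscape({2: {"G": -0.3, "W": np.nan, "*": -1.0}}, condition="b")
        c = make_landscape({2: {"G": -0.4, "W": -0.5, "*": -1.0}}, condition="c")
        return {"a": a, "b": b, "c": c}

    def test_complete_case_drops_mutant_everywhere(self):
        """A mutant missing in any single condition is excluded from
        the analysis for all conditions."""
        cm = build_condition_matrix(self.make_inputs())
        assert "A2W" not in cm.mutants
        assert "A2G" in cm.mutants

    def test_no_missing_keeps_all_columns(self):
        inputs = self.make_inputs()
        del inputs["b"]
        cm = build_condition_matrix(inputs)
        assert {"A2G", "A2W", "A2*"} <= set(cm.mutants)

    def test_exclude_stops_removes_exactly_stop_columns(self):
        inputs = self.make_inputs()
        inputs["b"] = make_landscape(
            {2: {"G": -0.3, "W": -0.2, "*": -1.0}}, condition="b"
        )  # complete data: only the stop filter removes columns
        cm = build_condition_matrix(inputs, exclude_stops=True)
        assert all(not m.endswith("*") for m in cm.mutants)
        with_stops = build_condition_matrix(inputs, exclude_stops=False)
        assert set(with_stops.mutants) - set(cm.mutants) == {"A2*"}

    def test_complete_case_idempotent_and_order_invariant(self):
        inputs = self.make_inputs()
        cm1 = build_condition_matrix(inputs)
        cm2 = build_condition_matrix(dict(reversed(list(inputs.items()))))
        assert set(cm1.mutants) == set(cm2.mutants)
        again = build_condition_matrix(
            {n: make_landscape(
                {2: {m[-1]: cm1.values.at[n, m] for m in cm1.mutants}}, condition=n
            ) for n in cm1.conditions}
        )
        assert set(again.mutants) == set(cm1.mutants)

    def test_too_few_conditions_errors(self):
        inputs = self.make_inputs()
        with pytest.raises(ValueError):
            build_condition_matrix({"a": inputs["a"]})

    def test_too_few_complete_mutants_errors(self):
        a = make_landscape({2: {"G": -0.2, "W": np.nan}}, condition="a")
        b = make_landscape({2: {"G": np.nan, "W": -0.1}}, condition="b")
        with pytest.raises(ValueError, match="complete-case"):
            build_condition_matrix({"a": a, "b": b})

    def test_accepts_difference_maps(self, mini_landscapes):
        dmaps = {
            name: difference_map(land, mini_landscapes["DMSO"])
            for name, land in mini_landscapes.items()
            if name != "DMSO"
        }
        cm = build_condition_matrix(dmaps, exclude_stops=True)
        assert len(cm.conditions) == 2


# ---------------------------------------------------------------- ward

def ward_increase(a: np.ndarray, b: np.ndarray) -> float:
    """Increase in total within-cluster sum of squares when merging
    clusters with members a, b (rows = points)."""
    na, nb = len(a), len(b)
    d = a.mean(axis=0) - b.mean(axis=0)
    return na * nb / (na + nb) * float(d @ d)


def brute_force_ward_check(X, Z, atol=1e-8):
    """Verify each scipy merge picks a minimum-objective pair and that
    the reported height equals sqrt(2 * objective increase)."""
    clusters = {i: [i] for i in range(len(X))}
    for step, (ia, ib, height, size) in enumerate(Z):
        increases = {
            (i, j): ward_increase(X[clusters[i]], X[clusters[j]])
            for i, j in itertools.combinations(sorted(clusters), 2)
        }
        best = min(increases.values())
        got = increases[tuple(sorted((int(ia), int(ib))))]
        assert got <= best + atol, f"step {step}: merged pair is not optimal"
        assert np.isclose(height, np.sqrt(2 * got), atol=atol)
        new_id = len(X) + step
        clusters[new_id] = clusters.pop(int(ia)) + clusters.pop(int(ib))
        assert size == len(clusters[new_id])


class TestWardCluster:
    def test_identical_vectors_merge_first_at_zero(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]])
        tree = ward_cluster(matrix_from_array(X))
        first = tree.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 2}
        assert first[2] == 0.0

    def test_heights_nondecreasing(self, rng=np.random.default_rng(1)):
        X = rng.normal(size=(8, 5))
        tree = ward_cluster(matrix_from_array(X))
        heights = tree.merges[:, 2]
        assert (np.diff(heights) >= 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_sequence_matches_ward_objective_oracle(self, seed):
        """Every agglomeration step minimizes the within-cluster
        variance increase (checked exhaustively over cluster pairs)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 7)
        X = rng.normal(size=(n, 4))
        tree = ward_cluster(matrix_from_array(X))
        brute_force_ward_check(X, tree.merges)

    def test_planted_groups_are_last_merge(self):
        rng = np.random.default_rng(0)
        X = rng.normal(scale=0.1, size=(6, 3))
        X[3:] += 100.0  # two well-separated groups
        tree = ward_cluster(matrix_from_array(X))
        last = tree.merges[-1]
        assert last[3] == 6
        fc = flat_clusters(tree, height_cutoff=50.0)
        assert len(set(fc.iloc[:3])) == 1 and len(set(fc.iloc[3:])) == 1
        assert fc.iloc[0] != fc.iloc[3]

    def test_missing_values_rejected(self):
        df = pd.DataFrame([[0.0, np.nan], [1.0, 2.0]], index=["a", "b"])
        cm = ConditionMatrix(values=df, complete_case=False, stops_excluded=False)
        with pytest.raises(ValueError, match="complete_case"):
            ward_cluster(cm)


class TestFlatClusters:
    def test_cutoff_below_first_merge_gives_singletons(self):
        X = np.arange(8.0).reshape(4, 2)
        tree = ward_cluster(matrix_from_array(X))
        fc = flat_clusters(tree, height_cutoff=1e-9)
        assert fc.nunique() == 4

    def test_cutoff_above_last_merge_gives_one_cluster(self):
        X = np.arange(8.0).reshape(4, 2)
        tree = ward_cluster(matrix_from_array(X))
        fc = flat_clusters(tree, tree.merges[-1, 2] + 1)
        assert fc.nunique() == 1


def test_newick_export_parses_and_preserves_leaves():
    from io import StringIO

    from Bio import Phylo

    X = np.random.default_rng(2).normal(size=(5, 3))
    tree = ward_cluster(matrix_from_array(X, conditions=list("abcde")))
    nwk = tree_to_newick(tree)
    parsed = Phylo.read(StringIO(nwk), "newick")
    assert sorted(t.name for t in parsed.get_terminals()) == list("abcde")


# ---------------------------------------------------------------- pca

def pca_eigendecomposition_oracle(X):
    """Covariance eigendecomposition, eigenvalues descending."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (len(X) - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestPCA:
    @pytest.mark.parametrize("shape", [(4, 3), (8, 12), (5, 7)])
    def test_matches_eigendecomposition_oracle(self, shape):
        rng = np.random.default_rng(shape[0] * 100 + shape[1])
        X = rng.normal(size=shape)
        result = pca_difference(matrix_from_array(X))
        evals, evecs = pca_eigendecomposition_oracle(X)
        k = result.n_components
        explained = result.explained_variance_ratio * evals.sum()
        assert np.allclose(explained, evals[:k], atol=1e-8)
        # directions in the null space (zero eigenvalue) are arbitrary;
        # compare only components carrying variance
        k = int((evals[:k] > 1e-10).sum())
        for j in range(k):
            got = result.loadings.iloc[:, j].to_numpy()
            want = evecs[:, j]
            # equality up to sign
            assert np.allclose(got, want, atol=1e-8) or np.allclose(
                got, -want, atol=1e-8
            )

    def test_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 10))
        result = pca_difference(matrix_from_array(X))
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T + result.mean.to_numpy()
        assert np.allclose(recon, X, atol=1e-8)

    def test_rank1_data_gives_pc1_ratio_one(self):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        coeffs = np.array([[1.0], [2.0], [4.0]])
        X = coeffs @ v[None, :]
        result = pca_difference(matrix_from_array(X))
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_variance_sums_to_one(self):
        X = np.random.default_rng(4).normal(size=(7, 5))
        result = pca_difference(matrix_from_array(X))
        evr = result.explained_variance_ratio
        assert evr.sum() == pytest.approx(1.0)
        assert (evr >= 0).all() and (np.diff(evr) <= 1e-12).all()

    def test_sign_convention(self):
        X = np.random.default_rng(5).normal(size=(6, 9))
        result = pca_difference(matrix_from_array(X))
        for col in result.loadings.columns:
            loads = result.loadings[col]
            assert loads.iloc[np.argmax(np.abs(loads.to_numpy()))] > 0

    def test_fewer_than_two_rows_errors(self):
        with pytest.raises(ValueError):
            pca_difference(matrix_from_array(np.zeros((1, 3))))


class TestLoadingSummaries:
    def make_result(self, loadings_pc1):
        X = np.random.default_rng(6).normal(size=(5, len(loadings_pc1)))
        result = pca_difference(matrix_from_array(X))
        result.loadings["PC1"] = loadings_pc1
        return result

    def test_percent_of_max(self):
        result = self.make_result([0.5, -0.25, 0.1])
        pct = loading_percent_of_max(result, 1)
        assert np.allclose(pct.to_numpy(), [100.0, -50.0, 20.0])
        assert pct.abs().max() == 100.0

    def test_all_zero_loadings_error(self):
        result = self.make_result([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            loading_percent_of_max(result, 1)

    def test_position_mean_loading(self):
        X = np.random.default_rng(7).normal(size=(4, 4))
        cm = matrix_from_array(X, mutants=["A2G", "A2W", "C3G", "C3W"])
        result = pca_difference(cm)
        result.loadings["PC1"] = [0.2, 0.4, -0.1, -0.1]
        means = position_mean_loading(result, 1)
        assert means[2] == pytest.approx(0.3)
        assert means[3] == pytest.approx(-0.1)

    def test_position_mean_residue_permutation_invariant(self):
        X = np.random.default_rng(8).normal(size=(4, 3))
        cm = matrix_from_array(X, mutants=["A2G", "A2W", "A2Y"])
        result = pca_difference(cm)
        result.loadings["PC1"] = [0.1, 0.2, 0.3]
        m1 = position_mean_loading(result, 1)
        result.loadings["PC1"] = [0.3, 0.1, 0.2]
        m2 = position_mean_loading(result, 1)
        assert m1[2] == pytest.approx(m2[2])

    def test_invalid_component_errors(self):
        result = self.make_result([0.1, 0.2, 0.3])
        with pytest.raises(IndexError):
            loading_percent_of_max(result, 99)
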