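"""Parallel analysis, principal-axis factoring with varimax, temporal
group assignment, and hierarchical clustering order."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from statsmodels.multivariate.factor_rotation import rotate_factors

from ontodyn.factor_clustering import (
    ConvergenceError,
    assign_temporal_groups,
    fit_factor_model,
    hier_cluster_order,
    horn_parallel_analysis,
    standardize_series,
)
from ontodyn.synthetic_data import simulate_expression


class TestHorn:
    def test_pure_noise_selects_zero_factors(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=(300, 12))
            k, _, _ = horn_parallel_analysis(x, n_sim=100, seed=seed)
            hits += k == 0
        assert hits >= 19

    def test_rank_one_structure_selects_one(self):
        rng = np.random.default_rng(0)
        profile = np.sin(np.linspace(0, np.pi, 12))
        x = rng.uniform(1, 3, (300, 1)) * profile + rng.normal(
            0, 0.3, (300, 12))
        k, _, _ = horn_parallel_analysis(x, n_sim=100, seed=0)
        assert k == 1

    def test_six_archetype_fixture_selects_three(self, six_archetype_matrix):
        matrix, _ = six_archetype_matrix
        std = standardize_series(matrix.log2_age_means())
        k, _, _ = horn_parallel_analysis(std, n_sim=200, seed=0)
        assert k == 3

    def test_parameter_validation(self):
        x = np.random.default_rng(0).normal(size=(50, 12))
        with pytest.raises(ValueError):
            horn_parallel_analysis(x, n_sim=50)
        with pytest.raises(ValueError):
            horn_parallel_analysis(x, quantile=0.4)
        with pytest.raises(ValueError):
            horn_parallel_analysis(x[:, :2])


class TestFitFactorModel:
    def test_exact_recovery_zero_noise(self, archetypes):
        rng = np.random.default_rng(3)
        mixing = rng.normal(size=(600, 3))
        x = mixing @ archetypes.bases
        xs = standardize_series(x)
        model = fit_factor_model(xs, 3, ages=archetypes.ages)
        # in the correlation metric, the loading span equals the span of
        # the generating profiles scaled by the per-age SDs
        target = (archetypes.bases / xs.std(axis=0, ddof=1)).T
        qa, _ = np.linalg.qr(model.loadings)
        qb, _ = np.linalg.qr(target)
        angles = np.arccos(np.clip(
            np.linalg.svd(qa.T @ qb, compute_uv=False), -1, 1))
        assert np.all(angles < 1e-6)

    def test_varimax_fixed_point(self, six_archetype_matrix):
        matrix, _ = six_archetype_matrix
        model = fit_factor_model(matrix, 3)
        again, _ = rotate_factors(model.loadings.copy(), "varimax")
        # unchanged up to column permutation and sign
        c = np.abs(model.loadings.T @ again)
        norms = np.linalg.norm(model.loadings, axis=0)
        best = c.max(axis=1)
        np.testing.assert_allclose(best, norms ** 2, rtol=1e-6)

    def test_communalities_invariant_under_rotation(self,
                                                    six_archetype_matrix):
        matrix, _ = six_archetype_matrix
        model = fit_factor_model(matrix, 3)
        rotated_comm = (model.loadings ** 2).sum(axis=1)
        np.testing.assert_allclose(rotated_comm, model.communalities,
                                   atol=1e-9)

    def test_nonconvergence_reports_iterations(self, six_archetype_matrix):
        matrix, _ = six_archetype_matrix
        with pytest.raises(ConvergenceError, match="2 iterations"):
            fit_factor_model(matrix, 3, maxiter=2, tol=1e-12)

    def test_k_bounds(self, six_archetype_matrix):
        matrix, _ = six_archetype_matrix
        with pytest.raises(ValueError):
            fit_factor_model(matrix, 12)


@pytest.fixture(scope="module")
def fitted(six_archetype_matrix):
    matrix, truth = six_archetype_matrix
    model = fit_factor_model(matrix, 3)
    return matrix, truth, model


class TestAssignment:

    def test_gene_equal_to_loading_assigned_positively(self, fitted):
        matrix, _, model = fitted
        series = model.loadings[:, 0][None, :]
        out = assign_temporal_groups(series, model, feature_ids=["probe"])
        row = out.table.iloc[0]
        assert row["assigned"] and row["sign"] == 1
        assert row["r"] == pytest.approx(1.0)

    def test_negated_loading_gets_negative_sign(self, fitted):
        matrix, _, model = fitted
        series = -model.loadings[:, 1][None, :]
        out = assign_temporal_groups(series, model, feature_ids=["probe"])
        assert out.table.iloc[0]["sign"] == -1

    def test_sub_threshold_correlation_unassigned(self, fitted):
        matrix, _, model = fitted
        z = standardize_series(model.loadings.T)
        rng = np.random.default_rng(8)
        w = rng.normal(size=12)
        basis = np.vstack([np.ones(12), z])
        w -= np.linalg.lstsq(basis.T, w, rcond=None)[0] @ basis
        w /= w.std(ddof=1)
        probe = 0.65 * z[0] + np.sqrt(1 - 0.65 ** 2) * w
        out = assign_temporal_groups(probe[None, :], model,
                                     feature_ids=["probe"])
        row = out.table.iloc[0]
        assert abs(row["r"]) == pytest.approx(0.65, abs=1e-9)
        assert not row["assigned"] and row["label"] == "unassigned"

    def test_zero_variance_series_flagged(self, fitted):
        _, _, model = fitted
        out = assign_temporal_groups(np.ones((1, 12)), model,
                                     feature_ids=["flat"])
        row = out.table.iloc[0]
        assert row["zero_variance"] and not row["assigned"]

    def test_label_recovery_on_archetype_fixture(self, fitted):
        matrix, truth, model = fitted
        out = assign_temporal_groups(matrix, model)
        correct = sum(
            out.table.loc[g, "label"] == truth.gene_labels[g]
            for g in matrix.feature_ids)
        assert correct / matrix.n_features >= 0.9

    def test_null_genes_mostly_unassigned(self, design):
        mix = {"null": 0.5, "Prenatal and Neonatal": 0.1,
               "Adolescent and Adult": 0.1, "Neonatal and Adolescent": 0.1,
               "Prenatal and Adult": 0.1, "Adult": 0.05, "Neonatal": 0.05}
        matrix, truth = simulate_expression(400, mix=mix, noise_sd=0.3,
                                            design=design, seed=21)
        model = fit_factor_model(matrix, 3)
        out = assign_temporal_groups(matrix, model)
        nulls = [g for g, lab in truth.gene_labels.items() if lab == "null"]
        unassigned = sum(out.table.loc[g, "label"] == "unassigned"
                         for g in nulls)
        assert unassigned / len(nulls) >= 0.8

    def test_invariant_to_affine_rescaling(self, fitted):
        matrix, _, model = fitted
        log2 = matrix.log2_age_means()[:30]
        base = assign_temporal_groups(standardize_series(log2), model)
        scaled = assign_temporal_groups(
            standardize_series(3.7 * log2 + 11.0), model)
        assert (base.table["label"] == scaled.table["label"]).all()


# ---------------------------------------------------------------------------
# brute-force agglomeration oracle

def naive_agglomeration(rows, metric, method):
    """Exhaustive nearest-pair agglomeration; returns merges as
    (leafset_a, leafset_b, height) in merge order."""
    n = len(rows)
    D = squareform(pdist(rows, metric=metric))
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        h, a, b = min((dist[tuple(sorted((a, b)))], a, b)
                      for i, a in enumerate(active) for b in active[i + 1:])
        merges.append((clusters[a], clusters[b], h))
        new = next_id
        next_id += 1
        clusters[new] = clusters[a] | clusters[b]
        sizes[new] = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            da = dist[tuple(sorted((a, c)))]
            db = dist[tuple(sorted((b, c)))]
            if method == "average":
                d = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            else:  # ward via Lance-Williams
                s = sizes[a] + sizes[b] + sizes[c]
                d = np.sqrt((sizes[a] + sizes[c]) / s * da ** 2
                            + (sizes[b] + sizes[c]) / s * db ** 2
                            - sizes[c] / s * h ** 2)
            dist[tuple(sorted((new, c)))] = d
        active = [c for c in active if c not in (a, b)] + [new]
    return merges


class TestHierClusterOrder:
    def test_identical_rows_merge_at_zero(self):
        rows = np.vstack([np.arange(5.0), np.arange(5.0),
                          np.arange(5.0) + 10])
        _, z = hier_cluster_order(rows, "euclidean", "average")
        assert z[0, 2] == 0.0
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_line_points_merge_closest_first(self):
        rows = np.array([[0.0], [1.0], [10.0]])
        _, z = hier_cluster_order(rows, "euclidean", "average")
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_ward_with_correlation_rejected(self):
        rows = np.random.default_rng(0).normal(size=(4, 6))
        with pytest.raises(ValueError, match="euclidean"):
            hier_cluster_order(rows, "correlation", "ward")

    @pytest.mark.parametrize("metric,method", [
        ("euclidean", "ward"), ("euclidean", "average"),
        ("correlation", "average"),
    ])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_merge_tree_matches_bruteforce(self, metric, method, seed):
        rows = np.random.default_rng(seed).normal(size=(6, 8))
        order, z = hier_cluster_order(rows, metric, method)
        merges = naive_agglomeration(rows, metric, method)
        sets = {i: frozenset([i]) for i in range(6)}
        for step, (a, b, h) in enumerate(merges):
            za, zb = int(z[step, 0]), int(z[step, 1])
            sets[6 + step] = sets[za] | sets[zb]
            assert {sets[za], sets[zb]} == {a, b}
            assert z[step, 2] == pytest.approx(h, abs=1e-10)
        # leaf order is consistent with the tree: each merged cluster
        # occupies a contiguous block of the leaf ordering
        pos = {leaf: i for i, leaf in enumerate(order)}
        for a, b, _ in merges:
            block = sorted(pos[leaf] for leaf in (a | b))
            assert block == list(range(block[0], block[0] + len(block)))
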