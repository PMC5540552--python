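"""Network construction: correlation, soft threshold, TOM, UPGMA, tree cut,
eigengenes, and module merging."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from immunomap import (average_linkage, compute_eigengene, detect_modules,
                       extract_modules, merge_modules, select_power,
                       spearman_correlation, tom_similarity)
from immunomap.network import BACKGROUND, _module_set, scale_free_fit
from immunomap.simulate import SimulationConfig, generate_cohorts


def _frame(X, prefix="p"):
    return pd.DataFrame(X, index=[f"{prefix}{i}" for i in range(len(X))])


class TestSpearman:
    def test_self_and_monotone_pairs(self, rng):
        X = rng.normal(size=(4, 20))
        X[1] = -np.exp(X[0])  # monotone decreasing transform of probe 0
        cor = spearman_correlation(_frame(X))
        assert cor.iloc[0, 0] == 1.0
        assert cor.iloc[0, 1] == pytest.approx(-1.0)
        np.testing.assert_allclose(cor.to_numpy(), cor.to_numpy().T)

    def test_five_sample_rank_formula_oracle(self):
        # 1 - 6 sum(d^2) / (n(n^2-1)) for untied ranks
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        d2 = ((x - y) ** 2).sum()  # (1, 1, 1, 1, 0)
        oracle = 1 - 6 * d2 / (5 * 24)
        from scipy.stats import spearmanr
        assert oracle == pytest.approx(spearmanr(x, y).statistic)
        cor = spearman_correlation(_frame(np.vstack([x, y])))
        assert cor.iloc[0, 1] == pytest.approx(oracle) == pytest.approx(0.8)

    def test_constant_probe_dropped(self, rng):
        X = rng.normal(size=(3, 10))
        X[2] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            cor = spearman_correlation(_frame(X))
        assert cor.shape == (2, 2)

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="3 samples"):
            spearman_correlation(_frame(rng.normal(size=(4, 2))))


class TestTOM:
    def test_zero_offdiagonal(self):
        A = np.eye(5)
        tom = tom_similarity(A)
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_fully_connected_triangle(self):
        A = np.ones((3, 3))
        tom = tom_similarity(A)
        # l = 1, a = 1, k = 2: (1+1)/(2+1-1) = 1
        assert np.allclose(tom, 1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            M = rng.uniform(size=(6, 6))
            A = (M + M.T) / 2
            np.fill_diagonal(A, 1.0)
            tom = tom_similarity(A)
            n = 6
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                    k_i = sum(A[i, u] for u in range(n) if u != i)
                    k_j = sum(A[j, u] for u in range(n) if u != j)
                    expected = (l + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
                    assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_rejected(self, rng):
        A = rng.uniform(size=(4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(A)


class TestUPGMA:
    def test_two_items(self):
        D = np.array([[0.0, 0.3], [0.3, 0.0]])
        Z = average_linkage(D)
        assert Z.shape == (1, 4) and Z[0, 2] == pytest.approx(0.3)

    def test_three_items_hand_case(self):
        D = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        Z = average_linkage(D)
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.5)  # average of 0.5 and 0.5

    def test_matches_independent_upgma_oracle(self, rng):
        """Brute-force UPGMA written here, independent of scipy."""
        n = 10
        M = rng.uniform(0.1, 1.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)

        # oracle: naive agglomeration with explicit cluster averaging
        clusters = {i: [i] for i in range(n)}
        dist = {frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
        heights = []
        next_id = n
        while len(clusters) > 1:
            pair = min(dist, key=lambda k: dist[k])
            h = dist[pair]
            heights.append(h)
            a, b = tuple(pair)
            merged = clusters.pop(a) + clusters.pop(b)
            for c in list(clusters):
                d_new = np.mean([D[x, y] for x in merged for y in clusters[c]])
                dist[frozenset((next_id, c))] = d_new
            dist = {k: v for k, v in dist.items() if a not in k and b not in k}
            clusters[next_id] = merged
            next_id += 1

        Z = average_linkage(D)
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(heights), atol=1e-12)

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            average_linkage(D)

    def test_merge_heights_nondecreasing(self, rng):
        M = rng.uniform(size=(15, 15))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        Z = average_linkage(D)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)


class TestExtractModules:
    def test_two_planted_blocks_recovered(self):
        cfg = SimulationConfig(n_cohort1=200, n_cohort2=20, n_followup=10,
                               n_genes=40, n_modules=2, module_sizes=[20, 20],
                               loading_mean=0.9, n_snps=10, n_metabolites=10,
                               n_assoc_metabolites_per_module=0, n_cis_eqtl=0,
                               mqtl_effect=0.0, seed=21)
        c1, _, _, truth = generate_cohorts(cfg)
        cor = spearman_correlation(c1.expression)
        tom = tom_similarity(np.abs(cor.to_numpy()) ** 5)
        Z = average_linkage(1 - tom)
        assignment = extract_modules(Z, cor.index, min_module_size=10)
        found = set(assignment) - {BACKGROUND}
        assert len(found) == 2
        for m in found:
            planted = truth.module_membership[assignment.index[assignment == m]]
            assert planted.nunique() == 1 and planted.iloc[0] != BACKGROUND

    def test_small_cluster_is_background(self, rng):
        # 9-leaf tight cluster under min size 10 stays background
        n = 30
        D = np.full((n, n), 1.0)
        D[:9, :9] = 0.01
        np.fill_diagonal(D, 0.0)
        Z = average_linkage(D)
        leaves = pd.Index([f"p{i}" for i in range(n)])
        assignment = extract_modules(Z, leaves, min_module_size=10)
        assert (assignment == BACKGROUND).all()

    def test_min_module_size_validated(self, rng):
        Z = average_linkage(np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError, match="min_module_size"):
            extract_modules(Z, pd.Index(["a", "b"]), min_module_size=1)

    def test_pure_noise_yields_no_large_module(self, rng):
        X = rng.normal(size=(150, 60))
        cor = spearman_correlation(_frame(X))
        tom = tom_similarity(np.abs(cor.to_numpy()) ** 5)
        Z = average_linkage(1 - tom)
        assignment = extract_modules(Z, cor.index, min_module_size=10)
        sizes = assignment[assignment != BACKGROUND].value_counts()
        # no module should approach the full probe set under pure noise
        assert sizes.empty or sizes.max() < 75


class TestEigengene:
    def test_identical_probes(self, rng):
        x = rng.normal(size=30)
        X = np.vstack([x, x, x])
        eig, ve = compute_eigengene(_frame(X), [f"p{i}" for i in range(3)])
        assert ve == pytest.approx(1.0)
        assert abs(np.corrcoef(eig, x)[0, 1]) == pytest.approx(1.0)

    def test_two_probe_variance_explained(self, rng):
        f = rng.normal(size=500)
        x = f + 0.6 * rng.normal(size=500)
        y = f + 0.6 * rng.normal(size=500)
        r = np.corrcoef(x, y)[0, 1]
        _, ve = compute_eigengene(_frame(np.vstack([x, y])), ["p0", "p1"])
        assert ve == pytest.approx((1 + abs(r)) / 2, abs=1e-10)

    def test_sign_convention_and_invariances(self, rng):
        X = rng.normal(size=(8, 50)) + rng.normal(size=50) * 0.8
        probes = [f"p{i}" for i in range(8)]
        frame = _frame(X)
        eig, ve = compute_eigengene(frame, probes)
        kme = [np.corrcoef(frame.loc[p], eig)[0, 1] for p in probes]
        assert np.mean(kme) >= 0
        # probe reordering
        eig2, ve2 = compute_eigengene(frame, probes[::-1])
        np.testing.assert_allclose(eig2, eig, atol=1e-8)
        assert ve2 == pytest.approx(ve)
        # sign flip of individual probes changes nothing up to the convention
        flipped = frame.copy()
        flipped.loc["p0"] *= -1
        eig3, ve3 = compute_eigengene(flipped, probes)
        assert ve3 == pytest.approx(ve)
        assert abs(np.corrcoef(eig3, eig)[0, 1]) == pytest.approx(1.0)

    def test_unit_variance(self, rng):
        X = rng.normal(size=(5, 40))
        eig, _ = compute_eigengene(_frame(X), [f"p{i}" for i in range(5)])
        assert eig.std(ddof=1) == pytest.approx(1.0)


class TestMergeModules:
    def _dataset(self, rng, r_between):
        f1 = rng.normal(size=300)
        f2 = r_between * f1 + np.sqrt(1 - r_between ** 2) * rng.normal(size=300)
        rows, labels = [], []
        for i in range(12):
            src = f1 if i < 6 else f2
            rows.append(src + 0.1 * rng.normal(size=300))
            labels.append("M1" if i < 6 else "M2")
        frame = _frame(np.array(rows))
        assignment = pd.Series(labels, index=frame.index)
        return frame, assignment

    def test_highly_correlated_eigengenes_merged(self, rng):
        frame, assignment = self._dataset(rng, 0.97)
        ms = merge_modules(_module_set(frame, assignment), frame, merge_height=0.2)
        assert len(ms.modules) == 1

    def test_distinct_eigengenes_not_merged(self, rng):
        frame, assignment = self._dataset(rng, 0.5)
        ms = merge_modules(_module_set(frame, assignment), frame, merge_height=0.2)
        assert len(ms.modules) == 2

    def test_single_module_unchanged(self, rng):
        frame, assignment = self._dataset(rng, 0.5)
        assignment[:] = "M1"
        ms = merge_modules(_module_set(frame, assignment), frame, merge_height=0.2)
        assert len(ms.modules) == 1
        assert (ms.assignment == "M1").all()


class TestScaleFree:
    def test_override(self, small_cohorts):
        c1 = small_cohorts[0]
        cor = spearman_correlation(c1.expression.iloc[:80])
        assert select_power(cor, override=5)[0] == 5
        assert select_power(cor, override=4)[0] == 4

    def test_selected_power_fit_has_negative_slope(self, small_cohorts):
        c1 = small_cohorts[0]
        cor = spearman_correlation(c1.expression.iloc[:120])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, r2 = select_power(cor)
        assert 1 <= beta <= 20
        # recompute the fit with an independent regression oracle
        C = cor.to_numpy()
        a = np.abs(C) ** beta
        k = a.sum(axis=1) - 1.0
        order = np.argsort(k)
        xs, ys = [], []
        for b in np.array_split(order, 10):
            kb = k[b]
            width = max(kb.max() - kb.min(), 1e-12)
            xs.append(np.log10(kb.mean()))
            ys.append(np.log10(len(b) / (width * len(k))))
        slope = np.polyfit(xs, ys, 1)[0]
        r2_oracle, slope_oracle = scale_free_fit(C, beta)
        assert slope == pytest.approx(slope_oracle, abs=1e-8)
        assert slope_oracle < 0

    def test_adjacency_monotone_in_beta(self, rng):
        C = np.corrcoef(rng.normal(size=(10, 40)))
        a3 = np.abs(C) ** 3
        a5 = np.abs(C) ** 5
        off = ~np.eye(10, dtype=bool)
        assert np.all(a5[off] <= a3[off] + 1e-15)


def test_detect_modules_recovers_planted_assignment(small_cohorts, small_config):
    from sklearn.metrics import adjusted_rand_score

    from immunomap import residualize
    c1, _, _, truth = small_cohorts
    adj = residualize(c1.expression.T, c1.covariates[["age", "sex"]]).T
    _, ms = detect_modules(adj, beta=5)
    ari = adjusted_rand_score(truth.module_membership,
                              ms.assignment.reindex(truth.module_membership.index,
                                                    fill_value=BACKGROUND))
    assert ari > 0.8
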