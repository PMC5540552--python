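"""LD pruning, genetic PCs, dosage association scans, weighted-Z
meta-analysis, cis/trans classification, and permutation cis tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunomap import (SimulationConfig, cis_eqtl_permutation, classify_locus,
                       conditional_scan, generate_cohorts, genetic_pcs,
                       ld_prune, mqtl_scan, trans_eqtl, weighted_z_meta)


def _dosages(rng, n, mafs):
    D = rng.binomial(1, mafs, (n, len(mafs))) + rng.binomial(1, mafs, (n, len(mafs)))
    return pd.DataFrame(D.astype(float), index=[f"s{i}" for i in range(n)],
                        columns=[f"snp{j}" for j in range(len(mafs))])


def _positions(snps, chrom="chr1", spacing=10_000):
    return pd.DataFrame({"chrom": chrom,
                         "pos": 1_000_000 + spacing * np.arange(len(snps))},
                        index=snps)


class TestLDPrune:
    def test_perfect_ld_pair_reduced(self, rng):
        d = _dosages(rng, 200, [0.3, 0.2])
        d["snp1"] = d["snp0"]
        kept = ld_prune(d, _positions(d.columns))
        assert len(kept) == 1

    def test_independent_snps_identity(self, rng):
        d = _dosages(rng, 500, [0.3, 0.4, 0.2, 0.45])
        kept = ld_prune(d, _positions(d.columns))
        assert set(kept) == set(d.columns)

    def test_generator_ld_block_collapsed(self, small_cohorts):
        c1 = small_cohorts[0]
        kept = ld_prune(c1.genotypes, c1.snp_positions)
        D = c1.genotypes[kept].to_numpy()
        R2 = np.corrcoef(D.T) ** 2
        np.fill_diagonal(R2, 0)
        assert R2.max() <= 0.2 + 0.1  # block reduced to ~one representative

    def test_monomorphic_excluded_with_warning(self, rng):
        d = _dosages(rng, 100, [0.3, 0.4])
        d["snp0"] = 0.0
        with pytest.warns(UserWarning, match="monomorphic"):
            kept = ld_prune(d, _positions(d.columns))
        assert list(kept) == ["snp1"]


class TestGeneticPCs:
    def test_orthogonal_ordered_scores(self, rng):
        d = _dosages(rng, 80, rng.uniform(0.1, 0.5, 30))
        pcs = genetic_pcs(d)
        G = pcs.to_numpy()
        gram = G.T @ G
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert np.all(np.diff(np.diag(gram)) <= 1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        d = _dosages(rng, 60, rng.uniform(0.1, 0.5, 20))
        Z = (d - d.mean()) / d.std(ddof=0)
        C = np.cov(Z.to_numpy().T, ddof=0)
        vals, vecs = np.linalg.eigh(C)
        scores_oracle = Z.to_numpy() @ vecs[:, ::-1][:, :10]
        pcs = genetic_pcs(d).to_numpy()
        for j in range(10):
            r = np.corrcoef(pcs[:, j], scores_oracle[:, j])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_duplicate_samples_get_identical_rows(self, rng):
        d = _dosages(rng, 40, rng.uniform(0.2, 0.5, 15))
        d.iloc[1] = d.iloc[0]
        pcs = genetic_pcs(d)
        np.testing.assert_allclose(pcs.iloc[0], pcs.iloc[1], atol=1e-10)

    def test_too_few_samples(self, rng):
        d = _dosages(rng, 5, rng.uniform(0.2, 0.5, 15))
        with pytest.raises(ValueError, match="samples"):
            genetic_pcs(d)


class TestMqtlScan:
    def test_matches_full_ols_oracle(self, rng):
        n = 150
        d = _dosages(rng, n, rng.uniform(0.2, 0.5, 5))
        cov = pd.DataFrame({"age": rng.uniform(25, 74, n)}, index=d.index)
        y = pd.Series(rng.normal(size=n), index=d.index)
        res = mqtl_scan(y, d, cov)
        import statsmodels.api as sm
        for snp in d.columns:
            X = sm.add_constant(np.column_stack([d[snp], cov["age"]]))
            fit = sm.OLS(y.to_numpy(), X).fit()
            assert res.loc[snp, "beta"] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.loc[snp, "p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_zero_variance_snp_skipped(self, rng):
        d = _dosages(rng, 50, [0.4, 0.3])
        d["snp0"] = 1.0
        y = pd.Series(rng.normal(size=50), index=d.index)
        res = mqtl_scan(y, d)
        assert "snp0" not in res.index and "snp1" in res.index

    def test_null_pvalues_uniform(self, rng):
        d = _dosages(rng, 120, rng.uniform(0.1, 0.5, 200))
        y = pd.Series(rng.normal(size=120), index=d.index)
        res = mqtl_scan(y, d)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01


class TestWeightedZ:
    def test_published_platelet_mqtl_meta(self):
        _, p = weighted_z_meta([(7.11e-14, -1, 518), (1.51e-16, -1, 1400)])
        assert abs(np.log10(p) - np.log10(7.35e-28)) < 0.15

    def test_single_study_identity(self):
        _, p = weighted_z_meta([(0.02, 1, 300)])
        assert p == pytest.approx(0.02)

    def test_closed_form_equal_studies(self):
        z, p = weighted_z_meta([(0.05, 1, 100), (0.05, 1, 100)])
        z_single = stats.norm.isf(0.025)
        assert z == pytest.approx(z_single * np.sqrt(2), abs=1e-4)
        assert p == pytest.approx(5.57e-3, rel=1e-2)

    def test_p_zero_rejected(self):
        with pytest.raises(ValueError, match="underlying"):
            weighted_z_meta([(0.0, 1, 100)])


class TestClassifyLocus:
    def test_inside_interval_is_cis(self):
        assert classify_locus("chr1", 500, "chr1", 100, 900) == "cis"

    def test_different_chromosome_is_trans(self):
        assert classify_locus("chr2", 500, "chr1", 100, 900) == "trans"

    def test_gap_zone_is_neither(self):
        assert classify_locus("chr1", 4_000_000, "chr1", 100, 900) == "neither"

    def test_boundaries(self):
        assert classify_locus("chr1", 1_001_000, "chr1", 1_000, 2_000) == "cis"
        assert classify_locus("chr1", 7_000_000, "chr1", 1_000, 2_000) == "trans"

    def test_unknown_chromosome(self):
        with pytest.raises(ValueError, match="chromosome"):
            classify_locus("", 1, "chr1", 1, 2)


@pytest.fixture(scope="module")
def qtl_cohorts():
    cfg = SimulationConfig(n_cohort1=250, n_cohort2=500, n_followup=50,
                           n_genes=80, n_modules=1, module_sizes=[30],
                           loading_mean=0.8, mqtl_effect=0.5, cis_effect=0.8,
                           maf_range=(0.3, 0.5), n_snps=40, n_metabolites=10,
                           n_assoc_metabolites_per_module=2, seed=13)
    return generate_cohorts(cfg)


def _cohort_dict(c, pcs=None):
    return {"expression": c.expression, "dosages": c.genotypes,
            "covariates": c.covariates[["age", "sex"]], "pcs": pcs,
            "probe_positions": c.probe_positions, "snp_positions": c.snp_positions}


class TestEqtl:
    def test_planted_mqtl_detected_in_meta(self, qtl_cohorts):
        c1, c2, _, truth = qtl_cohorts
        snp = truth.mqtl_effects["snp"].iloc[0]
        from immunomap import compute_eigengene, weighted_z_meta
        members = truth.module_membership.index[truth.module_membership == "M1"]
        studies = []
        for c in (c1, c2):
            eig, _ = compute_eigengene(c.expression, members)
            res = mqtl_scan(eig, c.genotypes[[snp]], c.covariates[["age", "sex"]])
            studies.append((res.loc[snp, "p"], 1 if res.loc[snp, "beta"] >= 0 else -1,
                            res.loc[snp, "n"]))
        _, p_meta = weighted_z_meta(studies)
        assert p_meta < 5e-8

    def test_trans_eqtl_flags_module_probes(self, qtl_cohorts):
        c1, c2, _, truth = qtl_cohorts
        snp = truth.mqtl_effects["snp"].iloc[0]
        members = truth.module_membership.index[truth.module_membership == "M1"]
        out = trans_eqtl(snp, members, [_cohort_dict(c1), _cohort_dict(c2)])
        assert out["significant"].mean() > 0.5  # majority of module probes

    def test_cis_pair_saturates_permutations(self, qtl_cohorts):
        c1, c2, _, truth = qtl_cohorts
        row = truth.cis_effects.iloc[0]
        p = cis_eqtl_permutation(row["snp"], row["probe"],
                                 [_cohort_dict(c1), _cohort_dict(c2)],
                                 n_perm=200, seed=5)
        assert p == pytest.approx(1 / 201)

    def test_null_cis_pair_not_significant(self, qtl_cohorts):
        c1, c2, _, truth = qtl_cohorts
        null_snp = c1.genotypes.columns[-1]
        probe = c1.expression.index[-1]
        p = cis_eqtl_permutation(null_snp, probe,
                                 [_cohort_dict(c1), _cohort_dict(c2)],
                                 n_perm=99, seed=5)
        assert p > 0.05

    def test_conditioning_on_factor_abolishes_mqtl(self, qtl_cohorts):
        c1, _, _, truth = qtl_cohorts
        snp = truth.mqtl_effects["snp"].iloc[0]
        f = truth.factor_values["C1"]["M1"]
        from immunomap import compute_eigengene
        members = truth.module_membership.index[truth.module_membership == "M1"]
        eig, _ = compute_eigengene(c1.expression, members)
        base = mqtl_scan(eig, c1.genotypes[[snp]], c1.covariates[["age", "sex"]])
        cond = conditional_scan(eig, c1.genotypes[[snp]],
                                c1.covariates[["age", "sex"]], None,
                                pd.DataFrame({"factor": f}))
        assert base.loc[snp, "p"] < 1e-6
        assert cond.loc[snp, "p"] > 1e-3

    def test_conditioning_on_independent_variable_maintains(self, qtl_cohorts, rng):
        c1, _, _, truth = qtl_cohorts
        snp = truth.mqtl_effects["snp"].iloc[0]
        from immunomap import compute_eigengene
        members = truth.module_membership.index[truth.module_membership == "M1"]
        eig, _ = compute_eigengene(c1.expression, members)
        noise = pd.DataFrame({"x": rng.normal(size=len(eig))}, index=eig.index)
        base = mqtl_scan(eig, c1.genotypes[[snp]], c1.covariates[["age", "sex"]])
        cond = conditional_scan(eig, c1.genotypes[[snp]],
                                c1.covariates[["age", "sex"]], None, noise)
        assert np.log10(cond.loc[snp, "p"]) == pytest.approx(
            np.log10(base.loc[snp, "p"]), abs=1.0)
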