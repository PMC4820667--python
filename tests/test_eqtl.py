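"""eQTL engine: pair classing, PCs, vectorized OLS vs naive oracle, calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sepstrat.datatypes import ExpressionMatrix, GenotypeMatrix
from sepstrat.eqtl import (
    EqtlConfig,
    EqtlScan,
    classify_pairs,
    compare_contexts,
    compute_expression_pcs,
    lead_snp_per_probe,
    srs_specific_eqtl,
)
from sepstrat.simulate import SimConfig, plan_cohort, simulate_cohort


def ann_frames():
    snp = pd.DataFrame({
        "snp_id": ["s1", "s2", "s3", "s4"],
        "chrom": ["chr1", "chr1", "chr1", "chr2"],
        "pos": [1_500_000, 2_200_000, 5_000_000, 700_000],
        "maf": [0.3] * 4,
    })
    probe = pd.DataFrame({
        "probe_id": ["p1", "pX"],
        "chrom": ["chr1", "chrX"],
        "start": [999_999, 1_000_000],
    })
    return snp, probe


class TestClassifyPairs:
    def test_windows_and_gap_zone(self):
        snp, probe = ann_frames()
        pairs = pd.DataFrame({"snp_id": ["s1", "s2", "s3", "s4"],
                              "probe_id": ["p1"] * 4})
        out = classify_pairs(snp, probe, EqtlConfig(), pairs).set_index("snp_id")
        assert out.loc["s1", "klass"] == "cis"  # distance 500 001 < 1 Mb
        assert out.loc["s1", "distance"] == 500_001
        assert out.loc["s2", "klass"] == "excluded"  # 1.2 Mb gap zone
        assert out.loc["s3", "klass"] == "trans"  # 4.0 Mb > 2.5 Mb
        assert out.loc["s4", "klass"] == "trans"  # different autosomes

    def test_trans_restricted_to_autosomes(self):
        snp, probe = ann_frames()
        pairs = pd.DataFrame({"snp_id": ["s4"], "probe_id": ["pX"]})
        out = classify_pairs(snp, probe, EqtlConfig(), pairs)
        assert out["klass"].iloc[0] == "excluded"
        out2 = classify_pairs(snp, probe, EqtlConfig(trans_autosomes_only=False), pairs)
        assert out2["klass"].iloc[0] == "trans"

    def test_partition_is_exhaustive_and_exclusive(self, small_cohort):
        out = classify_pairs(small_cohort.genotypes.snp_annotation().head(50),
                             small_cohort.expression.probe_annotation().head(40))
        assert len(out) == 50 * 40
        assert set(out["klass"]) <= {"cis", "trans", "excluded"}


class TestExpressionPcs:
    def test_rank_one_structure_lands_on_pc1(self, rng):
        load = rng.normal(size=200)
        scores_true = rng.normal(size=50)
        values = np.outer(load, scores_true) + rng.normal(0, 0.01, (200, 50))
        pcs = compute_expression_pcs(values, 3)
        r = np.corrcoef(pcs[:, 0], scores_true)[0, 1]
        assert abs(r) > 0.999

    def test_scores_are_orthogonal(self, rng):
        pcs = compute_expression_pcs(rng.normal(size=(300, 60)), 10)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_global_confounder_captured_by_pc1(self, rng):
        conf = rng.normal(0, 2.0, 80)
        loadings = rng.normal(1.0, 0.2, 500)
        values = np.outer(loadings, conf) + rng.normal(0, 1.0, (500, 80))
        pcs = compute_expression_pcs(values, 1)
        r2 = np.corrcoef(pcs[:, 0], conf)[0, 1] ** 2
        assert r2 >= 0.9

    def test_n_pcs_beyond_rank_rejected(self, rng):
        with pytest.raises(ValueError, match="rank"):
            compute_expression_pcs(rng.normal(size=(30, 10)), 10)

    def test_deterministic_sign_convention(self, rng):
        values = rng.normal(size=(100, 40))
        a = compute_expression_pcs(values, 5)
        b = compute_expression_pcs(values.copy(), 5)
        np.testing.assert_allclose(a, b)


def tiny_scan(rng, n=80, n_snps=50, n_probes=20, n_covs=3):
    dos = rng.binomial(2, 0.3, (n_snps, n))
    dos[dos.std(axis=1) == 0, 0] = 1  # no monomorphic rows
    geno = GenotypeMatrix(
        dosages=dos.astype(np.int8),
        snp_ids=np.array([f"s{i:03d}" for i in range(n_snps)], dtype=object),
        snp_chrom=np.array(["chr1"] * n_snps, dtype=object),
        snp_pos=rng.integers(1, 10_000_000, n_snps),
        maf=np.full(n_snps, 0.3),
        sample_ids=np.array([f"S{i}" for i in range(n)], dtype=object),
    )
    expr = ExpressionMatrix(
        values=rng.normal(8, 1, (n_probes, n)),
        probe_ids=np.array([f"p{i:03d}" for i in range(n_probes)], dtype=object),
        probe_chrom=np.array(["chr1"] * n_probes, dtype=object),
        probe_start=rng.integers(1, 10_000_000, n_probes),
        sample_ids=geno.sample_ids,
    )
    covs = rng.normal(size=(n, n_covs))
    pairs = pd.MultiIndex.from_product(
        [geno.snp_ids, expr.probe_ids], names=["snp_id", "probe_id"]
    ).to_frame(index=False)
    pairs["klass"] = "cis"
    pairs["distance"] = 0
    return expr, geno, covs, pairs


class TestEngineOracle:
    def test_vectorized_engine_matches_per_pair_ols(self, rng):
        """Max |delta beta| and |delta p| vs a statsmodels per-pair loop < 1e-8."""
        import statsmodels.api as sm

        expr, geno, covs, pairs = tiny_scan(rng)
        res = EqtlScan(expr, geno, pairs, covs).fit().records
        res = res.set_index(["snp_id", "probe_id"])
        pidx = {p: i for i, p in enumerate(expr.probe_ids)}
        sidx = {s: i for i, s in enumerate(geno.snp_ids)}
        max_db = max_dp = 0.0
        for (sid, pid) in res.index[:400]:
            X = sm.add_constant(np.column_stack(
                [geno.dosages[sidx[sid]].astype(float), covs]))
            fit = sm.OLS(expr.values[pidx[pid]], X).fit()
            max_db = max(max_db, abs(fit.params[1] - res.loc[(sid, pid), "beta"]))
            max_dp = max(max_dp, abs(fit.pvalues[1] - res.loc[(sid, pid), "p"]))
        assert max_db < 1e-8
        assert max_dp < 1e-8

    def test_orthogonal_covariate_leaves_beta_unchanged(self, rng):
        expr, geno, covs, pairs = tiny_scan(rng, n_covs=2)
        base = EqtlScan(expr, geno, pairs, covs).fit().records["beta"].to_numpy()
        # a covariate orthogonal to every dosage and every expression residual
        extra = rng.normal(size=(expr.n_samples, 1))
        M = np.column_stack([np.ones(expr.n_samples), covs,
                             geno.dosages.T.astype(float), expr.values.T])
        Q, _ = np.linalg.qr(M)
        extra = extra - Q @ (Q.T @ extra)
        aug = np.column_stack([covs, extra])
        out = EqtlScan(expr, geno, pairs, aug).fit().records["beta"].to_numpy()
        np.testing.assert_allclose(out, base, atol=1e-10)

    def test_global_null_yields_no_fdr_calls(self, rng):
        clean = 0
        for rep in range(4):
            expr, geno, covs, pairs = tiny_scan(np.random.default_rng(rep),
                                                n=60, n_snps=100, n_probes=100)
            res = EqtlScan(expr, geno, pairs.iloc[:10_000], covs).fit()
            clean += (res.records["fdr"] < 0.05).sum() == 0
        assert clean >= 3


class TestLeadSnp:
    def test_single_record_identity(self):
        rec = pd.DataFrame({"snp_id": ["a"], "probe_id": ["p"], "p": [0.5],
                            "beta": [0.1]})
        out = lead_snp_per_probe(rec)
        assert len(out) == 1 and out["snp_id"].iloc[0] == "a"

    def test_tie_break_by_beta_then_id(self):
        rec = pd.DataFrame({
            "snp_id": ["b", "a", "c"],
            "probe_id": ["p"] * 3,
            "p": [0.01, 0.01, 0.01],
            "beta": [0.5, 0.5, 0.9],
        })
        out = lead_snp_per_probe(rec)
        assert out["snp_id"].iloc[0] == "c"  # largest |beta| wins
        rec["beta"] = 0.5
        assert lead_snp_per_probe(rec)["snp_id"].iloc[0] == "a"  # then id order

    def test_planted_strongest_snp_recovered(self, small_cohort):
        cfg = EqtlConfig()
        truth = small_cohort.truth
        classed = classify_pairs(small_cohort.genotypes.snp_annotation(),
                                 small_cohort.expression.probe_annotation(),
                                 cfg, truth.eqtl_pairs[["snp_id", "probe_id"]])
        pcs = compute_expression_pcs(small_cohort.expression.values, 30)
        res = EqtlScan(small_cohort.expression, small_cohort.genotypes,
                       classed, pcs, cfg).fit()
        lead = lead_snp_per_probe(res.records[res.records["klass"] == "cis"])
        planted = truth.eqtl_pairs.query("klass == 'cis'")
        merged = lead.merge(planted, on="probe_id", suffixes=("_lead", "_true"))
        agree = (merged["snp_id_lead"] == merged["snp_id_true"]).mean()
        assert agree >= 0.9


class TestSrsSpecific:
    def test_rule_arithmetic(self):
        recs = pd.DataFrame({
            "snp_id": ["a", "b", "c"],
            "probe_id": ["p1", "p2", "p3"],
            "fdr": [0.005, 0.005, 0.5],
        })
        other = recs.copy()
        other["fdr"] = [0.5, 0.04, 0.002]
        out = srs_specific_eqtl(recs, other).set_index("snp_id")
        assert out.loc["a", "call"] == "srs1_only"
        assert out.loc["b", "call"] == "shared"  # 0.005 and 0.04 both < 0.05
        assert out.loc["c", "call"] == "srs2_only"

    def test_identical_tables_have_no_specific_calls(self):
        recs = pd.DataFrame({"snp_id": list("abcd"), "probe_id": list("wxyz"),
                             "fdr": [0.001, 0.2, 0.03, 0.9]})
        out = srs_specific_eqtl(recs, recs.copy())
        assert not (out["call"] == "srs1_only").any()
        assert not (out["call"] == "srs2_only").any()

    def test_disjoint_universes_rejected(self):
        a = pd.DataFrame({"snp_id": ["a"], "probe_id": ["p"], "fdr": [0.1]})
        b = pd.DataFrame({"snp_id": ["z"], "probe_id": ["q"], "fdr": [0.1]})
        with pytest.raises(ValueError, match="disjoint"):
            srs_specific_eqtl(a, b)

    def test_planted_group_restricted_pairs_recovered(self):
        hits = trials = 0
        for seed in (31, 32, 33):
            cfg = SimConfig(seed=seed, n_samples=240, n_probes=1200, n_snps=600,
                            n_de_probes=100, n_cis_eqtl=60, n_trans_eqtl=0,
                            n_group_specific=20, beta_range=(1.0, 1.5),
                            group_fractions=(0.5, 0.5))
            cohort = simulate_cohort(cfg, with_marks=False)
            truth = cohort.truth
            labels = truth.group_of_sample
            classed = classify_pairs(cohort.genotypes.snp_annotation(),
                                     cohort.expression.probe_annotation(),
                                     EqtlConfig(),
                                     truth.eqtl_pairs[["snp_id", "probe_id"]])
            per_group = {}
            for g in ("SRS1", "SRS2"):
                m = (labels.loc[cohort.expression.sample_ids] == g).to_numpy()
                expr_g = ExpressionMatrix(cohort.expression.values[:, m],
                                          cohort.expression.probe_ids,
                                          cohort.expression.probe_chrom,
                                          cohort.expression.probe_start,
                                          cohort.expression.sample_ids[m])
                geno_g = GenotypeMatrix(cohort.genotypes.dosages[:, m],
                                        cohort.genotypes.snp_ids,
                                        cohort.genotypes.snp_chrom,
                                        cohort.genotypes.snp_pos,
                                        cohort.genotypes.maf,
                                        cohort.genotypes.sample_ids[m])
                pcs = compute_expression_pcs(expr_g.values, 25)
                per_group[g] = EqtlScan(expr_g, geno_g, classed, pcs).fit()
            calls = srs_specific_eqtl(per_group["SRS1"].records,
                                      per_group["SRS2"].records)
            calls = calls.set_index(["snp_id", "probe_id"])
            spec = truth.eqtl_pairs[truth.eqtl_pairs["group_restriction"] != "both"]
            for row in spec.itertuples(index=False):
                expected = "srs1_only" if row.group_restriction == "group1-only" \
                    else "srs2_only"
                trials += 1
                hits += calls.loc[(row.snp_id, row.probe_id), "call"] == expected
        assert hits / trials >= 0.8


class TestCompareContexts:
    def test_identical_scans_give_no_specific_genes(self):
        rec = pd.DataFrame({"snp_id": list("abc"), "probe_id": list("xyz"),
                            "fdr": [0.01, 0.2, 0.03],
                            "distance": [100.0, 200.0, 300.0],
                            "p": [0.001, 0.1, 0.002], "beta": [1, 1, 1]})
        tss = pd.Series([0, 0, 0], index=list("xyz"))
        out = compare_contexts(rec, rec.copy(), tss)
        assert out["context_specific"] == []

    def test_mann_whitney_exact_small_sample(self):
        u, p = stats.mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided",
                                  method="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_planted_distal_specific_eqtl_detected(self, rng):
        n = 40
        probes = [f"p{i}" for i in range(n)]
        shared = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(n)],
            "probe_id": probes,
            "fdr": [0.001] * n,
            "p": [1e-5] * n,
            "beta": [1.0] * n,
            "distance": np.r_[rng.integers(500, 5_000, n // 2),  # proximal
                              rng.integers(200_000, 900_000, n // 2)].astype(float),
        })
        reference = shared.copy()
        reference.loc[n // 2:, "fdr"] = 0.9  # distal half absent from reference
        tss = pd.Series(0, index=probes)
        out = compare_contexts(shared, reference, tss)
        assert set(out["context_specific"]) == set(probes[n // 2:])
        assert out["mannwhitney_p"] < 0.01
        assert out["median_dist_specific"] > out["median_dist_shared"]


def test_recovery_sensitivity_and_fdr_at_generator_defaults():
    """Planted cis effects recovered with sens >= 0.8 and empirical FDR <= 0.1."""
    sens_all, fdr_all = [], []
    for seed in (41, 42):
        cfg = SimConfig(seed=seed, n_samples=240, n_probes=2000, n_snps=1500,
                        n_de_probes=200, n_cis_eqtl=200, n_trans_eqtl=10,
                        n_group_specific=0)
        cohort = simulate_cohort(cfg, with_marks=False)
        rng = np.random.default_rng(seed)
        extra = pd.DataFrame({
            "snp_id": rng.choice(cohort.genotypes.snp_ids, 20_000),
            "probe_id": rng.choice(cohort.expression.probe_ids, 20_000),
        })
        pairs = pd.concat([cohort.truth.eqtl_pairs[["snp_id", "probe_id"]],
                           extra]).drop_duplicates()
        classed = classify_pairs(cohort.genotypes.snp_annotation(),
                                 cohort.expression.probe_annotation(),
                                 EqtlConfig(), pairs)
        pcs = compute_expression_pcs(cohort.expression.values, 30)
        res = EqtlScan(cohort.expression, cohort.genotypes, classed, pcs).fit()
        called = res.significant("cis")
        called_keys = set(zip(called["snp_id"], called["probe_id"]))
        planted = set(zip(cohort.truth.eqtl_pairs["snp_id"],
                          cohort.truth.eqtl_pairs["probe_id"]))
        planted_cis = set(
            zip(cohort.truth.eqtl_pairs.query("klass == 'cis'")["snp_id"],
                cohort.truth.eqtl_pairs.query("klass == 'cis'")["probe_id"]))
        sens_all.append(len(called_keys & planted_cis) / len(planted_cis))
        fdr_all.append(len(called_keys - planted) / max(len(called_keys), 1))
    assert np.mean(sens_all) >= 0.8
    assert np.mean(fdr_all) <= 0.1
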