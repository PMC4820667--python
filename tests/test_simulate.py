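"""Generator-level guarantees: determinism, planted structure, marginals."""

import math

import numpy as np
import pandas as pd
import pytest

from sepstrat.epimarks import overlap_snps
from sepstrat.simulate import (
    SimConfig,
    plan_cohort,
    simulate_cohort,
    simulate_expression,
    simulate_genotypes,
    simulate_mark_intervals,
    simulate_survival,
)


def test_identical_config_gives_bit_identical_cohort(small_config):
    a = simulate_cohort(small_config)
    b = simulate_cohort(small_config)
    assert np.array_equal(a.expression.values, b.expression.values)
    assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
    assert a.metadata.table.equals(b.metadata.table)
    for name in a.marks:
        for chrom in a.marks[name].intervals:
            assert np.array_equal(a.marks[name].intervals[chrom],
                                  b.marks[name].intervals[chrom])


def test_genotypes_match_hardy_weinberg_at_fixed_maf():
    """Dosage frequencies at MAF 0.3 agree with (0.49, 0.42, 0.09) within 3 SE."""
    cfg = SimConfig(seed=5, n_samples=10_000, n_probes=200, n_snps=60,
                    n_de_probes=20, n_cis_eqtl=5, n_trans_eqtl=2,
                    n_group_specific=2, maf_range=(0.3, 0.3))
    geno = simulate_genotypes(cfg)
    expected = {0: 0.49, 1: 0.42, 2: 0.09}
    counts = np.stack([(geno.dosages == d).mean(axis=1) for d in (0, 1, 2)])
    for d, p in expected.items():
        se = math.sqrt(p * (1 - p) / cfg.n_samples)
        assert np.all(np.abs(counts[d] - p) < 3 * se + 0.01)
    assert geno.dosages.mean() == pytest.approx(2 * 0.3, abs=0.01)


def test_planted_group_sizes_are_deterministic(small_cohort, small_config):
    counts = small_cohort.truth.group_of_sample.value_counts()
    expected_srs1 = math.ceil(small_config.group_fractions[0] * small_config.n_samples)
    assert counts["SRS1"] == expected_srs1
    assert counts.sum() == small_config.n_samples


def test_planted_pairs_respect_cis_trans_distances(small_cohort):
    truth = small_cohort.truth
    truth.validate_distances(small_cohort.genotypes.snp_annotation(),
                             small_cohort.expression.probe_annotation())
    cis = truth.eqtl_pairs.query("klass == 'cis'")
    snp = small_cohort.genotypes.snp_annotation().set_index("snp_id")
    probe = small_cohort.expression.probe_annotation().set_index("probe_id")
    d = (snp.loc[cis["snp_id"], "pos"].to_numpy()
         - probe.loc[cis["probe_id"], "start"].to_numpy())
    assert np.all(np.abs(d) < 1e6)


def test_downregulated_fraction_uses_floor_rule():
    cfg = SimConfig(seed=2, n_samples=80, n_probes=6000, n_de_probes=3080,
                    n_snps=400, n_cis_eqtl=10, n_trans_eqtl=2, n_group_specific=2)
    truth = plan_cohort(cfg).truth
    n_down = int((truth.de_effects < 0).sum())
    assert n_down == math.floor(0.734 * 3080) == 2260


def test_expression_ols_recovers_planted_genotype_effect():
    """Regressing expression on dosage recovers a beta=1 planted effect."""
    cfg = SimConfig(seed=9, n_samples=500, n_probes=300, n_snps=120,
                    n_de_probes=10, n_cis_eqtl=20, n_trans_eqtl=0,
                    n_group_specific=0, beta_range=(1.0, 1.0),
                    s0sq=0.01, d0=50.0, confounding_strength=0.0)
    geno = simulate_genotypes(cfg)
    truth = plan_cohort(cfg).truth
    expr = simulate_expression(geno, truth, cfg)
    probe_pos = {p: i for i, p in enumerate(expr.probe_ids)}
    snp_pos = {s: i for i, s in enumerate(geno.snp_ids)}
    betas = []
    for row in truth.eqtl_pairs.itertuples(index=False):
        y = expr.values[probe_pos[row.probe_id]]
        g = geno.dosages[snp_pos[row.snp_id]].astype(float)
        betas.append(np.polyfit(g, y, 1)[0] * np.sign(row.beta))
    assert np.mean(betas) == pytest.approx(1.0, abs=0.03)


def test_null_expression_has_no_group_difference():
    cfg = SimConfig(seed=4, n_samples=200, n_probes=400, n_snps=300,
                    n_de_probes=1, n_cis_eqtl=0, n_trans_eqtl=0,
                    n_group_specific=0, de_effect_min=0.0, de_effect_scale=1e-9,
                    confounding_strength=0.0)
    geno = simulate_genotypes(cfg)
    plan = plan_cohort(cfg)
    expr = simulate_expression(geno, plan.truth, cfg)
    g1 = plan.group_index == 0
    diff = expr.values[:, g1].mean(axis=1) - expr.values[:, ~g1].mean(axis=1)
    pooled_se = np.sqrt(expr.values.var(axis=1) * (1 / g1.sum() + 1 / (~g1).sum()))
    assert np.mean(np.abs(diff) < 3 * pooled_se) > 0.95


def test_unknown_pair_id_fails_with_offender(small_config, small_cohort):
    truth = small_cohort.truth
    bad = truth.eqtl_pairs.copy()
    bad.loc[0, "probe_id"] = "NOT_A_PROBE"
    truth_bad = type(truth)(truth.group_of_sample, truth.de_effects, bad)
    with pytest.raises(KeyError, match="NOT_A_PROBE"):
        simulate_expression(small_cohort.genotypes, truth_bad, small_config)


class TestSurvival:
    def test_group_mortality_matches_planted_hazard_ratio(self):
        """Baseline tuned to 10% 14-day mortality in SRS2 gives ~22% in SRS1."""
        m1, m2 = [], []
        for seed in range(8):
            cfg = SimConfig(seed=seed, n_samples=265, n_probes=100, n_snps=60,
                            n_de_probes=10, n_cis_eqtl=5, n_trans_eqtl=1,
                            n_group_specific=1)
            plan = plan_cohort(cfg)
            surv = simulate_survival(plan.truth, cfg)
            dead14 = (surv["time"] <= 14) & (surv["event"] == 1)
            g = plan.truth.group_of_sample
            m1.append(dead14[g == "SRS1"].mean())
            m2.append(dead14[g == "SRS2"].mean())
        assert np.mean(m1) == pytest.approx(0.223, abs=0.03)
        assert np.mean(m2) == pytest.approx(0.10, abs=0.02)

    def test_censoring_horizon_truncates_times(self):
        cfg = SimConfig(seed=1, n_samples=300, n_probes=100, n_snps=60,
                        n_de_probes=10, n_cis_eqtl=5, n_trans_eqtl=1,
                        n_group_specific=1, censor_horizon_days=14.0)
        surv = simulate_survival(plan_cohort(cfg).truth, cfg)
        assert (surv["time"] <= 14).all()
        assert (surv.loc[surv["event"] == 1, "time"] < 14).all()
        assert (surv.loc[surv["event"] == 0, "time"] == 14).all()

    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, baseline_hazard=0.0)


class TestMarkIntervals:
    def test_factor_one_matches_background_rate(self):
        hits = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_samples=50, n_probes=500, n_snps=600,
                            n_de_probes=50, n_cis_eqtl=300, n_trans_eqtl=5,
                            n_group_specific=4)
            plan = plan_cohort(cfg)
            marks = simulate_mark_intervals(plan.truth, 1.0, cfg)
            cis = plan.truth.eqtl_pairs.query("klass == 'cis'")["snp_id"]
            ann = plan.snp_ann.set_index("snp_id").loc[cis].reset_index()
            hits.append(overlap_snps(ann, marks).mean())
        assert np.mean(hits) == pytest.approx(0.008, abs=0.004)

    def test_factor_four_yields_planted_overlap_rate(self):
        hits = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_samples=50, n_probes=500, n_snps=600,
                            n_de_probes=50, n_cis_eqtl=300, n_trans_eqtl=5,
                            n_group_specific=4)
            plan = plan_cohort(cfg)
            marks = simulate_mark_intervals(plan.truth, 4.0, cfg)
            cis = plan.truth.eqtl_pairs.query("klass == 'cis'")["snp_id"]
            ann = plan.snp_ann.set_index("snp_id").loc[cis].reset_index()
            hits.append(overlap_snps(ann, marks).mean())
        assert np.mean(hits) == pytest.approx(0.032, abs=0.008)

    def test_inadmissible_factor_rejected_with_maximum(self, small_config, small_cohort):
        with pytest.raises(ValueError, match="maximum admissible"):
            simulate_mark_intervals(small_cohort.truth, 200.0, small_config)

    def test_empty_truth_still_generates_background(self):
        cfg = SimConfig(seed=3, n_samples=50, n_probes=200, n_snps=100,
                        n_de_probes=10, n_cis_eqtl=0, n_trans_eqtl=0,
                        n_group_specific=0)
        marks = simulate_mark_intervals(plan_cohort(cfg).truth, 4.0, cfg)
        assert marks.n_intervals > 0


def test_variance_prior_recovered_by_moderation_estimator():
    """Gene-wise variances fitted by the DE moderation estimator recover (d0, s0sq)."""
    from sepstrat.de import estimate_variance_prior

    cfg = SimConfig(seed=6, n_samples=100, n_probes=8000, n_snps=400,
                    n_de_probes=10, n_cis_eqtl=5, n_trans_eqtl=1,
                    n_group_specific=1, confounding_strength=0.0)
    cohort = simulate_cohort(cfg, with_marks=False)
    vals = cohort.expression.values
    # two-group residual variances, as the DE model computes them
    g = (cohort.truth.group_of_sample.loc[cohort.expression.sample_ids]
         == "SRS1").to_numpy()
    resid = np.where(g, vals - vals[:, g].mean(axis=1, keepdims=True),
                     vals - vals[:, ~g].mean(axis=1, keepdims=True))
    df = cfg.n_samples - 2
    sigma2 = (resid ** 2).sum(axis=1) / df
    prior = estimate_variance_prior(sigma2, df)
    assert prior.d0 == pytest.approx(cfg.d0, rel=0.20)
    assert prior.s0sq == pytest.approx(cfg.s0sq, rel=0.20)
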