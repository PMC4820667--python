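"""Synthetic sepsis-cohort generator.

Emulates the statistical structure of a blood-leucocyte transcriptomic
study of sepsis patients: two latent expression groups of unequal size
(41%/59% by default) with a majority-downregulated differential-expression
program in group 1, gene-wise noise variances drawn from a scaled
inverse-chi-square prior (so empirical-Bayes variance moderation holds by
construction), additive cis/trans genotype effects on designated probes
(some restricted to one group), a cell-proportion confounder correlated
with group, group-dependent survival hazard, and epigenetic-mark intervals
enriched around true regulatory SNPs.

All randomness flows from ``SimConfig.seed`` through fixed-index
``SeedSequence`` spawns (one stream per generation step), so individual
steps are reproducible in isolation and the full cohort is bit-identical
across runs with the same config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .datatypes import (
    CohortMetadata,
    ExpressionMatrix,
    GenotypeMatrix,
    IntervalSet,
    SimTruth,
)

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort", "simulate_genotypes",
           "simulate_expression", "simulate_survival", "simulate_mark_intervals",
           "plan_cohort"]

# Synthetic genome: six 40-Mb autosomes plus one X-like chromosome, large
# enough that cis (<1 Mb) and trans (>2.5 Mb) windows both fit comfortably.
CHROM_LENGTHS = {
    "chr1": 40_000_000,
    "chr2": 40_000_000,
    "chr3": 40_000_000,
    "chr4": 40_000_000,
    "chr5": 40_000_000,
    "chr6": 40_000_000,
    "chrX": 40_000_000,
}
AUTOSOMES = tuple(c for c in CHROM_LENGTHS if c != "chrX")

# stream indices of the seed-splitting scheme; marks use 100 + mark index
_PLAN, _GENO, _EXPR, _SURV, _COVAR, _META = range(6)
_MARK_BASE = 100


def _rng(config: "SimConfig", stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SimConfig:
    """Generation parameters; defaults mirror the discovery-cohort scale.

    ``group_fractions`` plants ``len(group_fractions)`` latent groups with
    deterministic sizes (first ``round(f * n)`` samples of a seeded
    shuffle). ``frac_down_in_group1`` is the fraction of DE probes whose
    group-1 effect is negative. Gene noise variances follow
    ``s0sq * d0 / chi2(d0)``.
    """

    seed: int
    n_samples: int = 265
    n_probes: int = 26_185
    n_snps: int = 3_000
    group_fractions: tuple = (0.41, 0.59)
    # differential-expression program
    n_de_probes: int = 3_080
    frac_down_in_group1: float = 0.734
    de_effect_min: float = 0.585  # log2(1.5): planted effects exceed the FC call threshold
    de_effect_scale: float = 0.45  # exponential tail above the minimum
    # gene-wise variance prior (scaled inverse chi-square)
    d0: float = 4.0
    s0sq: float = 0.05
    # arrays that survive QC do not carry arbitrarily noisy probes; the
    # inverse-chi-square tail is truncated at this log2-scale variance
    sigma2_max: float = 2.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    # eQTL program
    n_cis_eqtl: int = 200
    n_trans_eqtl: int = 20
    n_group_specific: int = 20
    beta_range: tuple = (0.5, 1.5)
    maf_range: tuple = (0.1, 0.5)
    # confounding (cell-proportion proxy correlated with group)
    confounding_strength: float = 0.15
    confounded_probe_fraction: float = 0.10
    # survival; baseline hazard gives ~10% 14-day mortality in group 2
    baseline_hazard: float = -math.log(0.90) / 14.0
    hazard_ratio: float = 2.4
    censor_horizon_days: float = 180.0
    # epigenetic marks
    mark_background_rate: float = 0.008
    mark_enrichment_factor: float = 4.0
    mark_width: int = 1_000
    monomorphic_retries: int = 20

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not all(0 < f < 1 for f in self.group_fractions):
            raise ValueError("group fractions must lie in (0, 1)")
        if abs(sum(self.group_fractions) - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")
        if self.n_de_probes > self.n_probes:
            raise ValueError("n_de_probes cannot exceed n_probes")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 < self.frac_down_in_group1 < 1:
            raise ValueError("frac_down_in_group1 must lie in (0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")


@dataclass
class CohortPlan:
    """Deterministic genome/effect layout derived from the config seed."""

    probe_ann: pd.DataFrame  # probe_id, chrom, start
    snp_ann: pd.DataFrame  # snp_id, chrom, pos, maf
    truth: SimTruth
    sample_ids: np.ndarray
    group_index: np.ndarray  # 0-based group per sample


@lru_cache(maxsize=8)
def plan_cohort(config: SimConfig) -> CohortPlan:
    """Lay out probes, SNPs, groups, DE effects and eQTL pairs.

    Cis pair SNPs are placed within 1 Mb of their probe start; trans pair
    SNPs land on a different autosome (infinite cis distance). The layout
    is a pure function of the config.
    """
    rng = _rng(config, _PLAN)
    n_probes, n_snps, n = config.n_probes, config.n_snps, config.n_samples

    digits = max(6, len(str(n_probes)))
    probe_ids = np.array([f"P{i:0{digits}d}" for i in range(n_probes)], dtype=object)
    chrom_names = np.array(list(CHROM_LENGTHS), dtype=object)
    # ~5% of probes on chrX, rest uniform on autosomes
    probe_chrom = np.where(
        rng.random(n_probes) < 0.05,
        "chrX",
        rng.choice(np.array(AUTOSOMES, dtype=object), size=n_probes),
    ).astype(object)
    lengths = np.array([CHROM_LENGTHS[c] for c in probe_chrom])
    probe_start = rng.integers(1_000_000, lengths - 1_000_000)
    probe_ann = pd.DataFrame({"probe_id": probe_ids, "chrom": probe_chrom, "start": probe_start})

    # groups: seeded shuffle then deterministic block assignment
    sample_ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    perm = rng.permutation(n)
    sizes = [int(math.ceil(f * n)) for f in config.group_fractions]
    sizes[-1] = n - sum(sizes[:-1])
    group_index = np.empty(n, dtype=np.int64)
    start = 0
    for g, size in enumerate(sizes):
        group_index[perm[start:start + size]] = g
        start += size
    group_names = np.array([f"SRS{g + 1}" for g in range(len(sizes))], dtype=object)
    group_of_sample = pd.Series(group_names[group_index], index=sample_ids)

    # DE program: signed log2 effects for group 1, majority negative
    de_idx = rng.choice(n_probes, size=config.n_de_probes, replace=False)
    n_down = int(math.floor(config.frac_down_in_group1 * config.n_de_probes))
    signs = np.ones(config.n_de_probes)
    signs[:n_down] = -1.0
    magnitudes = config.de_effect_min + rng.exponential(config.de_effect_scale, config.n_de_probes)
    de_effects = pd.Series(signs * magnitudes, index=probe_ids[de_idx])

    # eQTL program: one planted SNP per chosen probe, probes disjoint
    n_pairs = config.n_cis_eqtl + config.n_trans_eqtl
    if config.n_group_specific > config.n_cis_eqtl:
        raise ValueError("group-specific pairs must be a subset of cis pairs")
    pool = rng.permutation(n_probes)[:n_pairs]
    cis_probes, trans_probes = pool[:config.n_cis_eqtl], pool[config.n_cis_eqtl:]

    snp_records = []
    pair_rows = []
    betas = rng.uniform(*config.beta_range, size=n_pairs) * rng.choice([-1.0, 1.0], n_pairs)
    restrictions = np.array(["both"] * n_pairs, dtype=object)
    spec_idx = rng.choice(config.n_cis_eqtl, size=config.n_group_specific, replace=False)
    restrictions[spec_idx] = np.where(
        np.arange(config.n_group_specific) % 2 == 0, "group1-only", "group2-only"
    )

    for k, pi in enumerate(cis_probes):
        chrom, pstart = probe_chrom[pi], int(probe_start[pi])
        offset = int(rng.integers(5_000, 900_000)) * int(rng.choice([-1, 1]))
        pos = int(np.clip(pstart + offset, 1, CHROM_LENGTHS[chrom] - 1))
        snp_records.append((chrom, pos))
        pair_rows.append((k, pi, betas[k], "cis", restrictions[k]))
    for k, pi in enumerate(trans_probes, start=config.n_cis_eqtl):
        others = [c for c in AUTOSOMES if c != probe_chrom[pi]]
        chrom = str(rng.choice(np.array(others, dtype=object)))
        pos = int(rng.integers(1, CHROM_LENGTHS[chrom]))
        snp_records.append((chrom, pos))
        pair_rows.append((k, pi, betas[k], "trans", restrictions[k]))

    # background SNPs fill the panel up to n_snps
    n_background = n_snps - n_pairs
    if n_background < 0:
        raise ValueError("n_snps too small for the planted eQTL program")
    bg_chrom = rng.choice(chrom_names, size=n_background)
    bg_pos = rng.integers(1, [CHROM_LENGTHS[c] for c in bg_chrom])
    all_chrom = np.concatenate([np.array([r[0] for r in snp_records], dtype=object), bg_chrom])
    all_pos = np.concatenate([np.array([r[1] for r in snp_records]), bg_pos])
    sdigits = max(6, len(str(n_snps)))
    snp_ids = np.array([f"snp{i:0{sdigits}d}" for i in range(n_snps)], dtype=object)
    maf = rng.uniform(*config.maf_range, size=n_snps)
    snp_ann = pd.DataFrame({"snp_id": snp_ids, "chrom": all_chrom, "pos": all_pos, "maf": maf})

    eqtl_pairs = pd.DataFrame(
        [
            (snp_ids[k], probe_ids[pi], beta, klass, restr)
            for k, pi, beta, klass, restr in pair_rows
        ],
        columns=["snp_id", "probe_id", "beta", "klass", "group_restriction"],
    )

    truth = SimTruth(
        group_of_sample=group_of_sample,
        de_effects=de_effects,
        eqtl_pairs=eqtl_pairs,
        variance_prior=(config.d0, config.s0sq),
        hazard_ratio_true=config.hazard_ratio,
    )
    return CohortPlan(probe_ann, snp_ann, truth, sample_ids, group_index)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages Binomial(2, MAF) per SNP and sample.

    Monomorphic draws are redrawn up to ``config.monomorphic_retries``
    times; a SNP still monomorphic after that raises, naming the SNP.
    """
    plan = plan_cohort(config)
    rng = _rng(config, _GENO)
    maf = plan.snp_ann["maf"].to_numpy()
    dosages = rng.binomial(2, maf[:, None], size=(config.n_snps, config.n_samples))
    for i in np.nonzero(dosages.std(axis=1) == 0)[0]:
        for attempt in range(config.monomorphic_retries):
            row = rng.binomial(2, maf[i], size=config.n_samples)
            if row.std() > 0:
                dosages[i] = row
                break
        else:
            raise RuntimeError(
                f"SNP {plan.snp_ann['snp_id'].iloc[i]} monomorphic after "
                f"{config.monomorphic_retries} retries (maf={maf[i]:.4f})"
            )
    return GenotypeMatrix(
        dosages=dosages.astype(np.int8),
        snp_ids=plan.snp_ann["snp_id"].to_numpy(),
        snp_chrom=plan.snp_ann["chrom"].to_numpy(),
        snp_pos=plan.snp_ann["pos"].to_numpy(),
        maf=maf,
        sample_ids=plan.sample_ids,
    )


def _confounder(config: SimConfig) -> np.ndarray:
    """Neutrophil-proportion proxy, higher in group 1 (cell-count confound)."""
    plan = plan_cohort(config)
    rng = _rng(config, _COVAR)
    is_g1 = plan.group_index == 0
    neut = np.where(
        is_g1,
        rng.normal(0.89, 0.07, config.n_samples),
        rng.normal(0.82, 0.09, config.n_samples),
    )
    return np.clip(neut, 0.30, 0.99)


def simulate_expression(
    genotypes: GenotypeMatrix, truth: SimTruth, config: SimConfig
) -> ExpressionMatrix:
    """Probe baseline + group effect + genotype effects + confounder + noise.

    Noise variance per probe is drawn from the scaled inverse-chi-square
    prior ``s0sq * d0 / chi2(d0)``. Group-restricted eQTL betas are zeroed
    outside their allowed group.
    """
    plan = plan_cohort(config)
    rng = _rng(config, _EXPR)
    n_probes, n = config.n_probes, config.n_samples

    probe_ids = plan.probe_ann["probe_id"].to_numpy()
    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_probes)
    sigma2 = np.minimum(
        config.s0sq * config.d0 / rng.chisquare(config.d0, n_probes),
        config.sigma2_max,
    )

    values = baseline[:, None] + rng.normal(0.0, 1.0, (n_probes, n)) * np.sqrt(sigma2)[:, None]

    # group effects: planted signed effect in group 1; extra groups (k > 2
    # scenarios) get their own independent signed program on the same probes
    n_groups = len(config.group_fractions)
    de_rows = np.array([probe_pos[p] for p in truth.de_effects.index])
    effects = np.zeros((len(de_rows), n_groups))
    effects[:, 0] = truth.de_effects.to_numpy()
    for g in range(2, n_groups):
        mag = config.de_effect_min + rng.exponential(config.de_effect_scale, len(de_rows))
        effects[:, g] = mag * rng.choice([-1.0, 1.0], len(de_rows))
    values[de_rows[:, None], np.arange(n)[None, :]] += effects[:, plan.group_index]

    # additive genotype effects, zeroed outside any group restriction
    group_index = plan.group_index
    for row in truth.eqtl_pairs.itertuples(index=False):
        if row.probe_id not in probe_pos:
            raise KeyError(f"eQTL pair references unknown probe {row.probe_id}")
        if row.snp_id not in snp_pos:
            raise KeyError(f"eQTL pair references unknown SNP {row.snp_id}")
        dos = genotypes.dosages[snp_pos[row.snp_id]].astype(float)
        active = np.ones(n, dtype=bool)
        if row.group_restriction == "group1-only":
            active = group_index == 0
        elif row.group_restriction == "group2-only":
            active = group_index == 1
        values[probe_pos[row.probe_id]] += row.beta * dos * active

    # cell-proportion confounder loads on a random subset of probes
    if config.confounding_strength > 0:
        conf = _confounder(config)
        z = (conf - conf.mean()) / max(conf.std(), 1e-12)
        n_conf = int(round(config.confounded_probe_fraction * n_probes))
        conf_rows = rng.choice(n_probes, size=n_conf, replace=False)
        loadings = rng.normal(0.0, config.confounding_strength, n_conf)
        values[conf_rows] += loadings[:, None] * z[None, :]

    return ExpressionMatrix(
        values=values,
        probe_ids=probe_ids,
        probe_chrom=plan.probe_ann["chrom"].to_numpy(),
        probe_start=plan.probe_ann["start"].to_numpy(),
        sample_ids=plan.sample_ids,
    )


def simulate_survival(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Exponential survival with hazard ``lambda0 * HR`` in group 1.

    Administrative censoring at ``censor_horizon_days``; events occur
    strictly before the horizon. Returns time/event indexed by sample.
    """
    if config.hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    plan = plan_cohort(config)
    rng = _rng(config, _SURV)
    hazard = np.where(plan.group_index == 0,
                      config.baseline_hazard * config.hazard_ratio,
                      config.baseline_hazard)
    raw = rng.exponential(1.0 / hazard)
    time = np.minimum(raw, config.censor_horizon_days)
    event = (raw < config.censor_horizon_days).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=plan.sample_ids)


def simulate_metadata(truth: SimTruth, config: SimConfig) -> CohortMetadata:
    """Clinical covariates (age, sex, severity score, cell proportion) plus survival."""
    plan = plan_cohort(config)
    rng = _rng(config, _META)
    is_g1 = plan.group_index == 0
    neut = _confounder(config)  # identical draws to the expression confounder stream
    age = np.clip(rng.normal(62, 16, config.n_samples), 18, 95)
    sex = rng.binomial(1, 0.55, config.n_samples)
    sofa = np.clip(np.where(is_g1, rng.normal(7.9, 4.0, config.n_samples),
                            rng.normal(5.4, 3.2, config.n_samples)), 0, 24)
    surv = simulate_survival(truth, config)
    table = pd.DataFrame(
        {
            "age": age,
            "male_sex": sex,
            "sofa": np.round(sofa, 1),
            "neutrophil_prop": np.round(neut, 3),
            "time": surv["time"],
            "event": surv["event"],
            "srs": truth.group_of_sample.to_numpy(),
        },
        index=plan.sample_ids,
    )
    table.index.name = "sample_id"
    return CohortMetadata(table)


def simulate_mark_intervals(
    truth: SimTruth,
    enrichment_factor: float,
    config: SimConfig,
    mark_name: str = "mark",
    stream_offset: int = 0,
) -> IntervalSet:
    """Fixed-width intervals with planted enrichment at true cis lead SNPs.

    Background intervals cover ``mark_background_rate`` of each chromosome
    uniformly; each true cis eSNP additionally receives a covering
    interval with probability chosen so its total overlap probability is
    ``enrichment_factor x background``.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    bg = config.mark_background_rate
    p_total = enrichment_factor * bg
    if p_total > 1:
        raise ValueError(
            f"enrichment_factor x background = {p_total:.3f} > 1; "
            f"maximum admissible factor is {1 / bg:.1f}"
        )
    plan = plan_cohort(config)
    rng = _rng(config, _MARK_BASE + stream_offset)
    w = config.mark_width
    intervals: dict[str, list] = {c: [] for c in CHROM_LENGTHS}
    for chrom, length in CHROM_LENGTHS.items():
        n_iv = int(round(bg * length / w))
        starts = rng.integers(0, length - w, size=n_iv)
        intervals[chrom].extend((int(s), int(s) + w) for s in starts)

    # targeted placement: total hit probability p_t + (1 - p_t) * bg = factor * bg
    p_target = (enrichment_factor - 1.0) * bg / (1.0 - bg)
    cis = truth.eqtl_pairs[truth.eqtl_pairs["klass"] == "cis"]
    if len(cis):
        snp_ann = plan.snp_ann.set_index("snp_id")
        for snp_id in cis["snp_id"]:
            if rng.random() < p_target:
                chrom = snp_ann.loc[snp_id, "chrom"]
                pos0 = int(snp_ann.loc[snp_id, "pos"]) - 1  # 0-based
                shift = int(rng.integers(0, w))
                start = max(0, pos0 - shift)
                intervals[chrom].append((start, start + w))
    arrays = {c: np.array(v, dtype=np.int64).reshape(-1, 2) for c, v in intervals.items()}
    return IntervalSet(arrays, mark_name=mark_name)


MARK_NAMES = ("H3K27ac", "H3K4me1", "H3K4me3", "DNaseI")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    genotypes: GenotypeMatrix
    metadata: CohortMetadata
    truth: SimTruth
    marks: dict = field(default_factory=dict)


def simulate_cohort(config: SimConfig, with_marks: bool = True) -> SyntheticCohort:
    """Generate the full cohort bundle used by the end-to-end pipeline."""
    plan = plan_cohort(config)
    genotypes = simulate_genotypes(config)
    expression = simulate_expression(genotypes, plan.truth, config)
    metadata = simulate_metadata(plan.truth, config)
    marks = {}
    if with_marks:
        for j, name in enumerate(MARK_NAMES):
            marks[name] = simulate_mark_intervals(
                plan.truth, config.mark_enrichment_factor, config,
                mark_name=name, stream_offset=j,
            )
    truth = plan.truth
    truth.confounder = pd.Series(_confounder(config), index=plan.sample_ids)
    return SyntheticCohort(expression, genotypes, metadata, truth, marks)
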