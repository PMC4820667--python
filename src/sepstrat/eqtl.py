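"""Covariate-adjusted additive-model eQTL mapping.

Each SNP-probe pair is tested by OLS of log2 expression on allele dosage
with covariates (typically expression principal components) projected
out. Pairs are classed as cis (same chromosome, SNP-to-probe-start
distance < 1 Mb) or trans (different chromosome, or > 2.5 Mb on the same
chromosome, autosomes only by default); same-chromosome pairs in the
1-2.5 Mb gap are excluded. Benjamini-Hochberg FDR is computed separately
within the cis and trans streams. The engine residualizes expression and
dosage against the covariates once and then evaluates all pairs with
vectorized cross-products, which is algebraically identical to a
per-pair OLS (checked against a naive loop in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GenotypeMatrix
from .de import bh_fdr

__all__ = ["EqtlConfig", "EqtlScan", "EqtlResults", "compute_expression_pcs",
           "classify_pairs", "map_eqtl", "lead_snp_per_probe",
           "srs_specific_eqtl", "compare_contexts"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EqtlConfig:
    cis_window: float = 1e6
    trans_min: float = 2.5e6
    n_pcs_main: int = 30
    n_pcs_group: int = 25
    fdr_cis: float = 0.05
    fdr_trans: float = 0.05
    srs_fdr_in: float = 0.01
    srs_fdr_out: float = 0.05
    trans_autosomes_only: bool = True

    def __post_init__(self):
        if self.cis_window >= self.trans_min:
            raise ValueError("cis_window must be below trans_min")
        if self.srs_fdr_in >= self.srs_fdr_out:
            raise ValueError("srs_fdr_in must be below srs_fdr_out")
        if self.n_pcs_main < 0 or self.n_pcs_group < 0:
            raise ValueError("n_pcs must be >= 0")


def compute_expression_pcs(values: np.ndarray, n_pcs: int) -> np.ndarray:
    """Principal-component scores (samples x n_pcs) of probe-centered data.

    Components are ordered by decreasing explained variance, with the sign
    convention that each component's largest-magnitude probe loading is
    positive.
    """
    Y = np.asarray(values, float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    eff_rank = int(np.sum(s > s[0] * 1e-12))
    if n_pcs >= eff_rank:
        raise ValueError(f"n_pcs={n_pcs} >= attained rank {eff_rank}")
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    scores = (Vt.T * s) * flip  # samples x components
    return scores[:, :n_pcs]


def _is_autosome(chrom: str) -> bool:
    c = str(chrom).removeprefix("chr")
    return c.isdigit()


def classify_pairs(snp_ann: pd.DataFrame, probe_ann: pd.DataFrame,
                   config: EqtlConfig = EqtlConfig(),
                   pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Class every SNP-probe pair as cis / trans / excluded.

    With ``pairs`` (columns snp_id, probe_id) only those pairs are
    classified; otherwise the full cross of SNPs x probes is built (only
    sensible for small panels). Distance is ``snp_pos - probe_start``
    (signed) on the same chromosome, undefined across chromosomes.
    """
    known = set(snp_ann["chrom"]).union(probe_ann["chrom"])
    for c in known:
        if not (str(c).startswith("chr") or str(c).removeprefix("chr").isalnum()):
            raise ValueError(f"unrecognizable chromosome label {c!r}")
    if pairs is None:
        pairs = pd.MultiIndex.from_product(
            [snp_ann["snp_id"], probe_ann["probe_id"]], names=["snp_id", "probe_id"]
        ).to_frame(index=False)
    snp = snp_ann.set_index("snp_id")
    probe = probe_ann.set_index("probe_id")
    out = pairs.copy()
    s_chrom = snp.loc[out["snp_id"], "chrom"].to_numpy()
    s_pos = snp.loc[out["snp_id"], "pos"].to_numpy(np.int64)
    p_chrom = probe.loc[out["probe_id"], "chrom"].to_numpy()
    p_start = probe.loc[out["probe_id"], "start"].to_numpy(np.int64)
    same = s_chrom == p_chrom
    dist = np.where(same, s_pos - p_start, np.iinfo(np.int64).max)
    absdist = np.abs(dist.astype(float))
    klass = np.full(len(out), "excluded", dtype=object)
    klass[same & (absdist < config.cis_window)] = "cis"
    trans_mask = (~same) | (same & (absdist > config.trans_min))
    if config.trans_autosomes_only:
        auto = np.array([_is_autosome(c) for c in s_chrom]) & \
            np.array([_is_autosome(c) for c in p_chrom])
        trans_mask &= auto
    klass[trans_mask & (klass == "excluded")] = "trans"
    out["klass"] = klass
    out["distance"] = np.where(same, dist, np.nan)
    return out


def _residualize(M: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Project out covariate columns (always including an intercept)."""
    n = M.shape[-1]
    if covariates is None:
        W = np.ones((n, 1))
    else:
        W = np.column_stack([np.ones(n), np.asarray(covariates, float)])
    Q, _ = np.linalg.qr(W)
    return M - (M @ Q) @ Q.T, W.shape[1]


class EqtlResults:
    """Association records with per-stream FDR and reporting helpers."""

    def __init__(self, records: pd.DataFrame, config: EqtlConfig, n_covariates: int):
        self.records = records
        self.config = config
        self.n_covariates = n_covariates

    def significant(self, klass: str = "cis", fdr: float | None = None) -> pd.DataFrame:
        cut = fdr if fdr is not None else (
            self.config.fdr_cis if klass == "cis" else self.config.fdr_trans)
        r = self.records
        return r[(r["klass"] == klass) & (r["fdr"] < cut)]

    def lead_per_probe(self, klass: str = "cis") -> pd.DataFrame:
        return lead_snp_per_probe(self.records[self.records["klass"] == klass])

    def summary(self) -> str:
        r = self.records
        lines = ["eQTL scan"]
        for klass in ("cis", "trans"):
            sub = r[r["klass"] == klass]
            if not len(sub):
                continue
            cut = self.config.fdr_cis if klass == "cis" else self.config.fdr_trans
            sig = sub[sub["fdr"] < cut]
            lead = lead_snp_per_probe(sig) if len(sig) else sig
            lines.append(
                f"  {klass}: {len(sub)} pairs tested, {len(sig)} significant "
                f"(FDR<{cut}), {sig['probe_id'].nunique()} probes"
            )
            if len(lead):
                lines.append(
                    f"    median r2 of lead SNP: {100 * lead['r2'].median():.1f}%"
                )
        return "\n".join(lines)


class EqtlScan:
    """Vectorized additive-model eQTL scan over classified pairs.

    Parameters
    ----------
    expr, genotypes : aligned containers (same sample order enforced)
    pairs : classified pair table from :func:`classify_pairs`
    covariates : optional samples x k array (PCs and/or clinical columns)
    """

    def __init__(self, expr: ExpressionMatrix, genotypes: GenotypeMatrix,
                 pairs: pd.DataFrame, covariates: np.ndarray | None = None,
                 config: EqtlConfig = EqtlConfig()):
        if list(expr.sample_ids) != list(genotypes.sample_ids):
            raise ValueError("expression and genotype sample ids are not aligned")
        self.expr = expr
        self.genotypes = genotypes
        self.pairs = pairs[pairs["klass"].isin(["cis", "trans"])].reset_index(drop=True)
        self.covariates = covariates
        self.config = config

    def fit(self) -> EqtlResults:
        n = self.expr.n_samples
        n_cov = 0 if self.covariates is None else np.atleast_2d(
            np.asarray(self.covariates)).reshape(n, -1).shape[1]
        G = self.genotypes.dosages.astype(float)
        keep_snp = G.std(axis=1) > 0
        skipped = self.pairs["snp_id"].isin(
            set(self.genotypes.snp_ids[~keep_snp]))
        if skipped.any():
            log.info("skipping %d pairs with monomorphic SNPs", int(skipped.sum()))
        pairs = self.pairs[~skipped].reset_index(drop=True)

        Yr, _ = _residualize(self.expr.values, self.covariates)
        Gr, k_w = _residualize(G, self.covariates)
        df = n - k_w - 1  # intercept+covariates plus the dosage term

        si = self.genotypes.snp_index(pairs["snp_id"])
        pi = self.expr.probe_index(pairs["probe_id"])
        g = Gr[si]
        y = Yr[pi]
        gg = np.einsum("ij,ij->i", g, g)
        yy = np.einsum("ij,ij->i", y, y)
        gy = np.einsum("ij,ij->i", g, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = gy / gg
            rss = yy - beta * gy
            sigma2 = rss / df
            se = np.sqrt(sigma2 / gg)
            t = beta / se
            r2 = np.where(yy > 0, gy ** 2 / (gg * yy), 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df)

        rec = pairs.copy()
        rec["beta"], rec["se"], rec["t"], rec["p"], rec["r2"] = beta, se, t, p, r2
        rec["fdr"] = np.nan
        for klass in ("cis", "trans"):
            m = rec["klass"] == klass
            if m.any():
                rec.loc[m, "fdr"] = bh_fdr(rec.loc[m, "p"].to_numpy())
        return EqtlResults(rec, self.config, n_cov)


def map_eqtl(expr, genotypes, pairs, covariates=None,
             config: EqtlConfig = EqtlConfig()) -> EqtlResults:
    return EqtlScan(expr, genotypes, pairs, covariates, config).fit()


def lead_snp_per_probe(records: pd.DataFrame) -> pd.DataFrame:
    """Minimum-p record per probe; ties by larger |beta| then snp_id order."""
    if not len(records):
        raise ValueError("no records to select leads from")
    r = records.copy()
    r["_absbeta"] = -r["beta"].abs()
    r = r.sort_values(["probe_id", "p", "_absbeta", "snp_id"], kind="mergesort")
    lead = r.groupby("probe_id", sort=True).head(1).drop(columns="_absbeta")
    return lead.reset_index(drop=True)


def srs_specific_eqtl(records_srs1: pd.DataFrame, records_srs2: pd.DataFrame,
                      config: EqtlConfig = EqtlConfig()) -> pd.DataFrame:
    """Group-specific eQTL calling from two per-group scans.

    A pair is SRS1-specific when FDR < ``srs_fdr_in`` in SRS1 and
    > ``srs_fdr_out`` in SRS2 (and symmetrically); shared when below
    ``srs_fdr_out`` in both; otherwise unclassified. The pair universes
    must intersect; the comparison is restricted to the intersection.
    """
    key = ["snp_id", "probe_id"]
    a = records_srs1.set_index(key)
    b = records_srs2.set_index(key)
    shared_idx = a.index.intersection(b.index)
    if len(shared_idx) == 0:
        raise ValueError("per-group record tables have disjoint pair universes")
    fdr1 = a.loc[shared_idx, "fdr"]
    fdr2 = b.loc[shared_idx, "fdr"]
    call = np.full(len(shared_idx), "unclassified", dtype=object)
    call[(fdr1 < config.srs_fdr_in) & (fdr2 > config.srs_fdr_out)] = "srs1_only"
    call[(fdr2 < config.srs_fdr_in) & (fdr1 > config.srs_fdr_out)] = "srs2_only"
    call[(fdr1 < config.srs_fdr_out) & (fdr2 < config.srs_fdr_out)] = "shared"
    out = pd.DataFrame({"fdr_srs1": fdr1, "fdr_srs2": fdr2, "call": call},
                       index=shared_idx).reset_index()
    return out


def compare_contexts(records_condition: pd.DataFrame,
                     records_reference: pd.DataFrame,
                     tss_positions: pd.Series,
                     fdr: float = 0.05) -> dict:
    """Label genes as context-specific vs shared and test lead-SNP distances.

    A gene (probe) is context-specific when significant (FDR < ``fdr``)
    in the condition scan but not in the reference; shared when
    significant in both. The two classes' |lead SNP - TSS| distances are
    compared by a two-sided Mann-Whitney U test.
    """
    genes_cond = set(records_condition.loc[records_condition["fdr"] < fdr, "probe_id"])
    genes_ref = set(records_reference.loc[records_reference["fdr"] < fdr, "probe_id"])
    universe = set(records_condition["probe_id"]) & set(records_reference["probe_id"])
    specific = (genes_cond - genes_ref) & universe
    shared = (genes_cond & genes_ref) & universe

    leads = lead_snp_per_probe(
        records_condition[records_condition["probe_id"].isin(genes_cond & universe)])
    leads = leads.set_index("probe_id")
    dist = {}
    for g in (specific | shared):
        if g in leads.index and g in tss_positions.index:
            d = leads.loc[g, "distance"]
            if pd.notna(d):
                dist[g] = abs(float(d))
    d_spec = [dist[g] for g in specific if g in dist]
    d_shared = [dist[g] for g in shared if g in dist]
    result = {"context_specific": sorted(specific), "shared": sorted(shared),
              "median_dist_specific": float(np.median(d_spec)) if d_spec else np.nan,
              "median_dist_shared": float(np.median(d_shared)) if d_shared else np.nan,
              "mannwhitney_p": np.nan}
    if d_spec and d_shared:
        _, p = stats.mannwhitneyu(d_spec, d_shared, alternative="two-sided")
        result["mannwhitney_p"] = float(p)
    else:
        log.warning("a distance class is empty; Mann-Whitney test skipped")
    return result
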