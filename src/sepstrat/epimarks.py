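"""Enrichment of expression-associated SNPs in epigenetic-mark intervals.

Two complementary tests against a background of all SNPs within 1 Mb of
any probe start: the proportion of SNPs overlapping a mark (Fisher's
exact test on the 2x2 table) and the distance to the nearest mark
(Mann-Whitney). Intervals are merged per chromosome before testing so
overlap proportions are well defined on peak files containing duplicates.
SNP positions are 1-based; intervals are 0-based half-open, so a SNP at
position p overlaps [s, e) iff s <= p-1 < e.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import IntervalSet

__all__ = ["EnrichmentResult", "overlap_snps", "snp_mark_distances",
           "enrichment_fisher", "distance_test", "background_snps_near_probes",
           "mark_enrichment"]

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    mark_name: str
    prop_fg: float
    prop_bg: float
    fisher_p: float
    odds_ratio: float
    median_dist_fg: float = np.nan
    median_dist_bg: float = np.nan
    mannwhitney_p: float = np.nan

    def summary(self) -> str:
        return (f"{self.mark_name}: overlap {100 * self.prop_fg:.2f}% vs "
                f"{100 * self.prop_bg:.2f}% (Fisher p={self.fisher_p:.3g}, "
                f"OR={self.odds_ratio:.2f}); median distance "
                f"{self.median_dist_fg:.0f} vs {self.median_dist_bg:.0f} bp "
                f"(Mann-Whitney p={self.mannwhitney_p:.3g})")


def overlap_snps(snp_ann: pd.DataFrame, interval_set: IntervalSet) -> np.ndarray:
    """Boolean per SNP: does its (1-based) position fall in any interval?

    Binary search per chromosome over merged intervals. Chromosomes
    absent from the interval set yield no overlap (logged, not an error).
    """
    merged = interval_set.merged().intervals
    hits = np.zeros(len(snp_ann), dtype=bool)
    missing = set()
    for chrom, sub in snp_ann.groupby("chrom", sort=False):
        if chrom not in merged or len(merged[chrom]) == 0:
            missing.add(chrom)
            continue
        ivals = merged[chrom]
        pos0 = sub["pos"].to_numpy(np.int64) - 1  # to 0-based
        idx = np.searchsorted(ivals[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(len(sub), dtype=bool)
        inside[ok] = pos0[ok] < ivals[idx[ok], 1]
        hits[snp_ann.index.get_indexer(sub.index)] = inside
    if missing:
        log.info("no intervals on chromosomes %s; SNPs there counted as "
                 "non-overlapping", sorted(map(str, missing)))
    return hits


def snp_mark_distances(snp_ann: pd.DataFrame, interval_set: IntervalSet) -> np.ndarray:
    """bp distance from each SNP to the nearest interval edge (0 if inside).

    SNPs on chromosomes without any interval get NaN (excluded upstream
    with a log message).
    """
    merged = interval_set.merged().intervals
    out = np.full(len(snp_ann), np.nan)
    for chrom, sub in snp_ann.groupby("chrom", sort=False):
        if chrom not in merged or len(merged[chrom]) == 0:
            continue
        ivals = merged[chrom]
        pos0 = sub["pos"].to_numpy(np.int64) - 1
        idx = np.searchsorted(ivals[:, 0], pos0, side="right") - 1
        n = len(sub)
        d = np.full(n, np.inf)
        ok = idx >= 0
        inside = np.zeros(n, dtype=bool)
        inside[ok] = pos0[ok] < ivals[idx[ok], 1]
        # gap to the end of the previous interval
        d[ok & ~inside] = pos0[ok & ~inside] - (ivals[idx[ok & ~inside], 1] - 1)
        # gap to the start of the next interval
        nxt = idx + 1
        has_next = nxt < len(ivals)
        sel = has_next & ~inside
        d[sel] = np.minimum(d[sel], ivals[nxt[sel], 0] - pos0[sel])
        d[inside] = 0.0
        out[snp_ann.index.get_indexer(sub.index)] = d
    return out


def background_snps_near_probes(snp_ann: pd.DataFrame, probe_ann: pd.DataFrame,
                                window: float = 1e6) -> pd.DataFrame:
    """All SNPs within ``window`` bp of any probe start (the comparator set)."""
    keep = np.zeros(len(snp_ann), dtype=bool)
    probes_by_chrom = {c: np.sort(sub["start"].to_numpy(np.int64))
                       for c, sub in probe_ann.groupby("chrom", sort=False)}
    for chrom, sub in snp_ann.groupby("chrom", sort=False):
        starts = probes_by_chrom.get(chrom)
        if starts is None:
            continue
        pos = sub["pos"].to_numpy(np.int64)
        j = np.searchsorted(starts, pos)
        near = np.full(len(sub), np.inf)
        left_ok = j > 0
        near[left_ok] = np.abs(pos[left_ok] - starts[j[left_ok] - 1])
        right_ok = j < len(starts)
        near[right_ok] = np.minimum(near[right_ok],
                                    np.abs(starts[j[right_ok]] - pos[right_ok]))
        keep[snp_ann.index.get_indexer(sub.index)] = near < window
    return snp_ann[keep]


def enrichment_fisher(fg_ann: pd.DataFrame, bg_ann: pd.DataFrame,
                      interval_set: IntervalSet) -> tuple:
    """Two-sided Fisher exact test of overlap proportions (fg vs bg)."""
    if len(fg_ann) == 0:
        raise ValueError("empty foreground SNP set")
    fg_hit = overlap_snps(fg_ann, interval_set)
    bg_hit = overlap_snps(bg_ann, interval_set)
    table = [[int(fg_hit.sum()), int((~fg_hit).sum())],
             [int(bg_hit.sum()), int((~bg_hit).sum())]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(fg_hit.mean()), float(bg_hit.mean()), float(p), float(odds), table


def distance_test(fg_ann: pd.DataFrame, bg_ann: pd.DataFrame,
                  interval_set: IntervalSet, exact_max_n: int = 20) -> tuple:
    """Two-sided Mann-Whitney on distance-to-nearest-mark (fg vs bg).

    Uses the exact null only for tiny arms; otherwise the tie-corrected
    normal approximation. Identical constant distances give p = 1.
    """
    d_fg = snp_mark_distances(fg_ann, interval_set)
    d_bg = snp_mark_distances(bg_ann, interval_set)
    n_na = int(np.isnan(d_fg).sum() + np.isnan(d_bg).sum())
    if n_na:
        log.info("excluding %d SNPs on chromosomes without marks", n_na)
    d_fg = d_fg[~np.isnan(d_fg)]
    d_bg = d_bg[~np.isnan(d_bg)]
    if len(d_fg) == 0 or len(d_bg) == 0:
        return np.nan, np.nan, np.nan
    if len(set(d_fg) | set(d_bg)) == 1:
        return float(np.median(d_fg)), float(np.median(d_bg)), 1.0
    method = "exact" if max(len(d_fg), len(d_bg)) <= exact_max_n and \
        len(set(np.concatenate([d_fg, d_bg]))) == len(d_fg) + len(d_bg) else "asymptotic"
    _, p = stats.mannwhitneyu(d_fg, d_bg, alternative="two-sided", method=method)
    return float(np.median(d_fg)), float(np.median(d_bg)), float(p)


def mark_enrichment(fg_ann: pd.DataFrame, bg_ann: pd.DataFrame,
                    interval_set: IntervalSet) -> EnrichmentResult:
    """Full overlap + distance enrichment report for one mark."""
    prop_fg, prop_bg, fisher_p, odds, _ = enrichment_fisher(fg_ann, bg_ann, interval_set)
    med_fg, med_bg, mw_p = distance_test(fg_ann, bg_ann, interval_set)
    return EnrichmentResult(interval_set.mark_name, prop_fg, prop_bg,
                            fisher_p, odds, med_fg, med_bg, mw_p)
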