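"""Core in-memory containers shared by every analysis stage.

Expression is held on the normalized log2 scale with probes as rows and
samples as columns, mirroring the layout of microarray summary files.
Genotypes are additive allele dosages in {0, 1, 2}. All genomic
coordinates on these containers are 1-based; BED interval sets are
0-based half-open (see :class:`IntervalSet`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GenotypeMatrix",
    "CohortMetadata",
    "IntervalSet",
    "SimTruth",
]


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of normalized log2 intensities.

    Parameters
    ----------
    values : (n_probes, n_samples) float array
    probe_ids, sample_ids : identifier sequences
    probe_chrom : chromosome label per probe
    probe_start : 1-based bp coordinate of each probe's start site,
        the anchor used for cis/trans distance.
    """

    values: np.ndarray
    probe_ids: np.ndarray
    probe_chrom: np.ndarray
    probe_start: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.probe_chrom = np.asarray(self.probe_chrom, dtype=object)
        self.probe_start = np.asarray(self.probe_start, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_probes, n_samples = self.values.shape
        if len(self.probe_ids) != n_probes:
            raise ValueError("probe_ids length does not match values rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match values columns")
        if len(np.unique(self.probe_ids)) != n_probes:
            raise ValueError("probe_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        if np.any(self.probe_start < 1):
            raise ValueError("probe_start coordinates must be >= 1")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def probe_index(self, probe_ids) -> np.ndarray:
        """Row indices for the given probe ids (raises on unknown ids)."""
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in lookup]
        if missing:
            raise KeyError(f"unknown probe ids: {missing[:10]}")
        return np.array([lookup[p] for p in probe_ids], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def probe_annotation(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "chrom": self.probe_chrom,
                "start": self.probe_start,
            }
        )


@dataclass
class GenotypeMatrix:
    """SNPs x samples additive dosage matrix with genomic positions."""

    dosages: np.ndarray
    snp_ids: np.ndarray
    snp_chrom: np.ndarray
    snp_pos: np.ndarray
    maf: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.snp_chrom = np.asarray(self.snp_chrom, dtype=object)
        self.snp_pos = np.asarray(self.snp_pos, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_snps, n_samples = self.dosages.shape
        if len(self.snp_ids) != n_snps:
            raise ValueError("snp_ids length does not match dosage rows")
        if len(np.unique(self.snp_ids)) != n_snps:
            raise ValueError("snp_ids must be unique")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match dosage columns")
        if not np.isin(np.unique(self.dosages), [0, 1, 2]).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        if np.any((self.maf <= 0) | (self.maf > 0.5)):
            raise ValueError("maf must lie in (0, 0.5]")

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown snp ids: {missing[:10]}")
        return np.array([lookup[s] for s in snp_ids], dtype=np.int64)

    def snp_annotation(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.snp_chrom,
                "pos": self.snp_pos,
                "maf": self.maf,
            }
        )


@dataclass
class CohortMetadata:
    """Per-sample clinical covariates, survival outcome and group label.

    ``table`` is indexed by sample id and carries covariate columns plus
    ``time`` (days to death or censoring, > 0), ``event`` (1 = death) and
    optionally ``srs`` in {"SRS1", "SRS2", "unassigned"}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if "time" in self.table.columns:
            if (self.table["time"] <= 0).any():
                raise ValueError("survival times must be > 0")
        if "event" in self.table.columns:
            if not self.table["event"].isin([0, 1]).all():
                raise ValueError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def aligned_to(self, sample_ids) -> "CohortMetadata":
        return CohortMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class IntervalSet:
    """Genomic intervals in 0-based half-open coordinates, sorted per chromosome.

    ``intervals`` maps chromosome -> (n, 2) int array of [start, end).
    ``mark_name`` labels the epigenetic mark the intervals describe.
    """

    intervals: dict
    mark_name: str = "mark"

    def __post_init__(self) -> None:
        clean = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and (np.any(arr[:, 0] < 0) or np.any(arr[:, 0] >= arr[:, 1])):
                raise ValueError(f"invalid interval on {chrom}: need 0 <= start < end")
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            clean[chrom] = arr[order]
        self.intervals = clean

    @property
    def n_intervals(self) -> int:
        return sum(len(a) for a in self.intervals.values())

    def total_span(self) -> int:
        """Total covered bp after merging overlapping intervals."""
        return sum(
            int(np.sum(m[:, 1] - m[:, 0])) for m in self.merged().intervals.values()
        )

    def merged(self) -> "IntervalSet":
        """Union of intervals per chromosome (overlaps and abutments merged)."""
        out = {}
        for chrom, arr in self.intervals.items():
            if len(arr) == 0:
                out[chrom] = arr
                continue
            merged = [arr[0].tolist()]
            for s, e in arr[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.array(merged, dtype=np.int64)
        return IntervalSet(out, mark_name=self.mark_name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                rows.append((chrom, int(s), int(e), self.mark_name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


@dataclass
class SimTruth:
    """Ground truth planted by the synthetic-cohort generator.

    Used only to score recovery; no analysis stage reads it.
    """

    group_of_sample: pd.Series  # sample id -> "SRS1" / "SRS2" / higher groups
    de_effects: pd.Series  # probe id -> signed log2 effect in SRS1 (DE probes only)
    eqtl_pairs: pd.DataFrame  # snp_id, probe_id, beta, klass, group_restriction
    variance_prior: tuple = (4.0, 0.05)  # (d0_true, s0sq_true)
    hazard_ratio_true: float = 2.4
    confounder: pd.Series | None = field(default=None)

    def validate_distances(self, snp_ann: pd.DataFrame, probe_ann: pd.DataFrame,
                           cis_window: float = 1e6, trans_min: float = 2.5e6) -> None:
        """Check every planted pair respects its intended cis/trans class."""
        snp = snp_ann.set_index("snp_id")
        probe = probe_ann.set_index("probe_id")
        for _, row in self.eqtl_pairs.iterrows():
            s, p = snp.loc[row.snp_id], probe.loc[row.probe_id]
            same = s["chrom"] == p["chrom"]
            dist = abs(int(s["pos"]) - int(p["start"])) if same else np.inf
            if row.klass == "cis" and not (same and dist < cis_window):
                raise AssertionError(f"pair {row.snp_id}-{row.probe_id} not cis")
            if row.klass == "trans" and dist <= trans_min:
                raise AssertionError(f"pair {row.snp_id}-{row.probe_id} not trans")
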