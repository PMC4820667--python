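"""Directional gene-set testing by residual-space rotation.

The test statistic is the mean moderated t over the signature genes, with
signs flipped so that genes expected to be "down" contribute positively
when concordant. The null distribution is generated by random rotations:
the data are transformed into the orthonormal effect space of the design
(one dimension for the contrast of interest plus the residual dimensions),
and the contrast direction is replaced by a uniformly random unit vector.
Rotation preserves gene-gene correlation, making the test self-contained
and valid for correlated sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr

from .de import ModerationParams, estimate_variance_prior

__all__ = ["SignatureSet", "RotationResult", "RotationTest",
           "derive_signature", "rotation_test", "enrichment_chisq"]


@dataclass
class SignatureSet:
    """Directional gene set: gene id -> "up"/"down", with provenance."""

    directions: pd.Series
    provenance: str = ""
    n_defined: int = 0
    n_measured: int = 0

    def __post_init__(self):
        if len(self.directions):
            bad = set(self.directions.unique()) - {"up", "down"}
            if bad:
                raise ValueError(f"directions must be 'up'/'down', got {bad}")
        if not self.n_defined:
            self.n_defined = len(self.directions)
        if not self.n_measured:
            self.n_measured = len(self.directions)

    def __len__(self) -> int:
        return len(self.directions)

    def restricted_to(self, universe) -> "SignatureSet":
        keep = self.directions[self.directions.index.isin(set(universe))]
        return SignatureSet(keep, self.provenance, self.n_defined, len(keep))

    def inverted(self) -> "SignatureSet":
        flipped = self.directions.map({"up": "down", "down": "up"})
        return SignatureSet(flipped, self.provenance + " [inverted]",
                            self.n_defined, self.n_measured)

    def to_frame(self) -> pd.DataFrame:
        return self.directions.rename("direction").rename_axis("gene").reset_index()


def derive_signature(reference_tables: list, fdr: float = 0.05, fc: float = 1.5,
                     measured_universe=None, provenance: str = "") -> SignatureSet:
    """Directional signature from reference DE tables (e.g. endotoxin tolerance).

    Each table needs ``log2_fc`` and ``fdr`` columns indexed by gene. Genes
    passing both thresholds in every table — with a consistent sign — are
    kept (intersection across references), then restricted to the measured
    universe. Returns an empty set with a warning when nothing passes.
    """
    if not reference_tables:
        raise ValueError("need at least one reference DE table")
    log_fc_min = np.log2(fc)
    per_table = []
    for tab in reference_tables:
        passing = tab[(tab["fdr"] < fdr) & (tab["log2_fc"].abs() > log_fc_min)]
        per_table.append(pd.Series(np.where(passing["log2_fc"] > 0, "up", "down"),
                                   index=passing.index))
    common = per_table[0]
    for other in per_table[1:]:
        shared = common.index.intersection(other.index)
        agree = shared[common.loc[shared] == other.loc[shared]]
        common = common.loc[agree]
    sig = SignatureSet(common, provenance=provenance, n_defined=len(common))
    if measured_universe is not None:
        sig = sig.restricted_to(measured_universe)
    if len(sig) == 0:
        warnings.warn("derived signature is empty")
    return sig


@dataclass
class RotationResult:
    statistic: float
    p_rotation: float
    n_rotations: int
    n_genes: int
    gene_t: pd.Series = field(default=None, repr=False)

    def summary(self) -> str:
        return (f"Rotation test: {self.n_genes} genes, signed mean moderated t = "
                f"{self.statistic:.3f}, p = {self.p_rotation:.3g} "
                f"({self.n_rotations} rotations)")


class RotationTest:
    """Directional rotation test of a signature in a two-group contrast.

    Parameters
    ----------
    values : probes x samples log2 expression
    design : samples x covariates DataFrame containing ``coef``
    signature : directional gene set (ids must match ``probe_ids``)
    probe_ids : row identifiers of ``values``
    """

    def __init__(self, values: np.ndarray, design: pd.DataFrame,
                 signature: SignatureSet, probe_ids, coef: str = "group"):
        if len(signature) == 0:
            raise ValueError("signature is empty")
        self.values = np.asarray(values, float)
        self.design = design
        self.signature = signature
        self.probe_ids = np.asarray(probe_ids, dtype=object)
        self.coef = coef

    def fit(self, n_rotations: int = 9999, seed: int = 0,
            prior: ModerationParams | None = None) -> RotationResult:
        if 0 < n_rotations < 99:
            raise ValueError("n_rotations < 99 gives too coarse a p-value floor")
        cols = list(self.design.columns)
        # contrast column moved last so its effect is the first free dimension
        order = [c for c in cols if c != self.coef] + [self.coef]
        X = self.design[order].to_numpy(float)
        n, p = X.shape
        Q, R = qr(X, mode="full")
        if R[p - 1, p - 1] < 0:  # fix QR sign so u1 carries the contrast's sign
            Q[:, p - 1] *= -1.0
        # effects space: dimension 0 = contrast effect, 1.. = residual space
        E = self.values @ Q[:, p - 1:]
        d = E.shape[1]
        df = d - 1

        ss = np.einsum("ij,ij->i", E, E)
        u1 = E[:, 0]
        sigma2 = (ss - u1 ** 2) / df
        if prior is None:
            prior = estimate_variance_prior(np.maximum(sigma2, 1e-12), df)
        d0, s0sq = prior.d0, prior.s0sq

        sig = self.signature.restricted_to(self.probe_ids)
        if len(sig) == 0:
            raise ValueError("no signature genes present in the expression matrix")
        lookup = {g: i for i, g in enumerate(self.probe_ids)}
        rows = np.array([lookup[g] for g in sig.directions.index])
        signs = np.where(sig.directions.to_numpy() == "down", -1.0, 1.0)

        def mod_t(u1_g, ss_g):
            s2 = (ss_g - u1_g ** 2) / df
            if np.isinf(d0):
                s2_post = np.full_like(s2, s0sq)
            else:
                s2_post = (d0 * s0sq + df * s2) / (d0 + df)
            return u1_g / np.sqrt(np.maximum(s2_post, 1e-300))

        t_obs = mod_t(u1[rows], ss[rows])
        stat_obs = float(np.mean(signs * t_obs))
        gene_t = pd.Series(t_obs, index=sig.directions.index)
        if n_rotations == 0:
            return RotationResult(stat_obs, np.nan, 0, len(rows), gene_t)

        rng = np.random.default_rng(seed)
        U = E[rows]  # (G_sig, d)
        ss_sig = ss[rows]
        R = rng.standard_normal((n_rotations, d))
        R /= np.linalg.norm(R, axis=1, keepdims=True)
        U1 = R @ U.T  # (n_rotations, G_sig) rotated contrast effects
        s2_rot = (ss_sig[None, :] - U1 ** 2) / df
        if np.isinf(d0):
            s2_post = np.full_like(s2_rot, s0sq)
        else:
            s2_post = (d0 * s0sq + df * s2_rot) / (d0 + df)
        t_rot = U1 / np.sqrt(np.maximum(s2_post, 1e-300))
        stats_rot = (t_rot * signs[None, :]).mean(axis=1)
        p = (1.0 + np.sum(stats_rot >= stat_obs)) / (n_rotations + 1.0)
        return RotationResult(stat_obs, float(p), n_rotations, len(rows), gene_t)


def rotation_test(values, design, signature, probe_ids, n_rotations=9999,
                  seed=0, coef="group") -> RotationResult:
    return RotationTest(values, design, signature, probe_ids, coef).fit(
        n_rotations=n_rotations, seed=seed)


def enrichment_chisq(set_a, set_b, universe, continuity: bool = False) -> dict:
    """Pearson chi-square (1 df) for overlap of two sets within a universe.

    Returns the 2x2 table, chi-square statistic, p-value and odds ratio
    (Haldane 0.5 correction applied when a cell is empty).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    a = set(set_a) & universe
    b = set(set_b) & universe
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    table = np.array([[n11, n10], [n01, n00]], float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table {table.tolist()}: "
                         "a margin is empty (is one set the whole universe?)")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    t = table.copy()
    if (t == 0).any():
        t = t + 0.5
    odds_ratio = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    return {"table": table.astype(int), "chi2": float(chi2), "p": float(p),
            "odds_ratio": odds_ratio}
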