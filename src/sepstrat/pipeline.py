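"""End-to-end orchestration: simulate -> discover -> DE -> classify ->
gene-set -> eQTL -> marks -> survival, from one seeded configuration.

Each stage writes its outputs plus a manifest entry (config hash, input
file hashes, package version), so a rerun with the same configuration is
bit-identical and every number in the report traces to a stage output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .classifier import SparseSignatureModel, assign_srs
from .datatypes import CohortMetadata, ExpressionMatrix, GenotypeMatrix
from .de import DifferentialExpression, build_design
from .discovery import DiscoveryConfig, SrsDiscovery
from .epimarks import background_snps_near_probes, mark_enrichment
from .eqtl import (EqtlConfig, EqtlScan, classify_pairs, compute_expression_pcs,
                   lead_snp_per_probe, srs_specific_eqtl)
from .rotation import RotationTest, SignatureSet, enrichment_chisq
from .simulate import SimConfig, simulate_cohort
from .survival import compare_covariates, cox_fit, km_estimate, logrank_test, mortality_at

log = logging.getLogger(__name__)

STAGES = ("simulate", "discover", "de", "classify", "geneset", "eqtl",
          "epimarks", "survive")


def default_config(seed: int = 1, scale: float = 1.0) -> dict:
    """Demo pipeline configuration; ``scale`` shrinks the probe/SNP panels.

    The cohort keeps its full 265 samples at any scale: the within-group
    sum-of-squares elbow that fixes the number of SRS groups is calibrated
    to the cohort size, so only the feature dimensions are thinned for a
    fast demonstration.
    """
    return {
        "seed": seed,
        "simulate": {
            "n_samples": 265,
            "n_probes": max(2000, int(26_185 * scale)),
            "n_snps": max(800, int(3000 * scale)),
            "n_de_probes": max(200, int(3080 * scale)),
            "n_cis_eqtl": max(50, int(200 * scale)),
            "n_trans_eqtl": max(5, int(20 * scale)),
            "n_group_specific": max(4, int(20 * scale)),
        },
        "discover": {"variance_fraction": 0.10, "k_min": 2, "k_max": 4},
        "de": {"fc_threshold": 1.5, "fdr_threshold": 0.05, "adjust_cell_proportion": False},
        "classify": {"screen_top_k": 200, "loocv": True},
        "geneset": {"n_rotations": 9999, "signature_size": 150},
        "eqtl": {"n_pcs_main": 30, "n_pcs_group": 25, "n_random_pairs": 20000},
        "epimarks": {},
        "survive": {"horizons": [14, 28]},
        "stages": list(STAGES),
    }


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _hash_config(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


class PipelineRun:
    """Stateful runner writing one artifact directory."""

    def __init__(self, config: dict, outdir):
        if "seed" not in config:
            raise ValueError("pipeline config must set a seed")
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {"version": __version__, "config_hash": _hash_config(config),
                         "stages": {}}
        self.state: dict = {}

    # ------------------------------------------------------------- stages

    def stage_simulate(self):
        sim_kwargs = dict(self.config.get("simulate", {}))
        cfg = SimConfig(seed=self.config["seed"], **sim_kwargs)
        cohort = simulate_cohort(cfg)
        d = self.outdir
        io.write_expression(cohort.expression, d / "expression.tsv", d / "probes.tsv")
        io.write_genotypes_tsv(cohort.genotypes, d / "dosages.tsv", d / "snps.tsv")
        io.write_genotypes_vcf(cohort.genotypes, d / "genotypes.vcf")
        io.write_metadata(cohort.metadata, d / "metadata.tsv")
        io.write_truth(cohort.truth, d / "truth.json")
        marks = pd.concat([m.to_frame() for m in cohort.marks.values()])
        marks.to_csv(d / "marks.bed", sep="\t", header=False, index=False)
        self.state.update(expr=cohort.expression, geno=cohort.genotypes,
                          meta=cohort.metadata, truth=cohort.truth,
                          marks=cohort.marks, sim_config=cfg)
        return ["expression.tsv", "probes.tsv", "dosages.tsv", "snps.tsv",
                "genotypes.vcf", "metadata.tsv", "truth.json", "marks.bed"]

    def _require(self, *keys):
        missing = [k for k in keys if k not in self.state]
        if missing:
            raise RuntimeError(f"stage inputs missing: {missing} "
                               "(did an upstream stage run?)")

    def stage_discover(self):
        self._require("expr")
        cfg = DiscoveryConfig(**self.config.get("discover", {}))
        assignment = SrsDiscovery(self.state["expr"], cfg).fit()
        assignment.labels.rename("srs").to_frame().to_csv(
            self.outdir / "srs_labels.tsv", sep="\t", index_label="sample_id")
        pd.Series(assignment.wss_by_k, name="wss").rename_axis("k").to_frame().to_csv(
            self.outdir / "wss_by_k.tsv", sep="\t")
        pcs = compute_expression_pcs(self.state["expr"].values, 3)
        pd.DataFrame(pcs, index=self.state["expr"].sample_ids,
                     columns=["PC1", "PC2", "PC3"]).join(
            assignment.labels).to_csv(self.outdir / "pcs.tsv", sep="\t",
                                      index_label="sample_id")
        self.state["srs"] = assignment
        (self.outdir / "discovery_summary.txt").write_text(assignment.summary() + "\n")
        return ["srs_labels.tsv", "wss_by_k.tsv", "pcs.tsv", "discovery_summary.txt"]

    def stage_de(self):
        self._require("expr", "srs")
        opts = self.config.get("de", {})
        covariates = None
        if opts.get("adjust_cell_proportion") and "meta" in self.state:
            covariates = self.state["meta"].table[["neutrophil_prop"]]
        model = DifferentialExpression.from_expression(
            self.state["expr"], self.state["srs"].labels, covariates)
        res = model.fit(opts.get("fc_threshold", 1.5), opts.get("fdr_threshold", 0.05))
        res.table.to_csv(self.outdir / "de_table.tsv", sep="\t")
        self.state["de"] = res
        (self.outdir / "de_summary.txt").write_text(res.summary() + "\n")
        return ["de_table.tsv", "de_summary.txt"]

    def stage_classify(self):
        self._require("expr", "srs")
        opts = self.config.get("classify", {})
        expr = self.state["expr"]
        feats = pd.DataFrame(expr.values.T, index=expr.sample_ids,
                             columns=expr.probe_ids)
        sm = SparseSignatureModel(
            feats, self.state["srs"].labels, positive_class="SRS1",
            screen_top_k=opts.get("screen_top_k", 200),
            max_support=opts.get("max_support"),
            seed=self.config["seed"],
        )
        model = sm.fit()
        (self.outdir / "classifier_model.json").write_text(
            json.dumps(model.to_dict(), indent=1))
        preds = assign_srs(feats, model)
        preds.to_csv(self.outdir / "classifier_predictions.tsv", sep="\t",
                     index_label="sample_id")
        outputs = ["classifier_model.json", "classifier_predictions.tsv"]
        if opts.get("loocv", True):
            cv = sm.loocv()
            (self.outdir / "classifier_loocv.txt").write_text(cv.summary() + "\n")
            self.state["cv"] = cv
            outputs.append("classifier_loocv.txt")
        self.state["classifier"] = model
        return outputs

    def stage_geneset(self):
        self._require("expr", "srs", "de")
        opts = self.config.get("geneset", {})
        truth = self.state.get("truth")
        de_table = self.state["de"].table
        if truth is not None:
            # reference signature: the planted downregulated program acts as
            # the endotoxin-tolerance-style reference gene set
            down = truth.de_effects[truth.de_effects < 0]
            size = min(opts.get("signature_size", 150), len(down))
            sig = SignatureSet(pd.Series("down", index=down.index[:size]),
                               provenance="planted downregulated program")
        else:
            called = de_table[de_table["called"]]
            sig = SignatureSet(
                pd.Series(np.where(called["log2_fc"] < 0, "down", "up"),
                          index=called.index),
                provenance="called DE probes")
        expr = self.state["expr"]
        design = build_design(self.state["srs"].labels.loc[list(expr.sample_ids)])
        res = RotationTest(expr.values, design, sig, expr.probe_ids).fit(
            n_rotations=opts.get("n_rotations", 9999), seed=self.config["seed"])
        sig.to_frame().to_csv(self.outdir / "signature.tsv", sep="\t", index=False)
        (self.outdir / "rotation_result.txt").write_text(res.summary() + "\n")
        self.state["rotation"] = res
        self.state["signature"] = sig
        return ["signature.tsv", "rotation_result.txt"]

    def stage_eqtl(self):
        self._require("expr", "geno", "srs")
        opts = self.config.get("eqtl", {})
        cfg = EqtlConfig(n_pcs_main=opts.get("n_pcs_main", 30),
                         n_pcs_group=opts.get("n_pcs_group", 25))
        expr, geno = self.state["expr"], self.state["geno"]
        rng = np.random.default_rng(self.config["seed"] + 1)
        n_rand = opts.get("n_random_pairs", 20000)
        pairs = pd.DataFrame({
            "snp_id": rng.choice(geno.snp_ids, n_rand),
            "probe_id": rng.choice(expr.probe_ids, n_rand),
        }).drop_duplicates()
        truth = self.state.get("truth")
        if truth is not None:
            pairs = pd.concat([truth.eqtl_pairs[["snp_id", "probe_id"]], pairs])
            pairs = pairs.drop_duplicates()
        classed = classify_pairs(geno.snp_annotation(), expr.probe_annotation(),
                                 cfg, pairs)
        pcs = compute_expression_pcs(expr.values, cfg.n_pcs_main)
        res = EqtlScan(expr, geno, classed, pcs, cfg).fit()
        res.records.to_csv(self.outdir / "eqtl_records.tsv", sep="\t", index=False)
        (self.outdir / "eqtl_summary.txt").write_text(res.summary() + "\n")
        self.state["eqtl"] = res

        # per-group scans for SRS-specific calling
        labels = self.state["srs"].labels
        group_results = {}
        for gname in ("SRS1", "SRS2"):
            m = (labels.loc[list(expr.sample_ids)] == gname).to_numpy()
            sub_expr = ExpressionMatrix(expr.values[:, m], expr.probe_ids,
                                        expr.probe_chrom, expr.probe_start,
                                        expr.sample_ids[m])
            sub_geno = GenotypeMatrix(geno.dosages[:, m], geno.snp_ids,
                                      geno.snp_chrom, geno.snp_pos, geno.maf,
                                      geno.sample_ids[m])
            n_pcs = min(cfg.n_pcs_group, int(m.sum()) - 2)
            sub_pcs = compute_expression_pcs(sub_expr.values, n_pcs)
            cis_only = classed[classed["klass"] == "cis"]
            group_results[gname] = EqtlScan(sub_expr, sub_geno, cis_only,
                                            sub_pcs, cfg).fit()
        spec = srs_specific_eqtl(group_results["SRS1"].records,
                                 group_results["SRS2"].records, cfg)
        spec.to_csv(self.outdir / "eqtl_srs_specific.tsv", sep="\t", index=False)
        self.state["eqtl_specific"] = spec
        self.state["eqtl_groups"] = group_results

        if self.state.get("de") is not None:
            de_called = set(self.state["de"].table[self.state["de"].table["called"]].index)
            cis_sig_probes = set(res.significant("cis")["probe_id"])
            universe = set(expr.probe_ids)
            try:
                enr = enrichment_chisq(cis_sig_probes, de_called, universe)
                (self.outdir / "eqtl_de_enrichment.txt").write_text(
                    f"cis-eQTL genes x DE genes: chi2={enr['chi2']:.2f} "
                    f"p={enr['p']:.3g} OR={enr['odds_ratio']:.2f}\n")
            except ValueError as e:
                log.warning("eQTL/DE enrichment skipped: %s", e)
        return ["eqtl_records.tsv", "eqtl_summary.txt", "eqtl_srs_specific.tsv"]

    def stage_epimarks(self):
        self._require("eqtl", "geno", "expr")
        leads = self.state["eqtl"].lead_per_probe("cis")
        leads = leads[leads["fdr"] < self.state["eqtl"].config.fdr_cis]
        snp_ann = self.state["geno"].snp_annotation().set_index("snp_id")
        fg = snp_ann.loc[leads["snp_id"].unique()].reset_index()
        bg = background_snps_near_probes(self.state["geno"].snp_annotation(),
                                         self.state["expr"].probe_annotation())
        rows = []
        for name, ivset in self.state.get("marks", {}).items():
            r = mark_enrichment(fg, bg, ivset)
            rows.append(dataclasses.asdict(r))
        tab = pd.DataFrame(rows)
        tab.to_csv(self.outdir / "mark_enrichment.tsv", sep="\t", index=False)
        self.state["mark_enrichment"] = tab
        return ["mark_enrichment.tsv"]

    def stage_survive(self):
        self._require("meta", "srs")
        meta = self.state["meta"].table
        labels = self.state["srs"].labels.loc[meta.index]
        horizons = self.config.get("survive", {}).get("horizons", [14, 28])
        km = km_estimate(meta["time"], meta["event"], labels)
        for g, curve in km.items():
            curve.to_frame().to_csv(self.outdir / f"km_{g}.tsv", sep="\t", index=False)
        chi2, p = logrank_test(meta["time"], meta["event"], labels)
        cox = cox_fit(meta["time"], meta["event"],
                      pd.DataFrame({"srs1": (labels == "SRS1").astype(float)}))
        parts = [f"log-rank chi2={chi2:.3f} p={p:.3g}", cox.summary()]
        mort_frames = []
        for h in horizons:
            mt = mortality_at(meta["time"], meta["event"], labels, h)
            mt.insert(0, "horizon_days", h)
            mort_frames.append(mt)
        pd.concat(mort_frames).to_csv(self.outdir / "mortality.tsv", sep="\t",
                                      index=False)
        cov_cols = [c for c in meta.columns if c not in ("time", "event", "srs")]
        comparison = compare_covariates(meta[cov_cols], labels)
        comparison.to_csv(self.outdir / "covariate_comparison.tsv", sep="\t",
                          index=False)
        (self.outdir / "survival_summary.txt").write_text("\n".join(parts) + "\n")
        self.state["cox"] = cox
        self.state["logrank"] = (chi2, p)
        return ["mortality.tsv", "covariate_comparison.tsv", "survival_summary.txt"]

    # ---------------------------------------------------------------- run

    def run(self) -> Path:
        enabled = self.config.get("stages", list(STAGES))
        for stage in STAGES:
            if stage not in enabled:
                self.manifest["stages"][stage] = {"status": "disabled"}
                continue
            try:
                outputs = getattr(self, f"stage_{stage}")()
            except Exception as e:
                self.manifest["stages"][stage] = {"status": "FAILED", "error": str(e)}
                self._write_manifest()
                (self.outdir / "FAILED").write_text(f"{stage}: {e}\n")
                raise
            self.manifest["stages"][stage] = {
                "status": "ok",
                "outputs": {f: _hash_file(self.outdir / f) for f in outputs},
            }
        self._write_manifest()
        return self.outdir

    def _write_manifest(self):
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True))


def run_pipeline(config: dict, outdir) -> PipelineRun:
    run = PipelineRun(config, outdir)
    run.run()
    return run


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_report(artifact_dir, truth_available: bool | None = None) -> Path:
    """Markdown report assembled from the stage outputs in ``artifact_dir``."""
    d = Path(artifact_dir)
    manifest = json.loads((d / "manifest.json").read_text()) \
        if (d / "manifest.json").exists() else {"stages": {}}
    lines = ["# sepstrat pipeline report", ""]

    def section(title, stage, body_fn):
        lines.append(f"## {title}")
        status = manifest["stages"].get(stage, {}).get("status")
        if status != "ok":
            lines.append(f"_not run_ (status: {status})")
            lines.append("")
            return
        try:
            body_fn()
        except FileNotFoundError as e:
            lines.append(f"_output missing: {e}_")
        lines.append("")

    def disc():
        lines.append("```")
        lines.append((d / "discovery_summary.txt").read_text().rstrip())
        lines.append("```")
        pcs = pd.read_csv(d / "pcs.tsv", sep="\t")
        lines.append(f"First 3 PCs exported for {len(pcs)} samples (pcs.tsv).")

    def de():
        lines.append("```")
        lines.append((d / "de_summary.txt").read_text().rstrip())
        lines.append("```")

    def classify():
        model = json.loads((d / "classifier_model.json").read_text())
        lines.append(f"Selected features: {', '.join(model['selected_features'])}")
        if (d / "classifier_loocv.txt").exists():
            lines.append((d / "classifier_loocv.txt").read_text().rstrip())

    def geneset():
        lines.append((d / "rotation_result.txt").read_text().rstrip())

    def eqtl():
        lines.append("```")
        lines.append((d / "eqtl_summary.txt").read_text().rstrip())
        lines.append("```")
        spec = pd.read_csv(d / "eqtl_srs_specific.tsv", sep="\t")
        counts = spec["call"].value_counts().to_dict()
        lines.append(f"SRS-specific calls: {counts}")

    def marks():
        tab = pd.read_csv(d / "mark_enrichment.tsv", sep="\t")
        lines.append(tab.to_markdown(index=False))

    def survive():
        lines.append("```")
        lines.append((d / "survival_summary.txt").read_text().rstrip())
        lines.append("```")
        mort = pd.read_csv(d / "mortality.tsv", sep="\t")
        lines.append(mort.to_markdown(index=False))

    section("SRS discovery", "discover", disc)
    section("Differential expression", "de", de)
    section("Gene-signature classifier", "classify", classify)
    section("Gene-set rotation test", "geneset", geneset)
    section("eQTL mapping", "eqtl", eqtl)
    section("Epigenetic-mark enrichment", "epimarks", marks)
    section("Survival by SRS group", "survive", survive)

    truth_path = d / "truth.json"
    if truth_available is None:
        truth_available = truth_path.exists()
    if truth_available and truth_path.exists():
        lines.append("## Recovery vs planted truth")
        truth = io.read_truth(truth_path)
        labels = pd.read_csv(d / "srs_labels.tsv", sep="\t", index_col="sample_id")["srs"]
        from sklearn.metrics import adjusted_rand_score
        ari = adjusted_rand_score(truth.group_of_sample.loc[labels.index], labels)
        lines.append(f"- Clustering ARI vs planted groups: {ari:.3f}")
        if (d / "eqtl_records.tsv").exists():
            rec = pd.read_csv(d / "eqtl_records.tsv", sep="\t")
            cis = rec[rec["klass"] == "cis"]
            sig = cis[cis["fdr"] < 0.05]
            planted = truth.eqtl_pairs.query(
                "klass == 'cis' and group_restriction == 'both'")
            planted_keys = set(zip(planted["snp_id"], planted["probe_id"]))
            any_planted = set(zip(truth.eqtl_pairs["snp_id"], truth.eqtl_pairs["probe_id"]))
            found = set(zip(sig["snp_id"], sig["probe_id"]))
            sens = len(planted_keys & found) / len(planted_keys) if planted_keys else np.nan
            fp = len(found - any_planted)
            efdr = fp / len(found) if found else 0.0
            lines.append(f"- cis-eQTL sensitivity (unrestricted planted pairs, FDR<0.05): {sens:.3f}")
            lines.append(f"- cis-eQTL empirical FDR: {efdr:.3f}")
        lines.append("")
    out = d / "report.md"
    out.write_text("\n".join(lines))
    return out
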