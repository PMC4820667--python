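"""Readers and writers for the plain-text formats used by the pipeline.

Conventions: expression/genotype/annotation tables are tab-separated with a
header row; genomic coordinates are 1-based in TSV and VCF, 0-based
half-open in BED. Genotypes round-trip either as a dosage TSV or as a
minimal VCF v4.2 with GT fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CohortMetadata, ExpressionMatrix, GenotypeMatrix, IntervalSet, SimTruth


# ---------------------------------------------------------------- expression

def write_expression(expr: ExpressionMatrix, values_path, annotation_path=None) -> None:
    expr.to_frame().to_csv(values_path, sep="\t", index_label="probe_id")
    if annotation_path is not None:
        expr.probe_annotation().to_csv(annotation_path, sep="\t", index=False)


def read_expression(values_path, annotation_path=None) -> ExpressionMatrix:
    df = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t").set_index("probe_id").loc[df.index]
        chrom, start = ann["chrom"].to_numpy(), ann["start"].to_numpy()
    else:
        chrom = np.array(["chrUn"] * len(df), dtype=object)
        start = np.ones(len(df), dtype=np.int64)
    return ExpressionMatrix(
        values=df.to_numpy(float),
        probe_ids=df.index.to_numpy(),
        probe_chrom=chrom,
        probe_start=start,
        sample_ids=df.columns.to_numpy(),
    )


# ----------------------------------------------------------------- genotypes

def write_genotypes_tsv(geno: GenotypeMatrix, dosage_path, annotation_path=None) -> None:
    pd.DataFrame(geno.dosages, index=geno.snp_ids, columns=geno.sample_ids).to_csv(
        dosage_path, sep="\t", index_label="snp_id"
    )
    if annotation_path is not None:
        geno.snp_annotation().to_csv(annotation_path, sep="\t", index=False)


def read_genotypes_tsv(dosage_path, annotation_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col="snp_id")
    ann = pd.read_csv(annotation_path, sep="\t").set_index("snp_id").loc[df.index]
    return GenotypeMatrix(
        dosages=df.to_numpy(np.int8),
        snp_ids=df.index.to_numpy(),
        snp_chrom=ann["chrom"].to_numpy(),
        snp_pos=ann["pos"].to_numpy(),
        maf=ann["maf"].to_numpy(),
        sample_ids=df.columns.to_numpy(),
    )


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with GT genotypes (REF=A, ALT=G placeholders)."""
    chroms = sorted(set(geno.snp_chrom), key=str)
    order = np.lexsort((geno.snp_pos, np.array([chroms.index(c) for c in geno.snp_chrom])))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sepstrat\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, geno.sample_ids)) + "\n")
        for i in order:
            gts = "\t".join(_GT_CODE[int(d)] for d in geno.dosages[i])
            fh.write(
                f"{geno.snp_chrom[i]}\t{geno.snp_pos[i]}\t{geno.snp_ids[i]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read a plain-text VCF with GT fields back into dosages."""
    snp_ids, chroms, poss, rows = [], [], [], []
    samples = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            snp_ids.append(parts[2])
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            dos = []
            for field in parts[9:]:
                gt = field.split(":")[gt_i].replace("|", "/")
                dos.append(sum(int(a) for a in gt.split("/")))
            rows.append(dos)
    dosages = np.asarray(rows, dtype=np.int8)
    p = dosages.mean(axis=1) / 2.0
    maf = np.minimum(np.clip(p, 1e-6, None), np.clip(1 - p, 1e-6, None))
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array(snp_ids, dtype=object),
        snp_chrom=np.array(chroms, dtype=object),
        snp_pos=np.array(poss, dtype=np.int64),
        maf=np.minimum(maf, 0.5),
        sample_ids=np.array(samples, dtype=object),
    )


# ------------------------------------------------------------------ metadata

def write_metadata(meta: CohortMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> CohortMetadata:
    return CohortMetadata(pd.read_csv(path, sep="\t", index_col="sample_id"))


# ----------------------------------------------------------------------- BED

def write_bed(marks: IntervalSet, path) -> None:
    marks.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, mark_name=None) -> dict:
    """Read a BED3+name file into {mark_name: IntervalSet}.

    Files without a name column yield a single set named ``mark_name``
    (default "mark").
    """
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 3:
        raise ValueError("BED needs at least chrom/start/end columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["name"] = df[3] if df.shape[1] > 3 else (mark_name or "mark")
    out = {}
    for name, grp in df.groupby("name", sort=True):
        ivals = {
            str(chrom): sub[["start", "end"]].to_numpy(np.int64)
            for chrom, sub in grp.groupby("chrom", sort=True)
        }
        out[str(name)] = IntervalSet(ivals, mark_name=str(name))
    return out


# ---------------------------------------------------------------- sim truth

def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "group_of_sample": truth.group_of_sample.to_dict(),
        "de_effects": truth.de_effects.to_dict(),
        "eqtl_pairs": truth.eqtl_pairs.to_dict(orient="list"),
        "variance_prior": list(truth.variance_prior),
        "hazard_ratio_true": truth.hazard_ratio_true,
        "confounder": None if truth.confounder is None else truth.confounder.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    conf = payload.get("confounder")
    return SimTruth(
        group_of_sample=pd.Series(payload["group_of_sample"]),
        de_effects=pd.Series(payload["de_effects"], dtype=float),
        eqtl_pairs=pd.DataFrame(payload["eqtl_pairs"]),
        variance_prior=tuple(payload["variance_prior"]),
        hazard_ratio_true=payload["hazard_ratio_true"],
        confounder=None if conf is None else pd.Series(conf, dtype=float),
    )
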