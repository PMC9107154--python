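"""Readers and writers for every study object.

All formats are plain text: VCF 4.2 (GT only) or a TSV dosage matrix for
genotypes; TSV count/abundance matrices with a header row of sample ids; a
BED-like methylation TSV (chrom, 1-based position, strand, then
coverage_<sample> and methCount_<sample> columns); sample-sheet, annotation
and truth TSVs; YAML config echo for provenance.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    FeatureMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    SampleSheet,
    StudyBundle,
    ValidationError,
    check_aligned,
    site_id,
)

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        for j, row in genotypes.variants.reset_index(drop=True).iterrows():
            gts = "\t".join(_GT[int(d)] for d in genotypes.dosages[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path, multiallelic: str = "reject") -> GenotypeMatrix:
    """Parse a VCF into a dosage matrix (GT -> alt-allele count).

    Multi-allelic records are rejected (default) or skipped per
    ``multiallelic``; malformed genotypes are rejected with the line number.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            if multiallelic == "skip":
                continue
            raise ValidationError(
                f"multi-allelic record at line {i + 1} ({rec.CHROM}:{rec.POS}); "
                "split or set multiallelic='skip'")
        gt = rec.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        if (gt == 2).any():
            raise ValidationError(f"missing genotype at {rec.CHROM}:{rec.POS}")
        dos = np.where(gt == 3, 2, gt).astype(np.int8)
        cols.append(dos)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        af = float(dos.mean() / 2.0)
        rows.append({"id": vid, "chrom": str(rec.CHROM), "pos": int(rec.POS),
                     "ref": rec.REF, "alt": rec.ALT[0], "af": af})
    gm = GenotypeMatrix(samples=samples, dosages=np.array(cols).T,
                        variants=pd.DataFrame(rows))
    gm.validate()
    return gm


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosages.T, index=genotypes.variants["id"],
                      columns=genotypes.samples)
    df.index.name = "variant"
    df.to_csv(path, sep="\t")
    meta = Path(str(path) + ".variants")
    genotypes.variants.to_csv(meta, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = Path(str(path) + ".variants")
    if meta_path.exists():
        variants = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
    else:
        variants = pd.DataFrame({"id": df.index, "chrom": "0",
                                 "pos": np.arange(1, len(df) + 1),
                                 "ref": "A", "alt": "G", "af": np.nan})
    gm = GenotypeMatrix(samples=list(df.columns),
                        dosages=df.to_numpy(dtype=np.int8).T, variants=variants)
    gm.validate()
    return gm


def write_matrix_tsv(fm: FeatureMatrix, path: str | Path) -> None:
    """Counts / abundance matrix, features in rows, sample-id header."""
    fm.values.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path, samples: list[str]) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    check_aligned(samples, df.columns, f"expression file {path}")
    return FeatureMatrix(layer="expression", samples=samples, values=df,
                         feature_meta=pd.DataFrame({"gene_id": df.index}, index=df.index))


def read_metabolite_tsv(path: str | Path, samples: list[str]) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    check_aligned(samples, df.columns, f"metabolite file {path}")
    return FeatureMatrix(layer="metabolite", samples=samples, values=df,
                         feature_meta=pd.DataFrame({"metabolite": df.index}, index=df.index))


def write_methylation_tsv(fm: FeatureMatrix, path: str | Path) -> None:
    meta = fm.feature_meta
    out = pd.DataFrame({
        "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(),
        "strand": meta["strand"].to_numpy(),
    }, index=fm.coverage.index)
    for s in fm.samples:
        out[f"coverage_{s}"] = fm.coverage[s].to_numpy()
    for s in fm.samples:
        out[f"methCount_{s}"] = fm.methylated[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path: str | Path, samples: list[str]) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cov_cols = [c for c in df.columns if c.startswith("coverage_")]
    met_cols = [c for c in df.columns if c.startswith("methCount_")]
    file_samples = [c[len("coverage_"):] for c in cov_cols]
    check_aligned(samples, file_samples, f"methylation file {path}")
    ids = [site_id(c, p) for c, p in zip(df["chrom"], df["pos"])]
    idx = pd.Index(ids, name="site_id")
    coverage = pd.DataFrame(df[cov_cols].to_numpy(), index=idx, columns=file_samples)
    methylated = pd.DataFrame(df[met_cols].to_numpy(), index=idx, columns=file_samples)
    meta = pd.DataFrame({"site_id": ids, "chrom": df["chrom"].to_numpy(),
                         "pos": df["pos"].to_numpy(), "strand": df["strand"].to_numpy()},
                        index=idx)
    return FeatureMatrix(layer="methylation", samples=samples, coverage=coverage,
                         methylated=methylated, feature_meta=meta)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path, covariates: tuple[str, ...] = ("exercise",)) -> SampleSheet:
    table = pd.read_csv(path, sep="\t", index_col=0)
    sheet = SampleSheet(table=table, covariates=covariates)
    sheet.validate()
    return sheet


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> GeneAnnotation:
    ann = GeneAnnotation(pd.read_csv(path, sep="\t", dtype={"chrom": str}))
    ann.validate()
    return ann


def write_truth(truth, path: str | Path) -> None:
    """Planted effects as one tidy TSV (kind, variant/source, layer, feature, beta)."""
    rows = []
    for q in truth.qtl_effects:
        rows.append({"kind": "qtl", "source": q.variant, "layer": q.layer,
                     "feature": q.feature, "beta": q.beta})
    for e in truth.causal_edges:
        rows.append({"kind": "edge", "source": f"{e.source[0]}:{e.source[1]}",
                     "layer": e.target[0], "feature": e.target[1], "beta": e.beta})
    for (layer, feat), b in truth.group_effects.items():
        rows.append({"kind": "group", "source": "group", "layer": layer,
                     "feature": feat, "beta": b})
    for (cov, (layer, feat)), b in truth.covariate_effects.items():
        rows.append({"kind": "covariate", "source": cov, "layer": layer,
                     "feature": feat, "beta": b})
    pd.DataFrame(rows, columns=["kind", "source", "layer", "feature", "beta"]).to_csv(
        path, sep="\t", index=False)


def write_bundle(bundle: StudyBundle, outdir: str | Path, vcf: bool = True) -> dict[str, str]:
    """Write every generated object; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": str(outdir / ("genotypes.vcf" if vcf else "genotypes.tsv")),
        "expression": str(outdir / "expression_counts.tsv"),
        "methylation": str(outdir / "methylation.tsv"),
        "metabolite": str(outdir / "metabolites.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "annotation": str(outdir / "gene_tss.tsv"),
    }
    if vcf:
        write_vcf(bundle.genotypes, paths["genotypes"])
    else:
        write_dosage_tsv(bundle.genotypes, paths["genotypes"])
    write_matrix_tsv(bundle.expression, paths["expression"])
    write_methylation_tsv(bundle.methylation, paths["methylation"])
    write_matrix_tsv(bundle.metabolite, paths["metabolite"])
    write_sample_sheet(bundle.sheet, paths["samples"])
    write_annotation(bundle.annotation, paths["annotation"])
    if bundle.truth is not None:
        paths["truth"] = str(outdir / "truth.tsv")
        write_truth(bundle.truth, paths["truth"])
    if bundle.provenance:
        paths["config"] = str(outdir / "config_echo.yml")
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(bundle.provenance, fh, sort_keys=True)
    return paths


def load_study_bundle(paths: dict[str, str] | str | Path,
                      covariates: tuple[str, ...] = ("exercise",)) -> StudyBundle:
    """Load a bundle from a path map or a directory written by write_bundle.

    Validates cross-file sample consistency; any mismatch is rejected naming
    the offending samples.
    """
    if not isinstance(paths, dict):
        d = Path(paths)
        geno = d / "genotypes.vcf"
        paths = {
            "genotypes": str(geno if geno.exists() else d / "genotypes.tsv"),
            "expression": str(d / "expression_counts.tsv"),
            "methylation": str(d / "methylation.tsv"),
            "metabolite": str(d / "metabolites.tsv"),
            "samples": str(d / "samples.tsv"),
            "annotation": str(d / "gene_tss.tsv"),
        }
    for key, p in paths.items():
        if not os.path.exists(p):
            raise ValidationError(f"missing {key} file: {p}")
    sheet = read_sample_sheet(paths["samples"], covariates=covariates)
    samples = sheet.samples
    if str(paths["genotypes"]).endswith((".vcf", ".vcf.gz")):
        genotypes = read_vcf(paths["genotypes"])
    else:
        genotypes = read_dosage_tsv(paths["genotypes"])
    check_aligned(samples, genotypes.samples, "genotype file")
    bundle = StudyBundle(
        genotypes=genotypes,
        expression=read_expression_tsv(paths["expression"], samples),
        methylation=read_methylation_tsv(paths["methylation"], samples),
        metabolite=read_metabolite_tsv(paths["metabolite"], samples),
        sheet=sheet,
        annotation=read_annotation(paths["annotation"]),
    )
    bundle.validate()
    return bundle
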