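"""File interfaces: minimal VCF, phenotype/depth TSVs, truth JSON, YAML.

The genotype VCF is the minimal VCFv4.2 subset the analysis needs
(CHROM/POS/REF/ALT plus GT), written as plain text and read back with
pysam.  Dosage is the number of alternate alleles in the GT call; any
missing allele makes the call missing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
import yaml

from .containers import DepthMatrix, GenotypeMatrix

_GT_FROM_DOSAGE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    sites, dosage = genotypes.sites, genotypes.dosage
    contigs = dict(contig_lengths or {})
    for sc, pos in zip(sites["supercontig"], sites["position"]):
        contigs[sc] = max(contigs.get(sc, 0), int(pos) + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        for site_id, row in sites.iterrows():
            calls = [
                _GT_FROM_DOSAGE.get(d, "./.") if not np.isnan(d) else "./."
                for d in dosage.loc[site_id].to_numpy(dtype=float)
            ]
            fh.write("\t".join([
                str(row["supercontig"]), str(int(row["position"])),
                str(site_id), row["ref"], row["alt"], ".", "PASS", ".", "GT",
            ] + calls) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    site_rows, dosage_rows = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            site_rows.append({
                "site_id": f"{rec.chrom}:{rec.pos}",
                "supercontig": rec.chrom,
                "position": rec.pos,
                "ref": rec.ref,
                "alt": ",".join(rec.alts or ()),
            })
            row = []
            for sample in samples:
                alleles = rec.samples[sample]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    row.append(np.nan)
                else:
                    row.append(float(sum(1 for a in alleles if a > 0)))
            dosage_rows.append(row)
    sites = pd.DataFrame(site_rows).set_index("site_id")
    dosage = pd.DataFrame(dosage_rows, index=sites.index, columns=samples,
                          dtype=float)
    return GenotypeMatrix(sites=sites, dosage=dosage)


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="sample")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_depths(depths: DepthMatrix, counts_path: str | Path,
                 bed_path: str | Path | None = None) -> None:
    depths.counts.to_csv(counts_path, sep="\t", index_label="amplicon_id")
    if bed_path is not None:
        write_amplicon_bed(depths.amplicons, bed_path)


def read_depths(counts_path: str | Path,
                bed_path: str | Path) -> DepthMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="amplicon_id")
    amplicons = read_amplicon_bed(bed_path).reindex(counts.index)
    if amplicons["length"].isna().any():
        raise ValueError("amplicon BED does not cover all counted amplicons")
    return DepthMatrix(amplicons=amplicons, counts=counts)


def write_amplicon_bed(amplicons: pd.DataFrame, path: str | Path) -> None:
    """BED (0-based half-open): chrom, start, end, name, score=pool, gene."""
    with open(path, "w") as fh:
        for amp_id, row in amplicons.iterrows():
            fh.write("\t".join(map(str, [
                row["supercontig"], int(row["start"]), int(row["end"]),
                amp_id, int(row.get("pool", 0)), row["gene_id"],
            ])) + "\n")


def read_amplicon_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["supercontig", "start", "end", "amplicon_id",
                            "pool", "gene_id"],
                     dtype={"supercontig": str})
    df = df.set_index("amplicon_id")
    df["length"] = df["end"] - df["start"]
    return df[["supercontig", "start", "end", "gene_id", "length", "pool"]]


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """qPCR Cq table: sample, gene, role in {target, reference}, replicate, cq."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "role", "replicate", "cq"}
    if missing := required - set(df.columns):
        raise ValueError(f"qPCR table missing columns {sorted(missing)}")
    if bad := set(df["role"]) - {"target", "reference"}:
        raise ValueError(f"qPCR roles must be target/reference, got {bad}")
    return df


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config_yaml(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
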