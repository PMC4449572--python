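"""Readers and writers for the pipeline's file formats.

Plain-text formats throughout: pedigree/phenotype/effects tables as CSV,
genotypes either as a 0/1/2 matrix CSV with a companion map or as
PLINK-style .ped/.map, regions as BED (0-based half-open) plus a 1-based
summary CSV, gene annotation from GFF3 or BED (parsed with pyranges),
ground truth and reports as JSON, configuration as YAML.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import GenotypeMatrix, PedigreeTable, TrajectoryRecordSet

__all__ = [
    "write_pedigree_csv", "read_pedigree_csv",
    "write_phenotype_csv", "read_phenotype_csv",
    "write_genotype_csv", "read_genotype_csv",
    "write_plink", "read_plink",
    "write_ground_truth", "read_annotation",
    "write_regions_bed", "load_config", "dump_config",
]


def write_pedigree_csv(ped: PedigreeTable, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path) -> PedigreeTable:
    return PedigreeTable.from_frame(pd.read_csv(path))


def write_phenotype_csv(records: TrajectoryRecordSet, path) -> None:
    records.df.to_csv(path, index=False)


def read_phenotype_csv(path) -> TrajectoryRecordSet:
    return TrajectoryRecordSet(pd.read_csv(path))


def write_genotype_csv(geno: GenotypeMatrix, path, map_path) -> None:
    df = pd.DataFrame(geno.codes, columns=geno.snp_map["snp_id"])
    df.insert(0, "animal", geno.animal)
    df.to_csv(path, index=False)
    geno.snp_map.to_csv(map_path, index=False)


def read_genotype_csv(path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    snp_map = pd.read_csv(map_path)
    codes = df[snp_map["snp_id"]].to_numpy(dtype=np.int8)
    return GenotypeMatrix(df["animal"].to_numpy(), codes, snp_map)


_ALLELES = ("A", "B")


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """PLINK-style .ped/.map; code 0 -> 'A A', 1 -> 'A B', 2 -> 'B B',
    missing -> '0 0'."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for a, row in zip(geno.animal, geno.codes):
            fields = [str(a), str(a), "0", "0", "0", "-9"]
            for c in row:
                if c < 0:
                    fields.extend(("0", "0"))
                else:
                    fields.extend((_ALLELES[min(c, 1)], _ALLELES[0 if c < 2 else 1]))
            fh.write(" ".join(fields) + "\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in geno.snp_map.iterrows():
            fh.write(f"{r['chrom']}\t{r['snp_id']}\t0\t{r['pos']}\n")


def read_plink(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"), sep="\t", header=None,
        names=["chrom", "snp_id", "cm", "pos"],
    )[["snp_id", "chrom", "pos"]]
    animals, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            animals.append(int(fields[1]))
            al = fields[6:]
            pairs = zip(al[0::2], al[1::2])
            row = [
                -1 if a == "0" else (a != _ALLELES[0]) + (b != _ALLELES[0])
                for a, b in pairs
            ]
            rows.append(row)
    return GenotypeMatrix(
        np.asarray(animals), np.asarray(rows, dtype=np.int8), snp_map
    )


def write_ground_truth(truth, path) -> None:
    payload = {
        "u_polygenic": truth.u_polygenic.tolist(),
        "u_qtl": truth.u_qtl.tolist(),
        "pe": truth.pe.tolist(),
        "qtl_effects": [list(q) for q in truth.qtl_effects],
        "qtl_snp_index": truth.qtl_snp_index.tolist(),
        "genetic_cov": truth.genetic_cov.tolist(),
        "pe_cov": truth.pe_cov.tolist(),
        "resid_var": truth.resid_var,
        "cg_effects": truth.cg_effects.tolist(),
        "parity_effects": truth.parity_effects.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_annotation(path) -> pd.DataFrame:
    """Gene features from GFF3 or BED as a frame with 0-based half-open
    coordinates: columns chrom, start, end, gene_id, gene_name."""
    import pyranges as pr

    path = str(path)
    if path.endswith((".gff3", ".gff", ".gff3.gz")):
        df = pr.read_gff3(path).df
        df = df[df["Feature"].isin(["gene", "pseudogene"])] if "Feature" in df else df
        out = pd.DataFrame(
            {
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "gene_id": df.get("ID", pd.Series([""] * len(df))).astype(str),
                "gene_name": df.get("Name", df.get("ID")).astype(str),
            }
        )
    elif path.endswith((".bed", ".bed.gz")):
        df = pr.read_bed(path).df
        name = df["Name"] if "Name" in df else pd.Series([""] * len(df))
        out = pd.DataFrame(
            {
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "gene_id": name.astype(str),
                "gene_name": name.astype(str),
            }
        )
    else:
        raise ValueError(f"unrecognized annotation format: {path}")
    return out.reset_index(drop=True)


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Regions as BED: 0-based half-open bp spans, name = region id,
    score = max window variance (scaled rank is meaningless across traits)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(
                f"{r['chrom']}\t{int(r['start_pos']) - 1}\t{int(r['end_pos'])}\t"
                f"region{int(r['region_id'])}_c{int(r['coefficient'])}\t"
                f"{r['max_var']:.6g}\n"
            )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
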