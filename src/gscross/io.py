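"""File I/O: genetic maps, genotype matrices, phenotypes, results, VCF import.

All deliverable formats are plain text.  Genotype files carry their dosage
coding in a ``# coding=...`` sidecar comment line so that a round-trip
through disk preserves semantics, not just numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .popsim import GeneticMap, GenotypeMatrix

__all__ = [
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_vcf",
]

_MAP_COLUMNS = ["marker_id", "linkage_group", "position_cm"]


def write_map(gmap: GeneticMap, path) -> None:
    """Write a 3-column tab-delimited map file (with header)."""
    df = pd.DataFrame(
        {
            "marker_id": gmap.marker_id,
            "linkage_group": gmap.linkage_group,
            "position_cm": gmap.position_cm,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    """Read a tab-delimited map file; enforces the within-group ordering."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing map columns {missing}")
    for lg, sub in df.groupby("linkage_group", sort=False):
        pos = sub["position_cm"].to_numpy(dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(
                f"{path}: positions not strictly increasing in linkage group {lg}"
            )
    return GeneticMap(
        marker_id=df["marker_id"].to_numpy(dtype=object),
        linkage_group=df["linkage_group"].to_numpy(dtype=int),
        position_cm=df["position_cm"].to_numpy(dtype=float),
    )


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """Write a genotype TSV: coding comment, header, one row per individual."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# coding={genotypes.coding}\n")
        fh.write("individual_id\t" + "\t".join(genotypes.marker_ids) + "\n")
        for ind, row in zip(genotypes.individual_ids, genotypes.values):
            if genotypes.coding == "discrete_012":
                cells = "\t".join(str(int(v)) for v in row)
            else:
                cells = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{ind}\t{cells}\n")


def read_genotypes(path, coding: str | None = None) -> GenotypeMatrix:
    """Read a genotype TSV written by :func:`write_genotypes`.

    The coding is taken from the ``# coding=`` sidecar line unless
    overridden by the ``coding`` argument.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    start = 0
    file_coding = None
    while start < len(lines) and lines[start].startswith("#"):
        line = lines[start].lstrip("# ").strip()
        if line.startswith("coding="):
            file_coding = line.split("=", 1)[1]
        start += 1
    coding = coding or file_coding
    if coding is None:
        raise ValueError(f"{path}: no coding sidecar line and no coding given")
    if start >= len(lines):
        raise ValueError(f"{path}: empty genotype file")
    header = lines[start].split("\t")
    marker_ids = header[1:]
    individual_ids, rows = [], []
    for ln, raw in enumerate(lines[start + 1 :], start=start + 2):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if len(cells) != len(header):
            raise ValueError(
                f"{path}:{ln}: expected {len(header)} columns, found {len(cells)}"
            )
        individual_ids.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: malformed dosage value ({err})") from None
    return GenotypeMatrix(
        values=np.asarray(rows, dtype=float),
        coding=coding,
        individual_ids=individual_ids,
        marker_ids=marker_ids,
    )


def write_phenotypes(individual_ids, values, path, population: str = "panel") -> None:
    """Write a phenotype TSV (individual_id, trait value, population id)."""
    pd.DataFrame(
        {"individual_id": list(individual_ids), "value": np.asarray(values, float),
         "population": population}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV into a DataFrame (individual_id, value, population)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("individual_id", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing phenotype column {col!r}")
    return df


def read_vcf(path) -> GenotypeMatrix:
    """Import diploid biallelic VCF records as a discrete {0,1,2} matrix.

    GT fields are mapped to alternate-allele dosage.  Multiallelic or
    non-diploid records and records with missing genotypes are rejected.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    marker_ids, rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"{path}: multiallelic record at {rec.CHROM}:{rec.POS}")
        gts = rec.genotype.array()
        if gts.shape[1] < 3:
            raise ValueError(f"{path}: non-diploid record at {rec.CHROM}:{rec.POS}")
        alleles = gts[:, :2]
        if np.any(alleles < 0):
            raise ValueError(
                f"{path}: missing genotype at {rec.CHROM}:{rec.POS}; "
                "impute or filter before import"
            )
        marker_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        rows.append(alleles.sum(axis=1).astype(float))
    return GenotypeMatrix(
        values=np.asarray(rows, dtype=float).T,
        coding="discrete_012",
        individual_ids=individual_ids,
        marker_ids=marker_ids,
    )
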