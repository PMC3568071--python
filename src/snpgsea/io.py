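"""Readers and writers for the text formats the pipeline touches.

PLINK text PED/MAP for genotypes, GMT for gene sets, a refFlat-like TSV for
transcript annotation, and TSV for all result tables.  Alleles are recoded to
minor-allele dosage on read; the minor allele is determined from allele
frequencies over the whole file (use :func:`to_trios` + parent-based QC for
family data, where the minor allele is recomputed on parents only).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datamodel import (
    SUBJECT_COLUMNS,
    TRANSCRIPT_COLUMNS,
    GeneAnnotation,
    GenotypeMatrix,
    GeneSetCollection,
    TrioCollection,
)
from .errors import ParseError

MISSING_ALLELE = "0"
_PHENO_MAP = {"1": 0.0, "2": 1.0, "0": np.nan, "-9": np.nan}


def read_map(map_path) -> pd.DataFrame:
    """Read a 4-column PLINK MAP file (chrom, snp, genetic distance, position).

    The genetic-distance column is read but unused (kept for format fidelity).
    """
    records = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ParseError(
                    f"MAP line has {len(fields)} fields, expected 4",
                    map_path, lineno,
                )
            chrom, snp, gd, pos = fields
            try:
                pos = int(pos)
            except ValueError:
                raise ParseError(f"non-integer position {pos!r}", map_path, lineno)
            records.append((chrom, snp, float(gd), pos))
    return pd.DataFrame(records, columns=["chrom", "snp", "genetic_distance", "pos"])


def read_ped_map(ped_path, map_path, minor_subject_mask=None):
    """Read PLINK text PED/MAP into a :class:`GenotypeMatrix`.

    Alleles are recoded to minor-allele dosage using whole-file allele
    frequencies (or the subjects selected by ``minor_subject_mask``); "0 0"
    pairs become missing; phenotype 1/2 maps to control/case, 0 or -9 to
    missing.
    """
    snp_map = read_map(map_path)
    n_snps = len(snp_map)

    subj_rows, allele_rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ParseError(
                    f"PED line has {len(fields)} fields, expected "
                    f"{6 + 2 * n_snps} for {n_snps} MAP SNPs",
                    ped_path, lineno,
                )
            fam, ind, fa, mo, sex, pheno = fields[:6]
            if pheno not in _PHENO_MAP:
                raise ParseError(f"phenotype code {pheno!r} not in 1/2/0/-9",
                                 ped_path, lineno)
            subj_rows.append((fam, ind, fa, mo, int(sex), _PHENO_MAP[pheno]))
            allele_rows.append(fields[6:])

    subjects = pd.DataFrame(subj_rows, columns=SUBJECT_COLUMNS)
    n_subj = len(subjects)
    alleles = np.array(allele_rows, dtype=object).reshape(n_subj, n_snps, 2) \
        if n_subj else np.empty((0, n_snps, 2), dtype=object)

    # half-missing pairs are treated as fully missing
    miss = (alleles == MISSING_ALLELE).any(axis=2) if n_subj else \
        np.zeros((0, n_snps), dtype=bool)

    freq_mask = (np.ones(n_subj, dtype=bool) if minor_subject_mask is None
                 else np.asarray(minor_subject_mask))

    dosages = np.full((n_subj, n_snps), np.nan)
    allele1, allele2 = [], []
    for j in range(n_snps):
        valid = ~miss[:, j]
        obs = alleles[valid & freq_mask, j, :].ravel()
        labels, counts = np.unique(obs, return_counts=True)
        if len(labels) > 2:
            raise ParseError(
                f"SNP {snp_map['snp'][j]!r} has {len(labels)} alleles",
                ped_path,
            )
        if len(labels) == 0:
            allele1.append(MISSING_ALLELE)
            allele2.append(MISSING_ALLELE)
            continue
        if len(labels) == 1:
            minor, major = MISSING_ALLELE, labels[0]
        else:
            order = np.lexsort((labels, counts))  # ascending count, label ties
            minor, major = labels[order[0]], labels[order[1]]
        allele1.append(minor)
        allele2.append(major)
        dosages[valid, j] = (alleles[valid, j, :] == minor).sum(axis=1)

    snps = pd.DataFrame({
        "snp": snp_map["snp"], "chrom": snp_map["chrom"], "pos": snp_map["pos"],
        "allele1": allele1, "allele2": allele2,
    })
    return GenotypeMatrix(dosages, snps, subjects)


def write_ped_map(matrix: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a GenotypeMatrix as PLINK text PED/MAP (genetic distance 0)."""
    with open(map_path, "w") as fh:
        for rec in matrix.snps.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.snp}\t0\t{rec.pos}\n")

    pheno_inv = {0.0: "1", 1.0: "2"}
    a1 = matrix.snps["allele1"].to_numpy()
    a2 = matrix.snps["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, subj in enumerate(matrix.subjects.itertuples(index=False)):
            pheno = pheno_inv.get(subj.phenotype, "0")
            fields = [str(subj.family), str(subj.individual), str(subj.father),
                      str(subj.mother), str(subj.sex), pheno]
            row = matrix.dosages[i]
            for j, d in enumerate(row):
                if np.isnan(d):
                    fields += [MISSING_ALLELE, MISSING_ALLELE]
                elif d == 0:
                    fields += [a2[j], a2[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")


def to_trios(matrix: GenotypeMatrix) -> TrioCollection:
    """Group a pedigree GenotypeMatrix into father/mother/child trios.

    Dosages are re-oriented to the minor allele computed on parents only.
    Families without both parents and exactly one child are rejected.
    """
    subj = matrix.subjects
    key = dict(zip(zip(subj["family"], subj["individual"]), range(len(subj))))
    fam_rows: dict[str, list[int]] = {}
    parent_idx: list[int] = []
    trios = []
    for i, row in subj.iterrows():
        if row["father"] != "0" and row["mother"] != "0":
            fa = key.get((row["family"], row["father"]))
            mo = key.get((row["family"], row["mother"]))
            if fa is None or mo is None:
                raise ParseError(
                    f"family {row['family']!r}: parent ids of child "
                    f"{row['individual']!r} not found"
                )
            trios.append((row["family"], fa, mo, i))
            parent_idx += [fa, mo]
            fam_rows.setdefault(row["family"], []).append(i)
    for fam, children in fam_rows.items():
        if len(children) != 1:
            raise ParseError(f"family {fam!r} has {len(children)} children, expected 1")

    # re-orient to parents-only minor allele
    parent_mask = np.zeros(matrix.n_subjects, dtype=bool)
    parent_mask[parent_idx] = True
    d = matrix.dosages.copy()
    maf = matrix.maf(subject_mask=parent_mask)
    flip = maf > 0.5
    snps = matrix.snps.copy()
    if flip.any():
        d[:, flip] = 2 - d[:, flip]
        snps.loc[flip, ["allele1", "allele2"]] = \
            snps.loc[flip, ["allele2", "allele1"]].to_numpy()

    father = np.array([d[fa] for _, fa, _, _ in trios])
    mother = np.array([d[mo] for _, _, mo, _ in trios])
    child = np.array([d[ch] for _, _, _, ch in trios])
    families = pd.DataFrame({"family": [f for f, _, _, _ in trios]})
    return TrioCollection(father, mother, child, snps, families)


def write_trios_ped_map(trios: TrioCollection, ped_path, map_path) -> None:
    """Write a TrioCollection as a pedigree PED/MAP (children coded affected)."""
    n = trios.n_families
    fam = trios.families["family"].astype(str).to_numpy()
    subjects = pd.DataFrame({
        "family": np.tile(fam, 3),
        "individual": np.concatenate([[f"{f}_fa" for f in fam],
                                      [f"{f}_mo" for f in fam],
                                      [f"{f}_ch" for f in fam]]),
        "father": ["0"] * (2 * n) + [f"{f}_fa" for f in fam],
        "mother": ["0"] * (2 * n) + [f"{f}_mo" for f in fam],
        "sex": [1] * n + [2] * n + [0] * n,
        "phenotype": [np.nan] * (2 * n) + [1.0] * n,
    })
    d = np.vstack([trios.father, trios.mother, trios.child])
    write_ped_map(GenotypeMatrix(d, trios.snps.copy(), subjects),
                  ped_path, map_path)


def read_gene_table(path) -> GeneAnnotation:
    """Read a refFlat-like transcript TSV (geneName, chrom, strand, txStart, txEnd).

    A header row with those names is accepted and skipped; coordinates are
    interpreted as 0-based half-open.  An empty file yields an empty annotation.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(
                    f"annotation line has {len(fields)} fields, expected >= 5",
                    path, lineno,
                )
            if lineno == 1 and not fields[3].lstrip("-").isdigit():
                continue  # header
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError("non-integer transcript coordinates", path, lineno)
            if fields[2] not in ("+", "-"):
                raise ParseError(f"strand {fields[2]!r} not +/-", path, lineno)
            rows.append((fields[0], fields[1], fields[2], start, end))
    return GeneAnnotation(pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS))


def write_gene_table(annotation: GeneAnnotation, path) -> None:
    df = annotation.transcripts.copy()
    df.columns = ["geneName", "chrom", "strand", "txStart", "txEnd"]
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, then gene ids)."""
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} tab-separated fields, expected >= 3",
                    path, lineno,
                )
            name, desc = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_results(results: pd.DataFrame, path) -> None:
    """Write a result table as TSV, floats at 6 significant digits."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
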