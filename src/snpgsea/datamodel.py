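"""Core in-memory containers shared by every pipeline stage.

Genotypes are held as minor-allele dosage matrices (``numpy`` float arrays
with ``NaN`` for missing calls) plus a pandas SNP map.  Annotation
coordinates are 0-based half-open internally (UCSC convention); reports use
1-based inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

SNP_COLUMNS = ["snp", "chrom", "pos", "allele1", "allele2"]
SUBJECT_COLUMNS = ["family", "individual", "father", "mother", "sex", "phenotype"]
TRANSCRIPT_COLUMNS = ["gene", "chrom", "strand", "tx_start", "tx_end"]


def _as_dosage(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        bad = arr[~ok].ravel()[0]
        raise ValueError(f"dosage values must be in {{0,1,2,NaN}}; found {bad!r}")
    return arr


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix with SNP metadata.

    ``dosages[i, j]`` counts copies of the *minor* allele (``allele1`` in the
    SNP map) carried by subject ``i`` at SNP ``j``; missing calls are ``NaN``.
    ``subjects`` carries the six PLINK pedigree columns; ``phenotype`` is
    0 (control), 1 (case) or ``NaN``.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    subjects: pd.DataFrame

    def __post_init__(self):
        self.dosages = _as_dosage(self.dosages)
        self.snps = self.snps.reset_index(drop=True)
        self.subjects = self.subjects.reset_index(drop=True)
        if self.dosages.shape != (len(self.subjects), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )
        if (self.snps["pos"] <= 0).any():
            raise ValueError("SNP positions must be strictly positive")
        if self.snps.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chromosome, position) in SNP map")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def phenotype(self) -> np.ndarray:
        return self.subjects["phenotype"].to_numpy(dtype=float)

    # --- per-SNP summaries -------------------------------------------------

    def snp_call_rate(self, subject_mask=None) -> np.ndarray:
        d = self.dosages if subject_mask is None else self.dosages[subject_mask]
        if d.shape[0] == 0:
            return np.zeros(self.n_snps)
        return 1.0 - np.isnan(d).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.ones(self.n_subjects)
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def maf(self, subject_mask=None) -> np.ndarray:
        """Minor-allele frequency over non-missing calls (NaN if all missing)."""
        d = self.dosages if subject_mask is None else self.dosages[subject_mask]
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def genotype_counts(self, subject_mask=None) -> np.ndarray:
        """(n_snps, 3) counts of dosage classes 0/1/2 over non-missing calls."""
        d = self.dosages if subject_mask is None else self.dosages[subject_mask]
        out = np.empty((self.n_snps, 3), dtype=np.int64)
        for k in range(3):
            out[:, k] = np.nansum(d == k, axis=0)
        return out

    # --- subsetting --------------------------------------------------------

    def subset(self, snp_mask=None, subject_mask=None) -> "GenotypeMatrix":
        d = self.dosages
        snps, subjects = self.snps, self.subjects
        if subject_mask is not None:
            d = d[np.asarray(subject_mask)]
            subjects = subjects.loc[np.asarray(subject_mask)]
        if snp_mask is not None:
            d = d[:, np.asarray(snp_mask)]
            snps = snps.loc[np.asarray(snp_mask)]
        return GenotypeMatrix(d.copy(), snps.copy(), subjects.copy())


@dataclass
class TrioCollection:
    """Father/mother/child dosages per family on a shared SNP map."""

    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    snps: pd.DataFrame
    families: pd.DataFrame  # one row per family: family id

    def __post_init__(self):
        self.father = _as_dosage(self.father)
        self.mother = _as_dosage(self.mother)
        self.child = _as_dosage(self.child)
        self.snps = self.snps.reset_index(drop=True)
        self.families = self.families.reset_index(drop=True)
        shape = (len(self.families), len(self.snps))
        for name, arr in (("father", self.father), ("mother", self.mother),
                          ("child", self.child)):
            if arr.shape != shape:
                raise ValueError(f"{name} dosage shape {arr.shape} != {shape}")

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def parent_matrix(self) -> GenotypeMatrix:
        """Stack parents into a GenotypeMatrix (for parent-stratum QC/MAF)."""
        d = np.vstack([self.father, self.mother])
        fam = self.families["family"].astype(str)
        subjects = pd.DataFrame({
            "family": np.concatenate([fam, fam]),
            "individual": ([f"{f}_father" for f in fam]
                           + [f"{f}_mother" for f in fam]),
            "father": "0", "mother": "0",
            "sex": [1] * self.n_families + [2] * self.n_families,
            "phenotype": np.nan,
        })
        return GenotypeMatrix(d, self.snps.copy(), subjects)

    def subset(self, snp_mask=None, family_mask=None) -> "TrioCollection":
        f, m, c = self.father, self.mother, self.child
        snps, fams = self.snps, self.families
        if family_mask is not None:
            fam = np.asarray(family_mask)
            f, m, c, fams = f[fam], m[fam], c[fam], fams.loc[fam]
        if snp_mask is not None:
            sm = np.asarray(snp_mask)
            f, m, c, snps = f[:, sm], m[:, sm], c[:, sm], snps.loc[sm]
        return TrioCollection(f.copy(), m.copy(), c.copy(), snps.copy(), fams.copy())


@dataclass
class GeneAnnotation:
    """Transcript table: gene id, chromosome, strand, txStart, txEnd.

    Coordinates are 0-based half-open (``tx_start < tx_end``).
    """

    transcripts: pd.DataFrame

    def __post_init__(self):
        t = self.transcripts.reset_index(drop=True)
        missing = [c for c in TRANSCRIPT_COLUMNS if c not in t.columns]
        if missing:
            raise ConfigurationError(f"annotation missing columns {missing}")
        if len(t) and (t["tx_start"] >= t["tx_end"]).any():
            bad = t.loc[t["tx_start"] >= t["tx_end"], "gene"].iloc[0]
            raise ValueError(f"transcript of gene {bad!r} has tx_start >= tx_end")
        self.transcripts = t

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.transcripts["gene"]))

    def __len__(self) -> int:
        return len(self.transcripts)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> ordered unique gene ids."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate gene ids")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]
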