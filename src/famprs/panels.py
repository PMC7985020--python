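"""Core data containers: genotype dosage panels and pedigree cohorts.

A :class:`DosagePanel` holds a subjects x variants dosage matrix together
with variant metadata (id, chromosome, position, counted allele A1, other
allele A2).  When produced by the simulator it additionally carries
allele-resolved haplotypes so that gene dropping can transmit individual
alleles rather than dosages.

A :class:`PedigreeCohort` wraps a per-subject table with family structure
(fid, iid, father, mother), diagnosis, cohort label and covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DosagePanel",
    "PedigreeCohort",
    "read_dosage_tsv",
    "read_vcf_dosages",
]

VARIANT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2"]


@dataclass
class DosagePanel:
    """Subjects x variants dosage matrix with variant metadata.

    Parameters
    ----------
    subjects:
        Subject identifiers, one per matrix row.
    variants:
        DataFrame with columns ``SNP CHR BP A1 A2``; dosages count the A1
        allele.
    dosages:
        Array of shape ``(n_subjects, n_variants)`` with entries in [0, 2].
    haplotypes:
        Optional int8 array of shape ``(n_subjects, n_variants, 2)`` with
        0/1 allele indicators (1 = A1 allele); present for simulated data.
    """

    subjects: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subjects = list(self.subjects)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["SNP"].tolist()

    def subject_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.subjects)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"subject {exc.args[0]!r} not in panel") from None

    def subset_subjects(self, ids: Sequence[str]) -> "DosagePanel":
        idx = self.subject_index(ids)
        haps = self.haplotypes[idx] if self.haplotypes is not None else None
        return DosagePanel(list(ids), self.variants.copy(), self.dosages[idx], haps)

    def subset_variants(self, mask_or_idx: np.ndarray) -> "DosagePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        haps = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return DosagePanel(
            self.subjects, self.variants.iloc[idx], self.dosages[:, idx], haps
        )

    def allele_frequencies(self) -> np.ndarray:
        """Sample A1 allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    # ------------------------------------------------------------------ IO
    def write_tsv(self, path: str | Path) -> None:
        """Write a variants x subjects dosage matrix TSV (metadata first)."""
        df = self.variants.copy()
        mat = pd.DataFrame(self.dosages.T, columns=self.subjects)
        pd.concat([df.reset_index(drop=True), mat], axis=1).to_csv(
            path, sep="\t", index=False
        )

    def write_vcf(self, path: str | Path) -> None:
        """Write a VCF v4.2 with a per-sample DS (dosage) FORMAT field."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,'
                'Description="Estimated alternate allele dosage">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.subjects)
                + "\n"
            )
            for j, row in self.variants.iterrows():
                # ALT is the counted (A1) allele so DS matches the matrix
                fields = [
                    str(row["CHR"]),
                    str(int(row["BP"])),
                    str(row["SNP"]),
                    str(row["A2"]),
                    str(row["A1"]),
                    ".",
                    "PASS",
                    ".",
                    "DS",
                ]
                fields += [format(d, "g") for d in self.dosages[:, j]]
                fh.write("\t".join(fields) + "\n")


def read_dosage_tsv(path: str | Path) -> DosagePanel:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    subjects = [c for c in df.columns if c not in VARIANT_COLUMNS]
    variants = df[VARIANT_COLUMNS].copy()
    dosages = df[subjects].to_numpy(dtype=float).T
    return DosagePanel(subjects, variants, dosages)


def read_vcf_dosages(path: str | Path) -> DosagePanel:
    """Read a VCF with per-sample DS fields into a DosagePanel.

    Only plain-text VCF is supported; the ALT allele is taken as the counted
    (A1) allele.
    """
    subjects: list[str] = []
    rows = []
    dose_rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            parts = line.split("\t")
            if line.startswith("#CHROM"):
                subjects = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[:5]
            fmt = parts[8].split(":")
            if "DS" not in fmt:
                raise ValueError(f"variant {vid}: no DS field in FORMAT")
            k = fmt.index("DS")
            dose_rows.append([float(p.split(":")[k]) for p in parts[9:]])
            rows.append((vid, chrom, int(pos), alt, ref))
    if not rows:
        raise ValueError(f"no variant records in {path}")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return DosagePanel(subjects, variants, np.array(dose_rows, dtype=float).T)


PHENO_COLUMNS = [
    "fid",
    "iid",
    "father",
    "mother",
    "sex",
    "diagnosis",
    "cohort",
    "generation",
    "married_in",
    "age_interview",
    "age_onset",
]


@dataclass
class PedigreeCohort:
    """Family structure, diagnoses and covariates for a set of subjects.

    ``table`` has one row per subject with columns ``fid iid father mother
    sex diagnosis cohort generation married_in age_interview age_onset``.
    ``father``/``mother`` are "0" for founders.  ``diagnosis`` is one of
    ``BD``, ``MDD``, ``unaffected``; ``cohort`` one of ``FAM``, ``CC``.
    Optional per-disorder liability/genetic-score columns may be present
    (``liab_<D>``, ``gscore_<D>``) for simulated cohorts.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table lacks columns: {missing}")
        if self.table["iid"].duplicated().any():
            dups = self.table.loc[self.table["iid"].duplicated(), "iid"].tolist()
            raise ValueError(f"duplicated subject ids: {dups}")
        self.table = self.table.reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        return self.table["iid"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def founders(self) -> pd.DataFrame:
        t = self.table
        return t[(t["father"] == "0") & (t["mother"] == "0")]

    def families(self) -> list[str]:
        return sorted(self.table["fid"].unique().tolist())

    def subset(self, mask: np.ndarray | pd.Series) -> "PedigreeCohort":
        return PedigreeCohort(self.table[np.asarray(mask)].copy())

    # ------------------------------------------------------------------ IO
    def write_fam(self, path: str | Path) -> None:
        """PLINK .fam: FID IID PAT MAT SEX PHENO (PHENO 2=affected BD)."""
        t = self.table
        pheno = np.where(t["diagnosis"] == "BD", 2, 1)
        out = pd.DataFrame(
            {
                "FID": t["fid"],
                "IID": t["iid"],
                "PAT": t["father"],
                "MAT": t["mother"],
                "SEX": t["sex"],
                "PHENO": pheno,
            }
        )
        out.to_csv(path, sep=" ", header=False, index=False)

    def write_phenotypes(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_phenotypes(cls, path: str | Path) -> "PedigreeCohort":
        df = pd.read_csv(
            path, sep="\t", dtype={"fid": str, "iid": str, "father": str, "mother": str}
        )
        return cls(df)
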