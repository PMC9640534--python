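"""Genotype/phenotype I/O and QC filters.

Genotypes are unphased diploid base calls read from PLINK text PED/MAP pairs
(GRCh37 coordinates).  A call is stored as a two-character string of bases in
sorted order ("AC" and "CA" are the same genotype); missing data is the code
``"00"`` internally ("0 0" in PED, "NN" in FASTA exports).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "00"
VALID_BASES = frozenset("ACGT")

#: phenotype TSV column order
PHENOTYPE_COLUMNS = ["subject_id", "sex", "age", "nci", "county"]


class PedParseError(ValueError):
    """Raised when a PED/MAP pair is malformed."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic marker with 1-based GRCh37 position.

    ``allele_a``/``allele_b`` are the observed alleles; ``allele_b`` is None
    for markers where only one allele was seen in the data.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str | None = None
    allele_b: str | None = None

    @property
    def is_indel(self) -> bool:
        """Insertion/deletion marker (multi-base or I/D coded alleles)."""
        for a in (self.allele_a, self.allele_b):
            if a is not None and (len(a) != 1 or a not in VALID_BASES):
                return True
        return False


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs table of unordered diploid base calls.

    calls[i, j] is the genotype of subject i at SNP j: two bases in sorted
    order, or MISSING.
    """

    subjects: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray  # (n_subjects, n_snps) of '<U2'

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U2")
        if self.calls.shape != (len(self.subjects), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject IDs")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP IDs")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        for j, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return j
        raise KeyError(snp_id)

    def column(self, j: int) -> np.ndarray:
        return self.calls[:, j]

    def call_rate(self, j: int) -> float:
        col = self.calls[:, j]
        return float(np.mean(col != MISSING)) if len(col) else 0.0

    def allele_counts(self, j: int) -> dict[str, int]:
        """Counts of each allele among non-missing calls at SNP j."""
        counts: dict[str, int] = {}
        for g in self.calls[:, j]:
            if g == MISSING:
                continue
            for b in g:
                counts[b] = counts.get(b, 0) + 1
        return counts

    def maf(self, j: int) -> float:
        """Minor allele frequency over non-missing alleles (0 if monomorphic)."""
        counts = self.allele_counts(j)
        total = sum(counts.values())
        if total == 0 or len(counts) < 2:
            return 0.0
        return min(counts.values()) / total

    def genotype_dosage(self, j: int, counted_allele: str) -> np.ndarray:
        """Per-subject copy number of ``counted_allele`` at SNP j; -1 = missing."""
        col = self.calls[:, j]
        out = np.full(len(col), -1, dtype=int)
        ok = col != MISSING
        out[ok] = [g.count(counted_allele) for g in col[ok]]
        return out

    def take_snps(self, indices: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            subjects=list(self.subjects),
            snps=[self.snps[j] for j in indices],
            calls=self.calls[:, indices].copy(),
        )

    def take_subjects(self, keep: list[str]) -> "GenotypeMatrix":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.subjects) if s in keep_set]
        return GenotypeMatrix(
            subjects=[self.subjects[i] for i in idx],
            snps=list(self.snps),
            calls=self.calls[idx, :].copy(),
        )


@dataclass
class FilterReport:
    """Accounting of SNP exclusions; each SNP is charged to the first rule
    that excludes it, in order: indel, monomorphic, low call rate, low MAF."""

    n_input: int
    n_excluded_indel: int = 0
    n_excluded_monomorphic: int = 0
    n_excluded_lowcall: int = 0
    n_excluded_maf: int = 0
    kept_ids: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    def check(self) -> None:
        total = (
            self.n_kept
            + self.n_excluded_indel
            + self.n_excluded_monomorphic
            + self.n_excluded_lowcall
            + self.n_excluded_maf
        )
        if total != self.n_input:
            raise AssertionError("filter report counts do not sum to n_input")


def normalize_call(a: str, b: str) -> str:
    """Canonical unordered genotype: sorted pair of bases, or MISSING."""
    if a == "0" or b == "0":
        return MISSING
    return a + b if a <= b else b + a


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a PLINK text PED/MAP pair.

    Returns the genotype matrix and a minimal phenotype frame (subject_id,
    sex from PED column 5; age/nci/county are absent and left as NA — use
    :func:`read_phenotypes` for the full phenotype table).
    """
    map_rows = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise PedParseError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
        chrom, snp_id, _cm, pos = parts
        map_rows.append((chrom, snp_id, int(pos)))

    n_snps = len(map_rows)
    subjects: list[str] = []
    sexes: list[int] = []
    call_rows: list[list[str]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise PedParseError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                f"({n_snps} MAP SNPs), got {len(parts)}"
            )
        _fid, iid, _fat, _mot, sex, _phe = parts[:6]
        alleles = parts[6:]
        row = []
        for j in range(n_snps):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            for sym in (a, b):
                if sym != "0" and sym not in VALID_BASES:
                    raise PedParseError(
                        f"{ped_path}:{lineno}: allele symbol {sym!r} is not one of A/C/G/T/0"
                    )
            row.append(normalize_call(a, b))
        subjects.append(iid)
        try:
            sexes.append(int(sex))
        except ValueError:
            sexes.append(0)
        call_rows.append(row)

    calls = np.array(call_rows, dtype="<U2") if call_rows else np.empty((0, n_snps), dtype="<U2")
    snps = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        seen = sorted({b for g in calls[:, j] if g != MISSING for b in g}) if len(calls) else []
        allele_a = seen[0] if seen else None
        allele_b = seen[1] if len(seen) > 1 else None
        snps.append(SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos, allele_a=allele_a, allele_b=allele_b))

    gm = GenotypeMatrix(subjects=subjects, snps=snps, calls=calls)
    pheno = pd.DataFrame(
        {
            "subject_id": subjects,
            "sex": sexes,
            "age": pd.array([pd.NA] * len(subjects), dtype="Int64"),
            "nci": pd.array([pd.NA] * len(subjects), dtype="Int64"),
            "county": [""] * len(subjects),
        }
    )
    return gm, pheno


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path, pheno: pd.DataFrame | None = None) -> None:
    """Write a PLINK text PED/MAP pair (sex/phenotype from ``pheno`` if given)."""
    with open(map_path, "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    sex_by_id: dict[str, int] = {}
    phe_by_id: dict[str, int] = {}
    if pheno is not None:
        for _, row in pheno.iterrows():
            sex_by_id[row["subject_id"]] = int(row["sex"]) if pd.notna(row["sex"]) else 0
            phe_by_id[row["subject_id"]] = int(row["nci"]) if pd.notna(row.get("nci")) else -9
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.subjects):
            sex = sex_by_id.get(sid, 0)
            phe = phe_by_id.get(sid, -9)
            fields = [sid, sid, "0", "0", str(sex), str(phe)]
            for g in gm.calls[i]:
                if g == MISSING:
                    fields.extend(["0", "0"])
                else:
                    fields.extend([g[0], g[1]])
            fh.write(" ".join(fields) + "\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV (subject_id, sex, age, nci, county)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "county": str})
    missing = [c for c in PHENOTYPE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns: {missing}")
    if "county" not in df.columns:
        df["county"] = ""
    return df[PHENOTYPE_COLUMNS]


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, columns=PHENOTYPE_COLUMNS)


def filter_snps(
    gm: GenotypeMatrix, min_call_rate: float = 0.75, min_maf: float = 0.01
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply marker QC: drop indels, monomorphic SNPs, SNPs genotyped in fewer
    than ``min_call_rate`` of subjects, and SNPs with MAF <= ``min_maf``.

    MAF is computed on non-missing alleles.  Exclusion rules run in that
    order and each SNP is charged to the first rule it fails.
    """
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    report = FilterReport(n_input=gm.n_snps)
    kept: list[int] = []
    for j, snp in enumerate(gm.snps):
        if snp.is_indel:
            report.n_excluded_indel += 1
            continue
        counts = gm.allele_counts(j)
        if len(counts) < 2:
            report.n_excluded_monomorphic += 1
            continue
        if gm.call_rate(j) < min_call_rate:
            report.n_excluded_lowcall += 1
            continue
        if gm.maf(j) <= min_maf:
            report.n_excluded_maf += 1
            continue
        kept.append(j)
    report.kept_ids = [gm.snps[j].snp_id for j in kept]
    report.check()
    if not kept:
        logger.warning("filter_snps: no SNPs survived QC (n_input=%d)", gm.n_snps)
    return gm.take_snps(kept), report


def filter_age_range(
    pheno: pd.DataFrame, min_age_female: int = 45, min_age_male: int = 55
) -> pd.DataFrame:
    """Keep females aged >= ``min_age_female`` and males aged >= ``min_age_male``.

    Sex coding: 1 = female, 2 = male.  Subjects with missing sex or age are
    dropped with a warning — a completed family cannot be assumed for them.
    """
    valid = pheno["sex"].isin([1, 2]) & pheno["age"].notna()
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("filter_age_range: dropping %d subjects with missing sex/age", n_bad)
    df = pheno[valid]
    keep = ((df["sex"] == 1) & (df["age"] >= min_age_female)) | (
        (df["sex"] == 2) & (df["age"] >= min_age_male)
    )
    return df[keep].reset_index(drop=True)


def region_slice(gm: GenotypeMatrix, chrom: str, start_pos: int, end_pos: int) -> GenotypeMatrix:
    """SNPs with start_pos <= pos <= end_pos on ``chrom`` (closed, 1-based)."""
    if start_pos > end_pos:
        raise ValueError(f"start_pos {start_pos} > end_pos {end_pos}")
    idx = [
        j
        for j, s in enumerate(gm.snps)
        if str(s.chrom) == str(chrom) and start_pos <= s.pos <= end_pos
    ]
    return gm.take_snps(idx)


def export_concat_fasta(gm: GenotypeMatrix, out_path) -> None:
    """One FASTA record per subject: diploid bases concatenated in chromosomal
    order (two characters per SNP, missing rendered NN) — the artificial
    sequences used for visual inspection of haplotype structure in an
    alignment viewer."""
    positions = [s.pos for s in gm.snps]
    if positions != sorted(positions):
        raise ValueError("SNPs must be sorted by position before FASTA export")
    with open(out_path, "w") as fh:
        for i, sid in enumerate(gm.subjects):
            seq = "".join("NN" if g == MISSING else g for g in gm.calls[i])
            fh.write(f">{sid}\n{seq}\n")


def sort_by_position(gm: GenotypeMatrix) -> GenotypeMatrix:
    order = sorted(range(gm.n_snps), key=lambda j: (str(gm.snps[j].chrom), gm.snps[j].pos))
    return gm.take_snps(order)
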