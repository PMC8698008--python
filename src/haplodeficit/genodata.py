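"""Phased-genotype and pedigree handling.

This module loads phased biallelic SNP genotypes (VCF 4.2) together with a
pedigree, applies the standard array-quality filters (animal call rate, SNP
call rate, minor allele frequency), builds the two analysis cohorts used by
the homozygosity screen (trio: offspring + sire + dam; pgp: offspring +
sire + maternal grandsire), and provides a minimal Mendelian trio phaser
for unphased input.

Conventions
-----------
* Marker coordinates are 1-based and inclusive, as in VCF.
* The allele matrix stores two rows per animal (rows ``2*i`` and ``2*i+1``
  for animal ``i``); allele codes are 0/1 with -1 for missing.
* For animals phased by pedigree, row ``2*i`` holds the paternal and row
  ``2*i+1`` the maternal allele.  Heterozygous genotypes whose phase is
  unknown are flagged in a per-animal x per-marker ``unresolved`` mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF


class DataError(Exception):
    """Malformed or inconsistent input data."""


class PedigreeCycleError(DataError):
    """An animal is its own ancestor."""


class QCError(DataError):
    """Quality control removed everything."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Ordered marker map: identifier, chromosome label, bp position (1-based).

    Markers are stored in file order; positions must be strictly increasing
    within a chromosome and marker identifiers must be unique.
    """

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if not (len(self.ids) == len(self.chrom) == len(self.pos)):
            raise DataError("marker map columns have unequal lengths")
        uniq, counts = np.unique(self.ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise DataError(f"duplicate marker id {dup!r}")
        for c in self.chromosomes:
            p = self.pos[self.chrom_slice(c)]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise DataError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slice(self, chromosome: str) -> slice:
        """Contiguous index slice of one chromosome's markers."""
        idx = np.flatnonzero(self.chrom == chromosome)
        if len(idx) == 0:
            raise KeyError(chromosome)
        if idx[-1] - idx[0] + 1 != len(idx):
            raise DataError(f"markers of chromosome {chromosome} are not contiguous")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_end_bp(self, chromosome: str) -> int:
        return int(self.pos[self.chrom_slice(chromosome)][-1])

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.ids[mask], self.chrom[mask], self.pos[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.ids, "chrom": self.chrom, "pos_bp": self.pos}
        )


@dataclass
class HaplotypeMatrix:
    """Two phased allele rows per animal, aligned to a marker map.

    ``alleles`` has shape ``(2 * n_animals, n_markers)`` with codes 0/1 and
    -1 for missing.  ``unresolved`` has shape ``(n_animals, n_markers)`` and
    marks heterozygous sites whose phase is unknown.
    """

    animal_ids: list[str]
    alleles: np.ndarray
    unresolved: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        n = len(self.animal_ids)
        if self.alleles.shape[0] != 2 * n:
            raise DataError(
                f"allele matrix has {self.alleles.shape[0]} rows for {n} animals"
            )
        if self.unresolved is None:
            self.unresolved = np.zeros((n, self.alleles.shape[1]), dtype=bool)
        self.unresolved = np.asarray(self.unresolved, dtype=bool)
        if self.unresolved.shape != (n, self.alleles.shape[1]):
            raise DataError("unresolved mask shape mismatch")
        self._index = {a: i for i, a in enumerate(self.animal_ids)}
        if len(self._index) != n:
            raise DataError("duplicate animal ids in genotype matrix")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def animal_alleles(self, animal_id: str) -> np.ndarray:
        i = self.index_of(animal_id)
        return self.alleles[2 * i : 2 * i + 2]

    def phased(self) -> np.ndarray:
        """Per-animal flag: True when no site has unknown phase."""
        return ~self.unresolved.any(axis=1)

    def genotype_missing(self) -> np.ndarray:
        """(n_animals, n_markers) mask: genotype has a missing allele."""
        miss = self.alleles < 0
        return miss[0::2] | miss[1::2]

    def animal_call_rate(self) -> np.ndarray:
        return 1.0 - self.genotype_missing().mean(axis=1)

    def marker_call_rate(self) -> np.ndarray:
        return 1.0 - self.genotype_missing().mean(axis=0)

    def minor_allele_freq(self) -> np.ndarray:
        """Per-marker MAF over non-missing alleles (NaN if all missing)."""
        ok = self.alleles >= 0
        with np.errstate(invalid="ignore"):
            p = np.where(
                ok.sum(axis=0) > 0,
                np.where(self.alleles > 0, 1, 0).sum(axis=0, where=ok)
                / np.maximum(ok.sum(axis=0), 1),
                np.nan,
            )
        return np.minimum(p, 1.0 - p)

    def subset_animals(self, keep: Sequence[int]) -> "HaplotypeMatrix":
        keep = np.asarray(keep, dtype=np.int64)
        rows = np.empty(2 * len(keep), dtype=np.int64)
        rows[0::2] = 2 * keep
        rows[1::2] = 2 * keep + 1
        return HaplotypeMatrix(
            [self.animal_ids[i] for i in keep],
            self.alleles[rows].copy(),
            self.unresolved[keep].copy(),
        )

    def subset_markers(self, mask: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            list(self.animal_ids),
            self.alleles[:, mask].copy(),
            self.unresolved[:, mask].copy(),
        )


@dataclass
class Pedigree:
    """Animal/sire/dam/sex records.

    Sex codes: 1 male, 2 female, 0 unknown.  Unknown parents are ``None``.
    """

    sire: dict[str, str | None]
    dam: dict[str, str | None]
    sex: dict[str, int]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str | None, str | None, int]]
    ) -> "Pedigree":
        sire: dict[str, str | None] = {}
        dam: dict[str, str | None] = {}
        sex: dict[str, int] = {}
        for animal, s, d, x in records:
            if animal in sire:
                raise DataError(f"duplicate pedigree record for animal {animal!r}")
            sire[animal] = s or None
            dam[animal] = d or None
            sex[animal] = int(x)
        ped = cls(sire, dam, sex)
        ped.validate()
        return ped

    @property
    def animals(self) -> list[str]:
        return list(self.sire)

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        return self.sire.get(animal), self.dam.get(animal)

    def maternal_grandsire(self, animal: str) -> str | None:
        d = self.dam.get(animal)
        if d is None:
            return None
        return self.sire.get(d)

    def validate(self) -> None:
        # acyclicity by iterative DFS over the animal -> parents graph
        WHITE, GREY, BLACK = 0, 1, 2
        color: dict[str, int] = {}
        for start in self.sire:
            if color.get(start, WHITE) != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            color[start] = GREY
            while stack:
                node, pi = stack[-1]
                ps = [p for p in self.parents(node) if p is not None and p in self.sire]
                if pi < len(ps):
                    stack[-1] = (node, pi + 1)
                    p = ps[pi]
                    c = color.get(p, WHITE)
                    if c == GREY:
                        raise PedigreeCycleError(
                            f"pedigree cycle involving animal {p!r}"
                        )
                    if c == WHITE:
                        color[p] = GREY
                        stack.append((p, 0))
                else:
                    color[node] = BLACK
                    stack.pop()
        # sex/role consistency
        for a, s in self.sire.items():
            if s is not None and self.sex.get(s, 0) == 2:
                raise DataError(f"animal {s!r} recorded female but used as sire of {a!r}")
        for a, d in self.dam.items():
            if d is not None and self.sex.get(d, 0) == 1:
                raise DataError(f"animal {d!r} recorded male but used as dam of {a!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animals,
                "sire_id": [self.sire[a] or "0" for a in self.animals],
                "dam_id": [self.dam[a] or "0" for a in self.animals],
                "sex": [self.sex[a] for a in self.animals],
            }
        )


@dataclass
class CohortSets:
    """Analysis cohorts: trios (offspring, sire, dam) and pgp
    (offspring, sire, maternal grandsire)."""

    trios: list[tuple[str, str, str]]
    pgp: list[tuple[str, str, str]]

    @property
    def trio_offspring(self) -> list[str]:
        return [t[0] for t in self.trios]

    @property
    def pgp_offspring(self) -> list[str]:
        return [t[0] for t in self.pgp]


@dataclass(frozen=True)
class QCThresholds:
    """Array QC thresholds; entities below a threshold are removed."""

    min_maf: float = 0.01
    min_snp_call_rate: float = 0.99
    min_animal_call_rate: float = 0.8

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_snp_call_rate", "min_animal_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Removal log: one row per removed entity with reason and value."""

    rows: list[tuple[str, str, str, float, float]] = field(default_factory=list)

    def add(self, entity: str, type_: str, reason: str, value: float, threshold: float) -> None:
        self.rows.append((entity, type_, reason, float(value), float(threshold)))

    @property
    def removed_animals(self) -> list[str]:
        return [r[0] for r in self.rows if r[1] == "animal"]

    @property
    def removed_markers(self) -> list[str]:
        return [r[0] for r in self.rows if r[1] == "marker"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["entity", "type", "reason", "value", "threshold"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_vcf(vcf_path: str | Path) -> tuple[HaplotypeMatrix, MarkerMap]:
    """Load a biallelic SNP VCF into a haplotype matrix and marker map.

    Multi-allelic records are rejected.  Heterozygous genotypes written with
    the ``/`` separator are flagged as phase-unresolved; genotypes with any
    missing allele are treated as fully missing.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise DataError(f"no such VCF: {vcf_path}")
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    n = len(samples)
    ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    cols: list[np.ndarray] = []
    unres_cols: list[np.ndarray] = []
    for v in vcf:
        if v.ALT is None or len(v.ALT) != 1:
            raise DataError(f"multi-allelic or ALT-less record at {v.CHROM}:{v.POS}")
        gts = np.asarray(v.genotypes, dtype=np.int64)
        a = gts[:, :2].astype(np.int8)
        if (a > 1).any():
            raise DataError(f"allele code >1 at {v.CHROM}:{v.POS}")
        phased = gts[:, 2].astype(bool)
        half_missing = (a < 0).any(axis=1)
        a[half_missing] = -1
        het = (a[:, 0] != a[:, 1]) & ~half_missing
        unres_cols.append(het & ~phased)
        col = np.empty(2 * n, dtype=np.int8)
        col[0::2] = a[:, 0]
        col[1::2] = a[:, 1]
        cols.append(col)
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        ids.append(mid)
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
    if not cols:
        raise DataError(f"VCF {vcf_path} contains no records")
    alleles = np.stack(cols, axis=1)
    unresolved = np.stack(unres_cols, axis=1)
    mmap = MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object), poss)
    matrix = HaplotypeMatrix(samples, alleles, unresolved)
    return matrix, mmap


def load_pedigree(pedigree_path: str | Path) -> Pedigree:
    """Load a pedigree TSV with header ``animal_id sire_id dam_id sex``."""
    pedigree_path = Path(pedigree_path)
    if not pedigree_path.exists():
        raise DataError(f"no such pedigree file: {pedigree_path}")
    df = pd.read_csv(pedigree_path, sep="\t", dtype=str)
    required = {"animal_id", "sire_id", "dam_id", "sex"}
    if not required.issubset(df.columns):
        raise DataError(
            f"pedigree file missing columns {sorted(required - set(df.columns))}"
        )
    records = [
        (
            row.animal_id,
            None if row.sire_id in ("0", None) or pd.isna(row.sire_id) else row.sire_id,
            None if row.dam_id in ("0", None) or pd.isna(row.dam_id) else row.dam_id,
            0 if pd.isna(row.sex) else int(row.sex),
        )
        for row in df.itertuples()
    ]
    return Pedigree.from_records(records)


def load_dataset(
    vcf_path: str | Path, pedigree_path: str | Path
) -> tuple[HaplotypeMatrix, MarkerMap, Pedigree]:
    """Load genotypes + marker map + pedigree in one call."""
    matrix, mmap = load_vcf(vcf_path)
    pedigree = load_pedigree(pedigree_path)
    return matrix, mmap, pedigree


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(
    matrix: HaplotypeMatrix,
    mmap: MarkerMap,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[HaplotypeMatrix, MarkerMap, QCReport]:
    """Apply array QC: animal call rate, then SNP call rate, then MAF.

    Each criterion is recomputed on the set surviving the previous one.
    Entities with value strictly below the threshold are removed.
    """
    report = QCReport()
    # 1. animal call rate
    cr_a = matrix.animal_call_rate()
    keep_a = cr_a >= thresholds.min_animal_call_rate
    for i in np.flatnonzero(~keep_a):
        report.add(
            matrix.animal_ids[i], "animal", "call_rate", cr_a[i],
            thresholds.min_animal_call_rate,
        )
    m2 = matrix.subset_animals(np.flatnonzero(keep_a)) if not keep_a.all() else matrix
    # 2. SNP call rate on surviving animals
    cr_m = m2.marker_call_rate()
    keep_m = cr_m >= thresholds.min_snp_call_rate
    for j in np.flatnonzero(~keep_m):
        report.add(
            str(mmap.ids[j]), "marker", "call_rate", cr_m[j],
            thresholds.min_snp_call_rate,
        )
    # 3. MAF on surviving animals and markers
    maf = m2.minor_allele_freq()
    maf_bad = ~(maf >= thresholds.min_maf)  # catches NaN too
    for j in np.flatnonzero(keep_m & maf_bad):
        report.add(
            str(mmap.ids[j]), "marker", "maf",
            0.0 if np.isnan(maf[j]) else maf[j], thresholds.min_maf,
        )
    keep_m &= ~maf_bad
    if not keep_m.any():
        raise QCError("QC removed all markers")
    if not keep_m.all():
        m2 = m2.subset_markers(keep_m)
        mmap = mmap.subset(keep_m)
    return m2, mmap, report


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def build_cohorts(
    pedigree: Pedigree,
    genotyped_ids: set[str] | Iterable[str],
    disjoint: bool = False,
) -> CohortSets:
    """Build trio and pgp cohorts from a pedigree and the genotyped id set.

    Trio membership requires offspring, sire and dam genotyped.  Pgp
    membership requires offspring, sire and maternal grandsire (the sire of
    the dam) genotyped; the dam herself need not be.  By default an
    offspring may appear in both cohorts; ``disjoint=True`` drops trio
    offspring from the pgp cohort.
    """
    genotyped = set(genotyped_ids)
    trios: list[tuple[str, str, str]] = []
    pgp: list[tuple[str, str, str]] = []
    for a in pedigree.animals:
        if a not in genotyped:
            continue
        s, d = pedigree.parents(a)
        if s in genotyped and d in genotyped:
            trios.append((a, s, d))
        mgs = pedigree.maternal_grandsire(a)
        if s in genotyped and mgs is not None and mgs in genotyped:
            pgp.append((a, s, mgs))
    if disjoint:
        trio_off = {t[0] for t in trios}
        pgp = [t for t in pgp if t[0] not in trio_off]
    if not trios and not pgp:
        warnings.warn("both cohorts are empty", stacklevel=2)
    return CohortSets(trios, pgp)


# ---------------------------------------------------------------------------
# Trio phasing
# ---------------------------------------------------------------------------

@dataclass
class TrioPhaseReport:
    resolved: int = 0
    ambiguous: int = 0
    mendelian_errors: int = 0


def trio_phase(
    matrix: HaplotypeMatrix, pedigree: Pedigree
) -> tuple[HaplotypeMatrix, TrioPhaseReport]:
    """Resolve the phase of heterozygous offspring sites by parental homozygosity.

    For every animal whose sire and dam are both in the matrix, each
    phase-unresolved heterozygous site is oriented (paternal allele in row
    ``2*i``, maternal in row ``2*i+1``) when exactly one transmission is
    Mendelian-consistent.  Sites where both orientations are consistent stay
    flagged; sites where neither is consistent are Mendelian errors and stay
    flagged as well.  Genotypes are never altered, only allele order.
    """
    alleles = matrix.alleles.copy()
    unresolved = matrix.unresolved.copy()
    report = TrioPhaseReport()

    def _has_allele(rows: np.ndarray, allele: int) -> np.ndarray:
        # missing parent alleles act as wildcards
        return (rows[0] == allele) | (rows[1] == allele) | (rows[0] < 0) | (rows[1] < 0)

    for i, animal in enumerate(matrix.animal_ids):
        s, d = pedigree.parents(animal)
        if s is None or d is None or s not in matrix or d not in matrix:
            report.ambiguous += int(unresolved[i].sum())
            continue
        srows = matrix.animal_alleles(s)
        drows = matrix.animal_alleles(d)
        orows = alleles[2 * i : 2 * i + 2]
        sites = unresolved[i]
        pat0 = _has_allele(srows, 0) & _has_allele(drows, 1)  # paternal 0, maternal 1
        pat1 = _has_allele(srows, 1) & _has_allele(drows, 0)
        fix0 = sites & pat0 & ~pat1
        fix1 = sites & pat1 & ~pat0
        err = sites & ~pat0 & ~pat1
        orows[0, fix0] = 0
        orows[1, fix0] = 1
        orows[0, fix1] = 1
        orows[1, fix1] = 0
        unresolved[i, fix0 | fix1] = False
        report.resolved += int(fix0.sum() + fix1.sum())
        report.ambiguous += int((sites & pat0 & pat1).sum())
        report.mendelian_errors += int(err.sum())
        # homozygous-site consistency (phase irrelevant, still checkable)
        hom = (orows[0] == orows[1]) & (orows[0] >= 0)
        for allele in (0, 1):
            bad = hom & (orows[0] == allele) & ~(
                _has_allele(srows, allele) & _has_allele(drows, allele)
            )
            report.mendelian_errors += int(bad.sum())
    return HaplotypeMatrix(list(matrix.animal_ids), alleles, unresolved), report
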