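"""Linking scan regions to candidate causal variants.

Variants from a sequenced carrier panel are filtered to protein-changing
consequence terms, correlated (r^2 on genotype dosages) with the per-animal
diplotype state of a region's top haplotype, and reported as candidates
when the linkage reaches the threshold (default: perfect, r^2 = 1) and no
alt-allele homozygote is seen in the panel.  Codon-level helpers translate
coding positions and simple duplication frameshifts into protein notation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genodata import DataError
from .hapscan import ScanRegion

#: Sequence Ontology terms that define a protein-changing variant.
PROTEIN_CHANGING_TERMS = frozenset(
    {
        "missense_variant",
        "start_lost",
        "stop_gained",
        "stop_lost",
        "stop_retained_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "conservative_inframe_deletion",
        "conservative_inframe_insertion",
        "disruptive_inframe_deletion",
        "disruptive_inframe_insertion",
        "exon_loss_variant",
        "frameshift_variant",
        "gene_fusion",
    }
)

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedVariant:
    """A sequenced-panel variant with consequence terms and dosages.

    ``dosages`` counts alt alleles (0/1/2) per panel sample, -1 for missing,
    aligned to the panel's sample order.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    consequences: tuple[str, ...]
    gene: str = ""
    transcript: str = ""
    dosages: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    c_dot: str | None = None
    p_dot: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise DataError(f"alt equals ref at {self.chrom}:{self.pos}")
        self.dosages = np.asarray(self.dosages, dtype=np.int8)

    def is_protein_changing(self) -> bool:
        return any(t in PROTEIN_CHANGING_TERMS for t in self.consequences)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class LDResult:
    """Squared dosage correlation between diplotype state and a variant."""

    variant: AnnotatedVariant | None
    r_squared: float | None
    undefined: bool
    n_samples: int
    diplotype_counts: tuple[int, int, int] = (0, 0, 0)
    dosage_counts: tuple[int, int, int] = (0, 0, 0)


@dataclass
class CandidateRecord:
    variant: AnnotatedVariant
    ld: LDResult
    panel_hom_count: int


@dataclass
class CandidateReport:
    region: ScanRegion | None
    candidates: list[CandidateRecord]
    all_ld: list[LDResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Consequence filtering and LD
# ---------------------------------------------------------------------------

def consequence_filter(variants: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Keep variants with at least one protein-changing consequence term.

    Matching is case-sensitive on Sequence Ontology term strings; a variant
    annotated on several transcripts is kept if any annotation qualifies.
    Input order is preserved.
    """
    return [v for v in variants if v.is_protein_changing()]


def ld_r2(
    diplotypes: np.ndarray | list[int],
    variant_dosages: np.ndarray | list[int],
    variant: AnnotatedVariant | None = None,
) -> LDResult:
    """r^2 between diplotype dosages and variant genotype dosages.

    Pairs with a missing value (< 0) on either side are dropped.  If either
    remaining vector is constant, or fewer than two complete pairs remain,
    the result is flagged undefined rather than set to zero.
    """
    d = np.asarray(diplotypes, dtype=float)
    v = np.asarray(variant_dosages, dtype=float)
    if d.shape != v.shape:
        raise ValueError("vectors must be aligned on the same samples")
    ok = (d >= 0) & (v >= 0)
    d, v = d[ok], v[ok]
    n = len(d)

    def _counts(x: np.ndarray) -> tuple[int, int, int]:
        return (int((x == 0).sum()), int((x == 1).sum()), int((x == 2).sum()))

    if n < 2 or np.ptp(d) == 0 or np.ptp(v) == 0:
        return LDResult(variant, None, True, n, _counts(d), _counts(v))
    r = float(np.corrcoef(d, v)[0, 1])
    return LDResult(variant, r * r, False, n, _counts(d), _counts(v))


def candidate_screen(
    region: ScanRegion,
    diplotypes: np.ndarray,
    variants: list[AnnotatedVariant],
    panel_dosages: dict[str, np.ndarray] | None = None,
    r2_threshold: float = 1.0,
    tol: float = 1e-9,
) -> CandidateReport:
    """Screen a region's variants for perfectly linked protein-changing candidates.

    Pipeline: restrict to the region's extended interval, keep
    protein-changing consequences, compute r^2 between the diplotype vector
    and each variant's dosages, and retain variants with
    ``r^2 >= r2_threshold - tol``.  The alt-homozygote count is taken from
    ``panel_dosages`` (a wider panel, keyed by variant) when provided, else
    from the variant's own dosages; a candidate causal recessive lethal is
    expected to show zero.
    """
    if not variants:
        raise DataError("empty variant panel")
    in_region = [
        v
        for v in variants
        if v.chrom == region.chrom and region.ext_start_bp <= v.pos <= region.ext_end_bp
    ]
    protein = consequence_filter(in_region)
    all_ld: list[LDResult] = []
    candidates: list[CandidateRecord] = []
    for v in protein:
        res = ld_r2(diplotypes, v.dosages, variant=v)
        all_ld.append(res)
        if res.undefined or res.r_squared is None:
            continue
        if res.r_squared >= r2_threshold - tol:
            wide = panel_dosages.get(v.key, v.dosages) if panel_dosages else v.dosages
            hom = int((np.asarray(wide) == 2).sum())
            candidates.append(CandidateRecord(v, res, hom))
    return CandidateReport(region, candidates, all_ld)


# ---------------------------------------------------------------------------
# Codon helpers
# ---------------------------------------------------------------------------

def codon_index(cds_position: int) -> int:
    """Codon number containing a 1-based coding nucleotide position."""
    if cds_position < 1:
        raise ValueError("coding position must be >= 1")
    return -(-cds_position // 3)


@dataclass
class FrameshiftEffect:
    affected_codon: int
    ref_residue: str      # three-letter code
    alt_residue: str | None
    ter_offset: int | None  # first stop in the shifted frame, 1 = at affected codon
    hgvs_p: str
    fraction_lost: float
    no_change: bool = False


def _translate(seq: str) -> str:
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = _CODON_TABLE.get(seq[i : i + 3].upper())
        if aa is None:
            raise ValueError(f"unknown codon {seq[i:i + 3]!r}")
        aas.append(aa)
    return "".join(aas)


def frameshift_consequence(cds: str, dup_position: int) -> FrameshiftEffect:
    """Protein consequence of duplicating one base of a coding sequence.

    ``cds`` must start with ATG, end in frame and contain a terminal stop
    codon.  The base at 1-based coding position ``dup_position`` is
    duplicated, the mutant sequence translated, and the result formatted as
    ``p.<Ref><pos><Alt>Ter<k>`` where ``k`` is the stop position in the
    shifted frame counted from the affected codon (inclusive).  When no stop
    is reached the stop offset is reported as ``Ter?``.
    """
    cds = cds.upper().replace(" ", "")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with the ATG start codon")
    if not 1 <= dup_position <= len(cds):
        raise ValueError("duplication position outside the CDS")
    wt = _translate(cds)
    if not wt.endswith("*"):
        raise ValueError("CDS must end with a stop codon")
    mutant_seq = cds[:dup_position] + cds[dup_position - 1] + cds[dup_position:]
    mutant = _translate(mutant_seq)
    affected = codon_index(dup_position)
    wt_res = wt[affected - 1]
    mut_res = mutant[affected - 1] if affected <= len(mutant) else ""
    wt_core = wt[:-1]  # residues before the terminal stop

    star = mutant.find("*", affected - 1)
    ter_offset = star - (affected - 1) + 1 if star >= 0 else None

    if mutant[: star + 1 if star >= 0 else len(mutant)].startswith(wt_core + "*"):
        # duplication leaves every wild-type residue and the stop intact
        return FrameshiftEffect(
            affected_codon=affected,
            ref_residue=_AA3[wt_res],
            alt_residue=None,
            ter_offset=ter_offset,
            hgvs_p="p.(=)",
            fraction_lost=0.0,
            no_change=True,
        )

    ref3 = _AA3[wt_res]
    if mut_res == "*":
        hgvs = f"p.{ref3}{affected}Ter"
        alt3: str | None = "Ter"
    else:
        alt3 = _AA3[mut_res]
        ter = str(ter_offset) if ter_offset is not None else "?"
        hgvs = f"p.{ref3}{affected}{alt3}Ter{ter}"
    lost = (len(wt_core) - (affected - 1)) / len(wt_core) if wt_core else 0.0
    return FrameshiftEffect(
        affected_codon=affected,
        ref_residue=ref3,
        alt_residue=alt3,
        ter_offset=ter_offset,
        hgvs_p=hgvs,
        fraction_lost=lost,
    )


# ---------------------------------------------------------------------------
# Input: SnpEff-style ANN VCF or sidecar annotation TSV
# ---------------------------------------------------------------------------

def _parse_ann(ann: str) -> list[tuple[tuple[str, ...], str, str, str | None, str | None]]:
    """Parse a SnpEff ANN INFO value into (terms, gene, transcript, c., p.) tuples."""
    out = []
    for entry in ann.split(","):
        fields = entry.split("|")
        terms = tuple(t for t in fields[1].split("&") if t) if len(fields) > 1 else ()
        gene = fields[3] if len(fields) > 3 else ""
        transcript = fields[6] if len(fields) > 6 else ""
        c_dot = fields[9] if len(fields) > 9 and fields[9] else None
        p_dot = fields[10] if len(fields) > 10 and fields[10] else None
        out.append((terms, gene, transcript, c_dot, p_dot))
    return out


def load_annotated_variants(
    vcf_path: str | Path,
    sidecar_tsv: str | Path | None = None,
) -> tuple[list[str], list[AnnotatedVariant]]:
    """Load a sequenced-panel VCF, with annotations from ANN or a sidecar TSV.

    Returns the panel sample ids and one :class:`AnnotatedVariant` per
    record, with consequence terms pooled across transcript annotations and
    qualifying transcripts listed.  The sidecar TSV must have columns
    ``chrom pos ref alt gene transcript consequence c_dot``; it overrides or
    supplies annotations when the VCF carries no ANN field.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise DataError(f"no such panel VCF: {vcf_path}")
    sidecar: dict[tuple[str, int, str, str], dict] = {}
    if sidecar_tsv is not None:
        df = pd.read_csv(sidecar_tsv, sep="\t", dtype=str)
        required = {"chrom", "pos", "ref", "alt", "consequence"}
        if not required.issubset(df.columns):
            raise DataError(
                f"annotation sidecar missing columns {sorted(required - set(df.columns))}"
            )
        for row in df.itertuples():
            key = (str(row.chrom), int(row.pos), row.ref, row.alt)
            sidecar[key] = {
                "terms": tuple(t for t in str(row.consequence).split("&") if t),
                "gene": getattr(row, "gene", "") or "",
                "transcript": getattr(row, "transcript", "") or "",
                "c_dot": getattr(row, "c_dot", None),
            }
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    for v in vcf:
        if v.ALT is None or len(v.ALT) != 1:
            raise DataError(f"multi-allelic panel record at {v.CHROM}:{v.POS}")
        gts = np.asarray(v.genotypes, dtype=np.int64)[:, :2]
        dos = np.where((gts < 0).any(axis=1), -1, gts.clip(0).sum(axis=1)).astype(np.int8)
        key = (str(v.CHROM), int(v.POS), v.REF, v.ALT[0])
        ann = v.INFO.get("ANN")
        terms: tuple[str, ...] = ()
        gene = transcript = ""
        c_dot = p_dot = None
        if ann is not None:
            parsed = _parse_ann(str(ann))
            seen: list[str] = []
            for t, g, tr, c, p in parsed:
                for term in t:
                    if term not in seen:
                        seen.append(term)
                if not gene and g:
                    gene, transcript, c_dot, p_dot = g, tr, c, p
            terms = tuple(seen)
        if key in sidecar:
            meta = sidecar[key]
            terms = meta["terms"]
            gene = meta["gene"]
            transcript = meta["transcript"]
            c_dot = meta["c_dot"] if isinstance(meta["c_dot"], str) else c_dot
        if not terms:
            raise DataError(
                f"variant {key[0]}:{key[1]} has no ANN annotation and no sidecar entry"
            )
        variants.append(
            AnnotatedVariant(
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                consequences=terms,
                gene=gene,
                transcript=transcript,
                dosages=dos,
                c_dot=c_dot,
                p_dot=p_dot,
            )
        )
    return samples, variants
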