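"""Synthetic pedigreed populations with embedded recessive-lethal haplotypes.

A gene-drop simulator: founder haplotypes are drawn per marker at
frequencies in a configured range, descendants are produced by Mendelian
segregation with Haldane crossovers (Poisson counts, 1 cM/Mb by default),
and at each configured lethal locus a multi-marker allele pattern is
planted on a chosen fraction of founder haplotypes.  Homozygotes for the
pattern are removed before genotyping with the configured penetrance,
mimicking embryonic lethality that is invisible except through the deficit
of homozygotes.  A sequenced carrier panel with one perfectly linked causal
variant per locus plus background variants can be attached, and the whole
population exports to phased VCF / pedigree TSV / marker map TSV / truth
TSV that round-trip through :mod:`haplodeficit.genodata`.

Crossovers falling inside a lethal-locus span are suppressed (a local
recombination cold spot) so the planted pattern segregates as one unit and
carrier status is well defined by exact string match over the span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genodata import HaplotypeMatrix, MarkerMap, Pedigree
from .linkvar import AnnotatedVariant

_BASES = ("A", "C", "G", "T")

_BACKGROUND_TERMS = (
    "synonymous_variant",
    "intron_variant",
    "missense_variant",
    "intergenic_region",
    "3_prime_UTR_variant",
    "frameshift_variant",
    "5_prime_UTR_variant",
    "stop_gained",
)

_CAUSAL_TERMS = ("frameshift_variant", "missense_variant", "stop_gained")


class SimulationError(Exception):
    """Invalid simulation configuration or unattainable target."""


@dataclass(frozen=True)
class LethalLocusSpec:
    """One recessive lethal haplotype to plant.

    ``target_carrier_frequency`` is the frequency of the lethal allele
    string among founder haplotypes; ``penetrance`` is the probability that
    a homozygote is removed before genotyping.  The causal variant sits
    ``linked_variant_offset_bp`` away from the window center.
    """

    chromosome: int  # 0-based chromosome index
    center_marker: int  # 0-based marker index within the chromosome
    span_markers: int
    target_carrier_frequency: float
    penetrance: float = 1.0
    linked_variant_offset_bp: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_carrier_frequency < 0.5:
            raise SimulationError(
                f"target_carrier_frequency {self.target_carrier_frequency} "
                "outside (0, 0.5)"
            )
        if not 0.0 <= self.penetrance <= 1.0:
            raise SimulationError(f"penetrance {self.penetrance} outside [0, 1]")
        if self.span_markers < 1:
            raise SimulationError("span_markers must be >= 1")

    def span(self, markers_per_chromosome: int) -> tuple[int, int]:
        """Inclusive within-chromosome marker bounds of the locus."""
        half = self.span_markers // 2
        lo = self.center_marker - half
        hi = lo + self.span_markers - 1
        if lo < 0 or hi >= markers_per_chromosome:
            raise SimulationError(
                f"lethal locus span [{lo}, {hi}] outside chromosome with "
                f"{markers_per_chromosome} markers"
            )
        return lo, hi


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 1
    markers_per_chromosome: int = 300
    chromosome_length_bp: int = 30_000_000
    n_founders: int = 120
    n_generations: int = 2
    matings_per_generation: int = 60
    offspring_per_mating: int = 2
    founder_minor_allele_freq_range: tuple[float, float] = (0.05, 0.5)
    n_ancestral_haplotypes: int = 0
    lethal_loci: tuple[LethalLocusSpec, ...] = ()
    genotype_missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    trio_fraction: float = 1.0
    even_parent_usage: bool = True
    seed: int = 0
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.founder_minor_allele_freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError(
                f"founder MAF range ({lo}, {hi}) must lie within (0, 0.5]"
            )
        for name in ("genotype_missing_rate", "genotype_error_rate", "trio_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.n_founders < 2 or self.n_chromosomes < 1:
            raise SimulationError("need at least 2 founders and 1 chromosome")
        if self.markers_per_chromosome < 2:
            raise SimulationError("need at least 2 markers per chromosome")
        object.__setattr__(self, "lethal_loci", tuple(self.lethal_loci))
        for locus in self.lethal_loci:
            if not 0 <= locus.chromosome < self.n_chromosomes:
                raise SimulationError(
                    f"lethal locus chromosome {locus.chromosome} out of range"
                )
            locus.span(self.markers_per_chromosome)  # validates bounds

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


@dataclass(frozen=True)
class TruthLocus:
    """Ground truth for one planted lethal haplotype."""

    spec: LethalLocusSpec
    chrom: str
    start_marker: int  # global marker index, inclusive
    end_marker: int
    start_bp: int
    end_bp: int
    allele_string: str
    variant_pos: int


@dataclass
class SimPopulation:
    pedigree: Pedigree
    haplotypes: HaplotypeMatrix
    marker_map: MarkerMap
    truth: list[TruthLocus]
    removed_ids: set[str]
    config: SimConfig | None = None

    def truth_dosages(self, locus: TruthLocus) -> np.ndarray:
        """Per-matrix-animal dosage (0/1/2) of the lethal allele string."""
        sl = slice(locus.start_marker, locus.end_marker + 1)
        pattern = np.frombuffer(locus.allele_string.encode(), dtype=np.uint8) - ord("0")
        sub = self.haplotypes.alleles[:, sl]
        match = (sub == pattern[None, :]).all(axis=1)
        return (match[0::2].astype(np.int8) + match[1::2].astype(np.int8))


@dataclass
class SequencePanel:
    """Sequenced subset: sample ids, variants, and truth diplotypes."""

    sample_ids: list[str]
    variants: list[AnnotatedVariant]
    diplotypes: dict[int, np.ndarray]  # truth locus index -> dosage per sample


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _marker_map(config: SimConfig) -> MarkerMap:
    spacing = config.chromosome_length_bp // (config.markers_per_chromosome + 1)
    if spacing < 1:
        raise SimulationError("chromosome too short for the marker count")
    ids, chroms, pos = [], [], []
    for c in range(config.n_chromosomes):
        label = str(c + 1)
        for i in range(config.markers_per_chromosome):
            ids.append(f"snp{label}_{i}")
            chroms.append(label)
            pos.append((i + 1) * spacing)
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object), pos)


def _cold_spans_bp(config: SimConfig, mmap: MarkerMap) -> dict[int, list[tuple[int, int]]]:
    """Per-chromosome bp intervals where crossovers are suppressed."""
    out: dict[int, list[tuple[int, int]]] = {}
    mpc = config.markers_per_chromosome
    for locus in config.lethal_loci:
        lo, hi = locus.span(mpc)
        g0 = locus.chromosome * mpc
        out.setdefault(locus.chromosome, []).append(
            (int(mmap.pos[g0 + lo]), int(mmap.pos[g0 + hi]))
        )
    return out


def _meiosis(
    parent_rows: np.ndarray,
    config: SimConfig,
    mmap_pos_by_chrom: list[np.ndarray],
    cold: dict[int, list[tuple[int, int]]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: a crossover mosaic of the parent's two haplotype rows."""
    mpc = config.markers_per_chromosome
    gamete = np.empty(parent_rows.shape[1], dtype=np.int8)
    morgans = config.chromosome_length_bp * config.cm_per_mb / 1e8
    for c in range(config.n_chromosomes):
        n_cx = rng.poisson(morgans)
        xs = np.sort(rng.uniform(0, config.chromosome_length_bp, size=n_cx))
        for lo_bp, hi_bp in cold.get(c, ()):
            xs = xs[(xs < lo_bp) | (xs > hi_bp)]
        start = int(rng.integers(2))
        src = (start + np.searchsorted(xs, mmap_pos_by_chrom[c])) % 2
        sl = slice(c * mpc, (c + 1) * mpc)
        gamete[sl] = np.where(src == 0, parent_rows[0, sl], parent_rows[1, sl])
    return gamete


def simulate_population(config: SimConfig) -> SimPopulation:
    """Gene-drop a pedigreed population with the configured lethal loci.

    Founders carry exactly ``round(2 * n_founders * target_carrier_frequency)``
    copies of each lethal allele string.  Each generation mates randomly
    chosen sires and dams from all earlier generations; offspring homozygous
    for a lethal string die before genotyping with probability
    ``penetrance`` (they stay in the pedigree but never breed and never
    appear in the genotype matrix).  Dams are genotyped with probability
    ``trio_fraction``; males and non-dam roles are always genotyped.
    """
    rng = np.random.default_rng(config.seed)
    mmap = _marker_map(config)
    M = config.n_markers
    mpc = config.markers_per_chromosome
    F = config.n_founders
    total = F + config.n_generations * config.matings_per_generation * config.offspring_per_mating
    alleles = np.empty((2 * total, M), dtype=np.int8)

    # founders: either independent per-marker draws, or draws from a small
    # pool of ancestral haplotypes so multi-marker haplotypes segregate at
    # closed-population frequencies (a few percent each)
    lo, hi = config.founder_minor_allele_freq_range
    freqs = rng.uniform(lo, hi, size=M)
    if config.n_ancestral_haplotypes > 0:
        pool = (
            rng.random((config.n_ancestral_haplotypes, M)) < freqs
        ).astype(np.int8)
        picks = rng.integers(config.n_ancestral_haplotypes, size=2 * F)
        alleles[: 2 * F] = pool[picks]
    else:
        alleles[: 2 * F] = (rng.random((2 * F, M)) < freqs).astype(np.int8)

    # plant lethal cores
    truth: list[TruthLocus] = []
    patterns: list[np.ndarray] = []
    spans: list[tuple[int, int]] = []
    for li, locus in enumerate(config.lethal_loci):
        k = int(round(2 * F * locus.target_carrier_frequency))
        if k < 1:
            raise SimulationError(
                f"lethal locus {li} on chromosome {locus.chromosome}: target "
                f"carrier frequency {locus.target_carrier_frequency} unreachable "
                f"with {F} founders"
            )
        s_lo, s_hi = locus.span(mpc)
        g_lo = locus.chromosome * mpc + s_lo
        g_hi = locus.chromosome * mpc + s_hi
        pattern = rng.integers(0, 2, size=locus.span_markers).astype(np.int8)
        # one row each of k distinct founders: carriers enter as heterozygotes
        carriers = rng.choice(F, size=k, replace=False)
        rows = 2 * carriers + rng.integers(0, 2, size=k)
        alleles[rows, g_lo : g_hi + 1] = pattern
        center_bp = int(mmap.pos[locus.chromosome * mpc + locus.center_marker])
        truth.append(
            TruthLocus(
                spec=locus,
                chrom=str(locus.chromosome + 1),
                start_marker=g_lo,
                end_marker=g_hi,
                start_bp=int(mmap.pos[g_lo]),
                end_bp=int(mmap.pos[g_hi]),
                allele_string="".join(str(int(a)) for a in pattern),
                variant_pos=center_bp + locus.linked_variant_offset_bp,
            )
        )
        patterns.append(pattern)
        spans.append((g_lo, g_hi))

    cold = _cold_spans_bp(config, mmap)
    pos_by_chrom = [
        np.asarray(mmap.pos[c * mpc : (c + 1) * mpc]) for c in range(config.n_chromosomes)
    ]

    ids: list[str] = [f"F{i:04d}" for i in range(F)]
    sires: list[str | None] = [None] * F
    dams: list[str | None] = [None] * F
    sexes: list[int] = [1 if i % 2 == 0 else 2 for i in range(F)]
    alive = np.ones(total, dtype=bool)
    removed_ids: set[str] = set()

    def _dosage(rows: np.ndarray, li: int) -> int:
        g_lo, g_hi = spans[li]
        return int((rows[0, g_lo : g_hi + 1] == patterns[li]).all()) + int(
            (rows[1, g_lo : g_hi + 1] == patterns[li]).all()
        )

    n_animals = F
    for gen in range(1, config.n_generations + 1):
        males = [i for i in range(n_animals) if sexes[i] == 1 and alive[i]]
        females = [i for i in range(n_animals) if sexes[i] == 2 and alive[i]]
        if not males or not females:
            raise SimulationError(f"no breeding {'males' if not males else 'females'} left in generation {gen}")
        pool_start = n_animals
        n_mat = config.matings_per_generation
        if config.even_parent_usage:
            # each parent serves a near-equal number of matings (AI-style),
            # which keeps allele-frequency drift per generation small
            sire_seq = np.concatenate(
                [rng.permutation(males) for _ in range(-(-n_mat // len(males)))]
            )[:n_mat]
            dam_seq = np.concatenate(
                [rng.permutation(females) for _ in range(-(-n_mat // len(females)))]
            )[:n_mat]
        for m in range(n_mat):
            if config.even_parent_usage:
                sire = int(sire_seq[m])
                dam = int(dam_seq[m])
            else:
                sire = males[int(rng.integers(len(males)))]
                dam = females[int(rng.integers(len(females)))]
            for _ in range(config.offspring_per_mating):
                i = n_animals
                rows = alleles[2 * i : 2 * i + 2]
                rows[0] = _meiosis(
                    alleles[2 * sire : 2 * sire + 2], config, pos_by_chrom, cold, rng
                )
                rows[1] = _meiosis(
                    alleles[2 * dam : 2 * dam + 2], config, pos_by_chrom, cold, rng
                )
                aid = f"G{gen}_{i - pool_start:05d}"
                ids.append(aid)
                sires.append(ids[sire])
                dams.append(ids[dam])
                sexes.append(1 if rng.random() < 0.5 else 2)
                for li, locus in enumerate(config.lethal_loci):
                    if _dosage(rows, li) == 2 and rng.random() < locus.penetrance:
                        alive[i] = False
                        removed_ids.add(aid)
                        break
                n_animals += 1

    # genotyped set: alive animals; dams (females) genotyped with trio_fraction
    genotyped = alive[:n_animals].copy()
    if config.trio_fraction < 1.0:
        female = np.array([s == 2 for s in sexes])
        drop = female & (rng.random(n_animals) >= config.trio_fraction)
        genotyped &= ~drop

    g_idx = np.flatnonzero(genotyped)
    rows = np.empty(2 * len(g_idx), dtype=np.int64)
    rows[0::2] = 2 * g_idx
    rows[1::2] = 2 * g_idx + 1
    g_alleles = alleles[rows].copy()

    if config.genotype_error_rate > 0:
        flips = rng.random(g_alleles.shape) < config.genotype_error_rate
        g_alleles[flips] ^= 1
    if config.genotype_missing_rate > 0:
        miss = rng.random((len(g_idx), M)) < config.genotype_missing_rate
        g_alleles[0::2][miss] = -1
        g_alleles[1::2][miss] = -1

    matrix = HaplotypeMatrix([ids[i] for i in g_idx], g_alleles)
    pedigree = Pedigree.from_records(
        (ids[i], sires[i], dams[i], sexes[i]) for i in range(n_animals)
    )
    pop = SimPopulation(pedigree, matrix, mmap, truth, removed_ids, config)
    for li, t in enumerate(truth):
        if not (pop.truth_dosages(t) >= 1).any():
            raise SimulationError(
                f"lethal locus {li}: no surviving genotyped carrier; "
                "increase founders or target frequency"
            )
    return pop


def apply_lethality(
    population: SimPopulation,
    locus: TruthLocus | LethalLocusSpec,
    seed: int | None = None,
) -> SimPopulation:
    """Remove homozygotes for a tracked haplotype from the genotype matrix.

    Each animal homozygous for the locus' allele string is dropped with
    probability equal to the locus penetrance; heterozygotes and
    non-carriers are untouched.  Intended for post-hoc use on populations
    simulated with penetrance 0.
    """
    if isinstance(locus, LethalLocusSpec):
        matches = [t for t in population.truth if t.spec == locus]
        if not matches:
            raise SimulationError("locus spec not found in population truth")
        locus = matches[0]
    rng = np.random.default_rng(seed)
    d = population.truth_dosages(locus)
    hom = np.flatnonzero(d == 2)
    killed = hom[rng.random(len(hom)) < locus.spec.penetrance]
    keep = np.setdiff1d(np.arange(population.haplotypes.n_animals), killed)
    matrix = population.haplotypes.subset_animals(keep)
    removed = set(population.removed_ids) | {
        population.haplotypes.animal_ids[i] for i in killed
    }
    return SimPopulation(
        population.pedigree, matrix, population.marker_map,
        population.truth, removed, population.config,
    )


# ---------------------------------------------------------------------------
# Sequenced carrier panel
# ---------------------------------------------------------------------------

def attach_sequence_panel(
    population: SimPopulation,
    n_carriers: int = 3,
    n_background_variants: int = 20,
    n_noncarriers: int | None = None,
    seed: int | None = None,
) -> SequencePanel:
    """Build a sequenced panel with one causal variant per truth locus.

    For each truth locus, ``n_carriers`` heterozygous carriers are drawn and
    a causal variant emitted whose dosage equals the locus diplotype for
    every panel animal (perfect co-segregation, protein-changing consequence
    term).  ``n_background_variants`` unlinked variants with random dosages
    and mixed consequence terms are added, and ``n_noncarriers`` animals
    carrying none of the truth haplotypes join the panel.
    """
    if n_noncarriers is None:
        n_noncarriers = n_carriers
    rng = np.random.default_rng(seed)
    matrix = population.haplotypes
    dosages = {li: population.truth_dosages(t) for li, t in enumerate(population.truth)}
    panel_idx: list[int] = []
    for li, t in enumerate(population.truth):
        hets = np.flatnonzero(dosages[li] == 1)
        if len(hets) < n_carriers:
            raise SimulationError(
                f"lethal locus {li}: only {len(hets)} heterozygous carriers, "
                f"need {n_carriers}"
            )
        panel_idx.extend(rng.choice(hets, size=n_carriers, replace=False).tolist())
    if n_noncarriers > 0 and population.truth:
        non = np.flatnonzero(
            np.all([d == 0 for d in dosages.values()], axis=0)
        )
        non = np.setdiff1d(non, np.asarray(panel_idx, dtype=np.int64))
        take = min(n_noncarriers, len(non))
        panel_idx.extend(rng.choice(non, size=take, replace=False).tolist())
    panel_idx = sorted(set(panel_idx))
    sample_ids = [matrix.animal_ids[i] for i in panel_idx]
    n_panel = len(sample_ids)

    variants: list[AnnotatedVariant] = []
    taken_pos: set[tuple[str, int]] = set()
    for li, t in enumerate(population.truth):
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        term = _CAUSAL_TERMS[li % len(_CAUSAL_TERMS)]
        variants.append(
            AnnotatedVariant(
                chrom=t.chrom,
                pos=t.variant_pos,
                ref=_BASES[ref],
                alt=_BASES[alt],
                consequences=(term,),
                gene=f"GENE{li + 1}",
                transcript=f"TR{li + 1:03d}.1",
                dosages=dosages[li][panel_idx].astype(np.int8),
                c_dot=f"c.{100 + li}{_BASES[ref]}>{_BASES[alt]}",
            )
        )
        taken_pos.add((t.chrom, t.variant_pos))

    chroms = population.marker_map.chromosomes
    length = (
        population.config.chromosome_length_bp
        if population.config is not None
        else int(population.marker_map.pos.max())
    )
    for b in range(n_background_variants):
        while True:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, length + 1))
            if (chrom, pos) not in taken_pos:
                taken_pos.add((chrom, pos))
                break
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        freq = rng.uniform(0.05, 0.5)
        variants.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref=_BASES[ref],
                alt=_BASES[alt],
                consequences=(_BACKGROUND_TERMS[b % len(_BACKGROUND_TERMS)],),
                gene=f"BG{b + 1}",
                transcript=f"BGTR{b + 1:03d}.1",
                dosages=rng.binomial(2, freq, size=n_panel).astype(np.int8),
            )
        )
    chrom_order = {c: i for i, c in enumerate(chroms)}
    variants.sort(key=lambda v: (chrom_order[v.chrom], v.pos))
    return SequencePanel(
        sample_ids,
        variants,
        {li: dosages[li][panel_idx].astype(np.int8) for li in dosages},
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_GT_CODES = np.array(["0|0", "0|1", "1|0", "1|1", ".|."], dtype=object)


def _write_vcf(
    path: Path,
    sample_ids: list[str],
    alleles: np.ndarray,
    mmap: MarkerMap,
    contig_lengths: dict[str, int],
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplodeficit\n")
        for c in mmap.chromosomes:
            fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        a0 = alleles[0::2]
        a1 = alleles[1::2]
        for j in range(mmap.n_markers):
            g = a0[:, j].astype(np.int64) * 2 + a1[:, j]
            g[(a0[:, j] < 0) | (a1[:, j] < 0)] = 4
            fh.write(
                f"{mmap.chrom[j]}\t{mmap.pos[j]}\t{mmap.ids[j]}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(_GT_CODES[g])
                + "\n"
            )


def export_population(population: SimPopulation, out_dir: str | Path) -> dict[str, Path]:
    """Write phased VCF, pedigree TSV, marker map TSV and truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmap = population.marker_map
    cfg = population.config
    contig_lengths = {
        c: (cfg.chromosome_length_bp if cfg is not None else int(mmap.pos.max()))
        for c in mmap.chromosomes
    }
    paths = {
        "vcf": out_dir / "genotypes.vcf",
        "pedigree": out_dir / "pedigree.tsv",
        "marker_map": out_dir / "markers.tsv",
        "truth": out_dir / "truth.tsv",
    }
    _write_vcf(
        paths["vcf"],
        population.haplotypes.animal_ids,
        population.haplotypes.alleles,
        mmap,
        contig_lengths,
    )
    population.pedigree.to_frame().to_csv(paths["pedigree"], sep="\t", index=False)
    mmap.to_frame().to_csv(paths["marker_map"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        fh.write(
            "locus_id\tchrom\tstart_marker\tend_marker\tstart_bp\tend_bp\t"
            "allele_string\tvariant_pos\tpenetrance\ttarget_frequency\n"
        )
        for li, t in enumerate(population.truth):
            fh.write(
                f"L{li + 1}\t{t.chrom}\t{t.start_marker}\t{t.end_marker}\t"
                f"{t.start_bp}\t{t.end_bp}\t{t.allele_string}\t{t.variant_pos}\t"
                f"{t.spec.penetrance}\t{t.spec.target_carrier_frequency}\n"
            )
    return paths


def export_panel(panel: SequencePanel, out_dir: str | Path) -> dict[str, Path]:
    """Write the panel as a VCF with SnpEff-style ANN plus a sidecar TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel_vcf": out_dir / "panel.vcf",
        "annotations": out_dir / "annotations.tsv",
    }
    gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    chrom_seen: dict[str, int] = {}
    for v in panel.variants:
        chrom_seen[v.chrom] = max(chrom_seen.get(v.chrom, 0), v.pos)
    with open(paths["panel_vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplodeficit\n")
        for c, mx in chrom_seen.items():
            fh.write(f"##contig=<ID={c},length={mx + 1}>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
            "annotations: 'Allele|Annotation|Annotation_Impact|Gene_Name|Gene_ID|"
            "Feature_Type|Feature_ID|Transcript_BioType|Rank|HGVS.c|HGVS.p'\">\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for v in panel.variants:
            ann = (
                f"{v.alt}|{'&'.join(v.consequences)}|MODERATE|{v.gene}|{v.gene}|"
                f"transcript|{v.transcript}|protein_coding|1/1|{v.c_dot or ''}|"
                f"{v.p_dot or ''}"
            )
            gts = "\t".join(gt[int(d)] for d in v.dosages)
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\tANN={ann}\tGT\t{gts}\n"
            )
    with open(paths["annotations"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\ttranscript\tconsequence\tc_dot\n")
        for v in panel.variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene}\t{v.transcript}\t"
                f"{'&'.join(v.consequences)}\t{v.c_dot or ''}\n"
            )
    return paths
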