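"""Missing-homozygosity haplotype scan.

Sliding 50-marker windows are moved marker by marker along each chromosome;
for every window haplotype that is frequent enough the observed number of
homozygous offspring is compared with its expectation, a one-sided exact
Hardy-Weinberg deficit test is computed conditional on the allele count,
p-values are corrected with the Benjamini-Yekutieli step-up procedure, and
significant windows are merged into regions extended by a configurable
margin (default 2 Mb) on both sides.

The exact test conditions on the focal-haplotype allele count
``n_A = 2*n_AA + n_AB`` within the tested cohort and weights each genotype
configuration with the same ``n`` and ``n_A`` proportionally to
``n! * 2**n_AB / (n_AA! * n_AB! * n_BB!)``; the one-sided p-value is the
probability of observing at most the observed number of focal homozygotes.

Two expectation modes are provided because the original analysis tool does
not document its internals: ``hwe`` computes ``E = n * q**2`` over all
analyzed animals, while ``transmission`` accumulates per-offspring
homozygosity probabilities from ancestor diplotypes (sire x dam for trios;
sire x maternal-grandsire with a population-frequency granddam allele for
pgp groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

from .genodata import CohortSets, HaplotypeMatrix, MarkerMap

__all__ = [
    "ScanConfig",
    "Window",
    "HaplotypeRecord",
    "ScanRegion",
    "enumerate_windows",
    "window_haplotypes",
    "diplotypes",
    "expected_homozygotes",
    "deficiency_percent",
    "exact_hwe_deficit_test",
    "by_adjust",
    "scan",
    "build_regions",
]


# ---------------------------------------------------------------------------
# Configuration and records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the homozygosity-deficit scan."""

    window_size: int = 50
    step: int = 1
    alpha: float = 0.05
    min_haplotype_freq: float = 0.01
    min_expected_homozygotes: float = 1.0
    region_extension: int = 2_000_000
    cohort_mode: str = "both"  # trio | pgp | both
    expected_mode: str = "hwe"  # hwe | transmission
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.region_extension < 0:
            raise ValueError("region_extension must be >= 0")
        if self.cohort_mode not in ("trio", "pgp", "both"):
            raise ValueError(f"unknown cohort_mode {self.cohort_mode!r}")
        if self.expected_mode not in ("hwe", "transmission"):
            raise ValueError(f"unknown expected_mode {self.expected_mode!r}")

    @property
    def modes(self) -> tuple[str, ...]:
        return ("trio", "pgp") if self.cohort_mode == "both" else (self.cohort_mode,)


@dataclass(frozen=True)
class Window:
    """One marker window: global inclusive marker indices plus bp interval."""

    chrom: str
    start: int  # global marker index, inclusive
    stop: int   # global marker index, inclusive
    start_bp: int
    end_bp: int

    @property
    def size(self) -> int:
        return self.stop - self.start + 1

    def overlaps(self, other: "Window") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.stop
            and other.start <= self.stop
        )


@dataclass
class HaplotypeRecord:
    """One tested (window, haplotype) pair."""

    window: Window
    allele_string: str
    approach: str
    q: float
    n: int              # analyzed animals (frequency denominator / E basis)
    n_offspring: int    # cohort offspring entering the exact test
    observed: int
    expected: float
    p: float
    p_adj: float = float("nan")
    significant: bool = False

    @property
    def deficiency(self) -> float:
        return deficiency_percent(self.observed, self.expected)


@dataclass
class ScanRegion:
    """Merged run of overlapping significant windows."""

    chrom: str
    start_marker: int
    end_marker: int
    start_bp: int
    end_bp: int
    ext_start_bp: int
    ext_end_bp: int
    top: HaplotypeRecord
    approaches: frozenset[str]
    records: list[HaplotypeRecord] = field(default_factory=list)

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


# ---------------------------------------------------------------------------
# Windows and haplotype counting (reference, string-based API)
# ---------------------------------------------------------------------------

def enumerate_windows(mmap: MarkerMap, config: ScanConfig) -> list[Window]:
    """All windows of ``window_size`` markers, moved by ``step``, per chromosome.

    Chromosomes with fewer markers than the window size are skipped with a
    warning; windows never span a chromosome boundary.
    """
    W = config.window_size
    windows: list[Window] = []
    for c in mmap.chromosomes:
        sl = mmap.chrom_slice(c)
        m = sl.stop - sl.start
        if m < W:
            warnings.warn(
                f"chromosome {c} has {m} markers < window size {W}; skipped",
                stacklevel=2,
            )
            continue
        for j in range(0, m - W + 1, config.step):
            lo = sl.start + j
            hi = lo + W - 1
            windows.append(
                Window(c, lo, hi, int(mmap.pos[lo]), int(mmap.pos[hi]))
            )
    return windows


def _complete_animals(matrix: HaplotypeMatrix, window: Window) -> np.ndarray:
    """Indices of animals with no missing and no unresolved site in the window."""
    sl = slice(window.start, window.stop + 1)
    bad = matrix.alleles[:, sl] < 0
    bad_animal = bad[0::2].any(axis=1) | bad[1::2].any(axis=1)
    bad_animal |= matrix.unresolved[:, sl].any(axis=1)
    return np.flatnonzero(~bad_animal)


def _hap_string(alleles_row: np.ndarray) -> str:
    return "".join("1" if a else "0" for a in alleles_row)


def window_haplotypes(
    matrix: HaplotypeMatrix,
    window: Window,
    animals: np.ndarray | list[int] | None = None,
) -> dict[str, tuple[int, float]]:
    """Tally window haplotypes: ``allele_string -> (count, frequency)``.

    Only animals with two complete, phased window haplotypes contribute;
    frequencies are counts over ``2 * n_complete`` and sum to one.
    """
    complete = _complete_animals(matrix, window)
    if animals is not None:
        complete = np.intersect1d(complete, np.asarray(animals, dtype=np.int64))
    if len(complete) == 0:
        warnings.warn(
            f"window {window.chrom}:{window.start}-{window.stop} has no complete "
            "haplotypes; skipped",
            stacklevel=2,
        )
        return {}
    sl = slice(window.start, window.stop + 1)
    tally: dict[str, int] = {}
    for i in complete:
        for r in (2 * i, 2 * i + 1):
            h = _hap_string(matrix.alleles[r, sl])
            tally[h] = tally.get(h, 0) + 1
    denom = 2 * len(complete)
    return {h: (c, c / denom) for h, c in tally.items()}


def diplotypes(
    matrix: HaplotypeMatrix,
    window: Window,
    focal: str,
    animals: np.ndarray | list[int] | None = None,
) -> np.ndarray:
    """Dosage (0/1/2) of the focal window haplotype per animal; -1 if absent.

    The returned vector is aligned to ``animals`` (or to all animals in the
    matrix); animals with missing or unresolved window data get -1.
    """
    if animals is None:
        animals = np.arange(matrix.n_animals)
    animals = np.asarray(animals, dtype=np.int64)
    complete = set(_complete_animals(matrix, window).tolist())
    sl = slice(window.start, window.stop + 1)
    out = np.full(len(animals), -1, dtype=np.int8)
    for k, i in enumerate(animals):
        if int(i) not in complete:
            continue
        d = 0
        for r in (2 * i, 2 * i + 1):
            if _hap_string(matrix.alleles[r, sl]) == focal:
                d += 1
        out[k] = d
    return out


# ---------------------------------------------------------------------------
# Expectations and deficiency
# ---------------------------------------------------------------------------

def expected_homozygotes(
    n: int | None = None,
    q: float | None = None,
    mode: str = "hwe",
    trio_ancestor_dosages: np.ndarray | None = None,
    pgp_ancestor_dosages: np.ndarray | None = None,
) -> float:
    """Expected count of focal-haplotype homozygotes.

    ``hwe`` mode returns ``n * q**2``.  ``transmission`` mode sums
    per-offspring homozygosity probabilities from ancestor dosages ``d``:
    ``(d_sire/2) * (d_dam/2)`` for trio offspring and
    ``(d_sire/2) * ((d_mgs/2) * 0.5 + q * 0.5)`` for pgp offspring, where the
    maternal-granddam allele is drawn at the population frequency ``q``.
    """
    if q is None or not 0.0 <= q <= 1.0:
        raise ValueError(f"haplotype frequency {q!r} outside [0, 1]")
    if mode == "hwe":
        if n is None:
            raise ValueError("hwe mode requires n")
        return float(n) * q * q
    if mode != "transmission":
        raise ValueError(f"unknown expected mode {mode!r}")
    total = 0.0
    if trio_ancestor_dosages is not None and len(trio_ancestor_dosages):
        d = np.asarray(trio_ancestor_dosages, dtype=float)
        total += float(np.sum((d[:, 0] / 2.0) * (d[:, 1] / 2.0)))
    if pgp_ancestor_dosages is not None and len(pgp_ancestor_dosages):
        d = np.asarray(pgp_ancestor_dosages, dtype=float)
        total += float(
            np.sum((d[:, 0] / 2.0) * ((d[:, 1] / 2.0) * 0.5 + q * 0.5))
        )
    return total


def deficiency_percent(observed: float, expected: float) -> float:
    """Homozygote deficiency ``100 * (E - O) / E``."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return 100.0 * (1.0 - observed / expected)


# ---------------------------------------------------------------------------
# Exact HWE deficit test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=65536)
def _deficit_distribution(n: int, n_a: int) -> tuple[int, np.ndarray]:
    """Conditional distribution of the focal homozygote count.

    Returns ``(n_aa_min, probs)`` where ``probs[k]`` is the probability of
    ``n_AA = n_aa_min + k`` given ``n`` genotypes and ``n_A`` focal alleles.
    Computed in log space to stay overflow-safe for large ``n``.
    """
    n_aa_min = max(0, n_a - n)
    n_aa_max = n_a // 2
    n_aa = np.arange(n_aa_min, n_aa_max + 1)
    n_ab = n_a - 2 * n_aa
    n_bb = n - n_aa - n_ab
    logw = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(n_ab + 1)
        - gammaln(n_bb + 1)
        + n_ab * np.log(2.0)
    )
    probs = np.exp(logw - logsumexp(logw))
    return n_aa_min, probs


def exact_hwe_deficit_test(
    n_AA: int, n_AB: int, n_BB: int, two_sided: bool = False
) -> float:
    """Exact HWE test for a deficit of focal homozygotes.

    Conditions on the total ``n`` and the focal allele count
    ``n_A = 2*n_AA + n_AB`` and returns the one-sided probability of
    observing at most ``n_AA`` focal homozygotes (or, with
    ``two_sided=True``, the summed probability of all configurations no more
    likely than the observed one).
    """
    for name, v in (("n_AA", n_AA), ("n_AB", n_AB), ("n_BB", n_BB)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise ValueError("no genotypes to test")
    n_a = 2 * n_AA + n_AB
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    n_aa_min, probs = _deficit_distribution(n, n_a)
    k = n_AA - n_aa_min
    if two_sided:
        p = float(probs[probs <= probs[k] * (1.0 + 1e-12)].sum())
    else:
        p = float(probs[: k + 1].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Benjamini-Yekutieli correction
# ---------------------------------------------------------------------------

def by_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    ``adjusted_(i) = min_{j >= i} (m * c(m) / j) * p_(j)`` capped at one,
    with ``c(m) = sum_{k=1..m} 1/k``; valid under arbitrary dependence.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return np.empty(0, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    c_m = float(np.sum(1.0 / np.arange(1, m + 1)))
    ranks = np.arange(1, m + 1)
    scaled = p[order] * m * c_m / ranks
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------

def _packed_window_codes(sub: np.ndarray, W: int, step: int) -> np.ndarray:
    """Pack each W-marker window of each haplotype row into one uint64.

    ``sub`` is a (rows, markers) 0/1 array (missing already clipped to 0 and
    handled via validity masks).  Bit ``k`` of a code is the allele at
    window offset ``k``.  Requires ``W <= 64``.
    """
    rows, m = sub.shape
    nw = m - W + 1
    A = sub.astype(np.uint64)
    codes = np.empty((rows, nw), dtype=np.uint64)
    c = np.zeros(rows, dtype=np.uint64)
    for k in range(W):
        c |= A[:, k] << np.uint64(k)
    codes[:, 0] = c
    top = np.uint64(W - 1)
    one = np.uint64(1)
    for j in range(1, nw):
        c = (c >> one) | (A[:, j + W - 1] << top)
        codes[:, j] = c
    return codes[:, ::step]


def _decode(code: int, W: int) -> str:
    # bit k of the code is the allele at window offset k
    return format(int(code), f"0{W}b")[::-1]


def _decode_many(codes: np.ndarray, W: int) -> list[str]:
    """Vectorized decode of packed window codes to allele strings."""
    if len(codes) == 0:
        return []
    b = np.ascontiguousarray(codes, dtype="<u8").view(np.uint8).reshape(-1, 8)
    bits = np.unpackbits(b, axis=1, bitorder="little")[:, :W]
    chars = (bits + ord("0")).astype(np.uint8)
    return [bytes(row).decode("ascii") for row in chars]


def _offspring_indices(
    matrix: HaplotypeMatrix, cohorts: CohortSets, mode: str
) -> np.ndarray:
    off = cohorts.trio_offspring if mode == "trio" else cohorts.pgp_offspring
    idx = [matrix.index_of(a) for a in off if a in matrix]
    return np.asarray(sorted(set(idx)), dtype=np.int64)


def _ancestor_indices(
    matrix: HaplotypeMatrix, cohorts: CohortSets, mode: str
) -> np.ndarray:
    """(n_groups, 3) animal indices: offspring, sire, dam-or-mgs."""
    groups = cohorts.trios if mode == "trio" else cohorts.pgp
    rows = [
        (matrix.index_of(o), matrix.index_of(s), matrix.index_of(x))
        for (o, s, x) in groups
        if o in matrix and s in matrix and x in matrix
    ]
    return np.asarray(rows, dtype=np.int64).reshape(-1, 3)


def scan(
    matrix: HaplotypeMatrix,
    mmap: MarkerMap,
    cohorts: CohortSets,
    config: ScanConfig = ScanConfig(),
) -> list[HaplotypeRecord]:
    """Run the sliding-window homozygosity-deficit scan.

    For every window and every haplotype with frequency >= ``min_haplotype_freq``
    and expectation >= ``min_expected_homozygotes``, the observed homozygote
    count among cohort offspring is tested against the exact conditional
    distribution; p-values are BY-adjusted within each cohort mode and
    records with ``p_adj < alpha`` are flagged significant.

    Haplotype frequencies are estimated from all analyzed animals with
    complete window data; the cohort determines which offspring enter the
    exact test.
    """
    W = config.window_size
    records: list[HaplotypeRecord] = []
    mode_record_idx: dict[str, list[int]] = {m: [] for m in config.modes}
    off_idx = {m: _offspring_indices(matrix, cohorts, m) for m in config.modes}
    anc_idx = (
        {m: _ancestor_indices(matrix, cohorts, m) for m in config.modes}
        if config.expected_mode == "transmission"
        else {}
    )

    for chrom in mmap.chromosomes:
        sl = mmap.chrom_slice(chrom)
        m_chr = sl.stop - sl.start
        if m_chr < W:
            warnings.warn(
                f"chromosome {chrom} has {m_chr} markers < window size {W}; skipped",
                stacklevel=2,
            )
            continue
        sub = matrix.alleles[:, sl]
        bad = sub < 0
        unres = matrix.unresolved[:, sl]
        bad_rows = bad.copy()
        bad_rows[0::2] |= unres
        bad_rows[1::2] |= unres
        # windowed invalidity via cumulative sums
        cs = np.zeros((bad_rows.shape[0], m_chr + 1), dtype=np.int32)
        np.cumsum(bad_rows, axis=1, out=cs[:, 1:])
        starts = np.arange(0, m_chr - W + 1, config.step)
        badcnt = cs[:, starts + W] - cs[:, starts]
        clipped = np.where(sub < 0, 0, sub)
        packed = W <= 64
        if packed:
            # incremental sliding 64-bit packing: bit k = allele at offset k
            c_run = np.zeros(clipped.shape[0], dtype=np.uint64)
            for k in range(W):
                c_run |= clipped[:, k].astype(np.uint64) << np.uint64(k)
            top_shift = np.uint64(W - 1)
            one = np.uint64(1)

        for wi, j in enumerate(starts):
            if packed and wi > 0:
                prev = starts[wi - 1]
                for jj in range(prev + 1, j + 1):
                    c_run = (c_run >> one) | (
                        clipped[:, jj + W - 1].astype(np.uint64) << top_shift
                    )
            lo = sl.start + int(j)
            window = Window(
                chrom, lo, lo + W - 1, int(mmap.pos[lo]), int(mmap.pos[lo + W - 1])
            )
            row_ok = badcnt[:, wi] == 0
            animal_ok = row_ok[0::2] & row_ok[1::2]
            n_ok = int(animal_ok.sum())
            if n_ok == 0:
                warnings.warn(
                    f"window {chrom}:{window.start}-{window.stop} has no complete "
                    "haplotypes; skipped",
                    stacklevel=2,
                )
                continue
            if packed:
                c1 = c_run[0::2]
                c2 = c_run[1::2]
                hap1 = c1[animal_ok]
                hap2 = c2[animal_ok]
                uniq, counts = np.unique(
                    np.concatenate([hap1, hap2]), return_counts=True
                )
                decode = [None] * len(uniq)  # lazy
            else:
                block = np.ascontiguousarray(clipped[:, j : j + W])
                rows2 = np.empty((2 * n_ok, W), dtype=np.uint8)
                ok_animals = np.flatnonzero(animal_ok)
                rows2[0::2] = block[2 * ok_animals]
                rows2[1::2] = block[2 * ok_animals + 1]
                u_rows, inv = np.unique(rows2, axis=0, return_inverse=True)
                uniq = np.arange(len(u_rows))
                counts = np.bincount(inv, minlength=len(u_rows))
                hap1 = inv[0::2]
                hap2 = inv[1::2]
                decode = ["".join(str(int(a)) for a in r) for r in u_rows]

            q = counts / (2.0 * n_ok)
            cand = np.flatnonzero(q >= config.min_haplotype_freq)
            if packed:
                for k, s in zip(cand, _decode_many(uniq[cand], W)):
                    decode[k] = s
            if config.expected_mode == "hwe":
                expectations = n_ok * q * q
            else:
                expectations = None
            for mode in config.modes:
                # offspring with complete windows, positions within the ok set
                off = off_idx[mode]
                if len(off) == 0:
                    continue
                off_ok = off[animal_ok[off]]
                n_off = len(off_ok)
                if n_off == 0:
                    continue
                if packed:
                    o1 = c1[off_ok]
                    o2 = c2[off_ok]
                    i1 = np.searchsorted(uniq, o1)
                    i2 = np.searchsorted(uniq, o2)
                else:
                    pos_of = {int(a): k for k, a in enumerate(ok_animals)}
                    sel = [pos_of[int(a)] for a in off_ok]
                    i1 = hap1[sel]
                    i2 = hap2[sel]
                hom = i1 == i2
                n_u = len(uniq)
                hom_counts = np.bincount(i1[hom], minlength=n_u)
                het_counts = np.bincount(i1[~hom], minlength=n_u) + np.bincount(
                    i2[~hom], minlength=n_u
                )
                if expectations is not None:
                    E_vec = expectations
                else:
                    anc = anc_idx[mode]
                    anc_ok = anc[animal_ok[anc].all(axis=1)] if len(anc) else anc
                    E_vec = None  # computed per candidate below
                for k in cand:
                    if E_vec is not None:
                        E = float(E_vec[k])
                    else:
                        if packed:
                            hk = uniq[k]
                            d_anc = (c1[anc_ok[:, 1:]] == hk).astype(np.int8) + (
                                c2[anc_ok[:, 1:]] == hk
                            ).astype(np.int8)
                        else:
                            d_anc = np.zeros((len(anc_ok), 2), dtype=np.int8)
                            for col in (1, 2):
                                for r, a in enumerate(anc_ok[:, col]):
                                    p = pos_of[int(a)]
                                    d_anc[r, col - 1] = int(hap1[p] == k) + int(
                                        hap2[p] == k
                                    )
                        E = expected_homozygotes(
                            q=float(q[k]),
                            mode="transmission",
                            trio_ancestor_dosages=d_anc if mode == "trio" else None,
                            pgp_ancestor_dosages=d_anc if mode == "pgp" else None,
                        )
                    if E < config.min_expected_homozygotes:
                        continue
                    n_AA = int(hom_counts[k])
                    n_AB = int(het_counts[k])
                    n_BB = n_off - n_AA - n_AB
                    p = exact_hwe_deficit_test(
                        n_AA, n_AB, n_BB, two_sided=config.two_sided
                    )
                    if decode[k] is None:
                        decode[k] = _decode(uniq[k], W)
                    rec = HaplotypeRecord(
                        window=window,
                        allele_string=decode[k],
                        approach=mode,
                        q=float(q[k]),
                        n=n_ok,
                        n_offspring=n_off,
                        observed=n_AA,
                        expected=E,
                        p=p,
                    )
                    mode_record_idx[mode].append(len(records))
                    records.append(rec)

    # BY correction within each cohort-mode family
    for mode, idxs in mode_record_idx.items():
        if not idxs:
            continue
        adj = by_adjust([records[i].p for i in idxs])
        for i, a in zip(idxs, adj):
            records[i].p_adj = float(a)
            records[i].significant = bool(a < config.alpha)
    return records


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def build_regions(
    records: list[HaplotypeRecord],
    mmap: MarkerMap,
    config: ScanConfig = ScanConfig(),
) -> list[ScanRegion]:
    """Merge significant windows into regions with extended intervals.

    Significant windows on the same chromosome sharing at least one marker
    merge transitively (across cohort approaches; the region is labeled with
    every approach that contributed).  The region's top haplotype has the
    lowest p-value (ties: larger deficiency, then leftmost window start);
    the extended interval adds ``region_extension`` bp on each side, clipped
    to ``[1, last marker position of the chromosome]``.
    """
    sig = [r for r in records if r.significant]
    if not sig:
        return []
    chrom_order = {c: i for i, c in enumerate(mmap.chromosomes)}
    sig.sort(key=lambda r: (chrom_order[r.window.chrom], r.window.start, r.window.stop))
    groups: list[list[HaplotypeRecord]] = []
    cur: list[HaplotypeRecord] = [sig[0]]
    cur_end = sig[0].window.stop
    for r in sig[1:]:
        if r.window.chrom == cur[0].window.chrom and r.window.start <= cur_end:
            cur.append(r)
            cur_end = max(cur_end, r.window.stop)
        else:
            groups.append(cur)
            cur = [r]
            cur_end = r.window.stop
    groups.append(cur)

    regions: list[ScanRegion] = []
    for members in groups:
        chrom = members[0].window.chrom
        start_m = min(r.window.start for r in members)
        end_m = max(r.window.stop for r in members)
        start_bp = int(mmap.pos[start_m])
        end_bp = int(mmap.pos[end_m])
        top = min(
            members, key=lambda r: (r.p, -r.deficiency, r.window.start)
        )
        regions.append(
            ScanRegion(
                chrom=chrom,
                start_marker=start_m,
                end_marker=end_m,
                start_bp=start_bp,
                end_bp=end_bp,
                ext_start_bp=max(1, start_bp - config.region_extension),
                ext_end_bp=min(
                    mmap.chrom_end_bp(chrom), end_bp + config.region_extension
                ),
                top=top,
                approaches=frozenset(r.approach for r in members),
                records=members,
            )
        )
    return regions
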