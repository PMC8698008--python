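"""Unit and property tests for the haplotype scan module."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from haplodeficit.genodata import HaplotypeMatrix, MarkerMap, build_cohorts
from haplodeficit.hapscan import (
    HaplotypeRecord,
    ScanConfig,
    Window,
    build_regions,
    by_adjust,
    deficiency_percent,
    diplotypes,
    enumerate_windows,
    exact_hwe_deficit_test,
    expected_homozygotes,
    scan,
    window_haplotypes,
)


def brute_force_deficit_p(n_AA: int, n_AB: int, n_BB: int) -> Fraction:
    """Independent enumeration oracle with exact integer arithmetic."""
    n = n_AA + n_AB + n_BB
    n_a = 2 * n_AA + n_AB
    weights: dict[int, int] = {}
    for ab in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        aa = (n_a - ab) // 2
        bb = n - aa - ab
        if bb < 0:
            continue
        w = (
            math.factorial(n)
            * 2**ab
            // (math.factorial(aa) * math.factorial(ab) * math.factorial(bb))
        )
        weights[aa] = w
    total = sum(weights.values())
    hit = sum(w for aa, w in weights.items() if aa <= n_AA)
    return Fraction(hit, total)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

class TestExactTest:
    def test_worked_example(self):
        # n=5, n_A=4, observed n_AA=0: configurations n_AB in {0,2,4} with
        # weights 10, 120, 80 -> p = 80/210
        assert exact_hwe_deficit_test(0, 4, 1) == pytest.approx(80 / 210, rel=1e-12)

    def test_max_homozygotes_gives_one(self):
        # n_AA at its maximum given n_A: whole support is <= observed
        assert exact_hwe_deficit_test(2, 0, 3) == 1.0

    def test_single_allele_gives_one(self):
        assert exact_hwe_deficit_test(0, 1, 7) == 1.0

    def test_degenerate_no_focal_allele(self):
        assert exact_hwe_deficit_test(0, 0, 9) == 1.0

    def test_all_focal(self):
        assert exact_hwe_deficit_test(5, 0, 0) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            exact_hwe_deficit_test(0, 0, 0)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            exact_hwe_deficit_test(-1, 2, 3)

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8, 12])
    def test_matches_brute_force_small(self, n):
        for n_a in range(0, 2 * n + 1):
            aa_min = max(0, n_a - n)
            for aa in range(aa_min, n_a // 2 + 1):
                ab = n_a - 2 * aa
                bb = n - aa - ab
                if bb < 0:
                    continue
                got = exact_hwe_deficit_test(aa, ab, bb)
                want = float(brute_force_deficit_p(aa, ab, bb))
                assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_large_n_overflow_safe(self):
        p = exact_hwe_deficit_test(0, 300, 1700)
        assert 0.0 < p < 1e-4

    def test_two_sided_at_least_one_sided_mass(self):
        one = exact_hwe_deficit_test(0, 6, 4)
        two = exact_hwe_deficit_test(0, 6, 4, two_sided=True)
        assert 0 < one <= 1 and 0 < two <= 1


# ---------------------------------------------------------------------------
# Benjamini-Yekutieli
# ---------------------------------------------------------------------------

class TestByAdjust:
    def test_single_p_unchanged(self):
        assert by_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_example(self):
        # m=3, c(3)=11/6: (0.01, 0.02, 0.9) -> (0.055, 0.055, 1)
        adj = by_adjust([0.01, 0.02, 0.9])
        assert adj == pytest.approx([0.055, 0.055, 1.0], rel=1e-12)

    def test_empty(self):
        assert by_adjust([]).size == 0

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            by_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            by_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_statsmodels_and_inflates(self, pvals):
        adj = by_adjust(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_by")
        assert adj == pytest.approx(ref, rel=1e-9, abs=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-15).all()

    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_order_preserving(self, pvals):
        p = np.asarray(pvals)
        adj = by_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# Expectations / deficiency
# ---------------------------------------------------------------------------

class TestExpectedHomozygotes:
    def test_hwe_printed_cells(self):
        assert round(expected_homozygotes(9965, 0.062)) == 38
        assert round(expected_homozygotes(9965, 0.032)) == 10
        assert round(expected_homozygotes(9965, 0.055)) == 30

    def test_transmission_pgp_hand_value(self):
        # sire het, maternal grandsire het, q=0 -> (1/2)*((1/2)*(1/2)) = 1/8
        e = expected_homozygotes(
            q=0.0, mode="transmission", pgp_ancestor_dosages=np.array([[1, 1]])
        )
        assert e == pytest.approx(1 / 8)

    def test_transmission_trio(self):
        e = expected_homozygotes(
            q=0.1,
            mode="transmission",
            trio_ancestor_dosages=np.array([[1, 1], [2, 1], [0, 2]]),
        )
        assert e == pytest.approx(0.25 + 0.5 + 0.0)

    def test_bad_q_raises(self):
        with pytest.raises(ValueError):
            expected_homozygotes(100, 1.5)

    def test_deficiency(self):
        assert deficiency_percent(0, 10.0) == 100.0
        E = expected_homozygotes(9965, 0.040)
        assert round(deficiency_percent(1, E)) == 94
        with pytest.raises(ValueError):
            deficiency_percent(1, 0.0)


# ---------------------------------------------------------------------------
# Windows, haplotype counting, diplotypes
# ---------------------------------------------------------------------------

def _map_one_chrom(m: int, chrom: str = "1", spacing: int = 1000) -> MarkerMap:
    return MarkerMap(
        np.array([f"m{chrom}_{i}" for i in range(m)], dtype=object),
        np.array([chrom] * m, dtype=object),
        np.arange(1, m + 1) * spacing,
    )


def _concat_maps(maps: list[MarkerMap]) -> MarkerMap:
    return MarkerMap(
        np.concatenate([mp.ids for mp in maps]),
        np.concatenate([mp.chrom for mp in maps]),
        np.concatenate([mp.pos for mp in maps]),
    )


class TestEnumerateWindows:
    def test_m_minus_w_plus_one(self):
        ws = enumerate_windows(_map_one_chrom(100), ScanConfig(window_size=50))
        assert len(ws) == 51

    def test_single_window(self):
        ws = enumerate_windows(_map_one_chrom(50), ScanConfig(window_size=50))
        assert len(ws) == 1

    def test_two_chromosomes(self):
        mmap = _concat_maps([_map_one_chrom(60, "1"), _map_one_chrom(60, "2")])
        ws = enumerate_windows(mmap, ScanConfig(window_size=50))
        assert len(ws) == 22
        assert all(w.size == 50 for w in ws)
        assert {w.chrom for w in ws} == {"1", "2"}

    def test_short_chromosome_skipped_with_warning(self):
        mmap = _concat_maps([_map_one_chrom(60, "1"), _map_one_chrom(10, "2")])
        with pytest.warns(UserWarning, match="chromosome 2"):
            ws = enumerate_windows(mmap, ScanConfig(window_size=50))
        assert {w.chrom for w in ws} == {"1"}


def _matrix_from_haps(haps: list[str]) -> HaplotypeMatrix:
    """Build a matrix from one haplotype string per row (2 rows per animal)."""
    arr = np.array([[int(c) for c in h] for h in haps], dtype=np.int8)
    n = len(haps) // 2
    return HaplotypeMatrix([f"A{i}" for i in range(n)], arr)


class TestWindowHaplotypes:
    def test_single_haplotype(self):
        h = "01101"
        m = _matrix_from_haps([h] * 8)
        w = Window("1", 0, 4, 1, 5)
        res = window_haplotypes(m, w)
        assert res == {h: (8, 1.0)}

    def test_direct_counts(self):
        m = _matrix_from_haps(["00000", "00000", "00000", "11111"])
        w = Window("1", 0, 4, 1, 5)
        res = window_haplotypes(m, w)
        assert res["00000"] == (3, 0.75)
        assert res["11111"] == (1, 0.25)

    def test_frequencies_sum_to_one(self, recovery_pop):
        w = Window("1", 10, 59, 1, 1)
        res = window_haplotypes(recovery_pop.haplotypes, w)
        assert sum(q for _, q in res.values()) == pytest.approx(1.0)

    def test_missing_excludes_animal(self):
        m = _matrix_from_haps(["00000", "00000", "11111", "11111"])
        m.alleles[2, 3] = -1
        w = Window("1", 0, 4, 1, 5)
        res = window_haplotypes(m, w)
        assert res == {"00000": (2, 1.0)}

    def test_empty_window_warns(self):
        m = _matrix_from_haps(["000", "000"])
        m.alleles[:, :] = -1
        with pytest.warns(UserWarning, match="no complete"):
            assert window_haplotypes(m, Window("1", 0, 2, 1, 3)) == {}


class TestDiplotypes:
    def test_hom_het_none(self):
        m = _matrix_from_haps(
            ["00000", "00000", "00000", "11111", "11111", "11111"]
        )
        w = Window("1", 0, 4, 1, 5)
        d = diplotypes(m, w, "00000")
        assert d.tolist() == [2, 1, 0]

    def test_missing_marked_absent(self):
        m = _matrix_from_haps(["00000", "00000"])
        m.alleles[0, 0] = -1
        d = diplotypes(m, Window("1", 0, 4, 1, 5), "00000")
        assert d.tolist() == [-1]

    def test_sum_identity(self, recovery_pop):
        # sum of dosages equals 2 * n * q for every tallied haplotype
        w = Window("1", 30, 79, 1, 1)
        res = window_haplotypes(recovery_pop.haplotypes, w)
        for h, (count, q) in list(res.items())[:5]:
            d = diplotypes(recovery_pop.haplotypes, w, h)
            assert d[d >= 0].sum() == count


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scan_records(recovery_pop, recovery_cohorts):
    cfg = ScanConfig(cohort_mode="trio")
    return scan(
        recovery_pop.haplotypes, recovery_pop.marker_map, recovery_cohorts, cfg
    )


class TestScan:
    def test_recovers_lethal_haplotype(self, recovery_pop, scan_records):
        t = recovery_pop.truth[0]
        top = min(scan_records, key=lambda r: (r.p_adj, r.p))
        assert top.significant
        assert top.observed == 0
        assert top.window.start >= t.start_marker - 49
        assert top.window.stop <= t.end_marker + 49
        # the top window's haplotype matches the planted core substring
        off = top.window.start - t.start_marker
        if 0 <= off and top.window.stop <= t.end_marker:
            assert top.allele_string == t.allele_string[off : off + 50]

    def test_zero_observed_is_full_deficiency(self, scan_records):
        zeros = [r for r in scan_records if r.observed == 0]
        assert zeros and all(r.deficiency == 100.0 for r in zeros)

    def test_matches_string_tally_oracle(self, recovery_pop, recovery_cohorts, scan_records):
        cfg = ScanConfig(cohort_mode="trio")
        matrix = recovery_pop.haplotypes
        idx = np.asarray(
            sorted(matrix.index_of(o) for o in set(recovery_cohorts.trio_offspring)),
            dtype=np.int64,
        )
        window = scan_records[0].window
        oracle = window_haplotypes(matrix, window)
        for r in scan_records:
            if r.window != window:
                continue
            count, q = oracle[r.allele_string]
            assert r.q == pytest.approx(q)
            d = diplotypes(matrix, window, r.allele_string, idx)
            assert r.observed == int((d == 2).sum())

    def test_padj_at_least_p(self, scan_records):
        assert all(r.p_adj >= r.p - 1e-15 for r in scan_records)
        assert all(0 < r.p <= 1 for r in scan_records)

    def test_expected_consistent_with_hwe(self, scan_records):
        r = scan_records[0]
        assert r.expected == pytest.approx(r.n * r.q**2)

    def test_transmission_mode_runs(self, recovery_pop, recovery_cohorts):
        cfg = ScanConfig(cohort_mode="trio", expected_mode="transmission")
        recs = scan(
            recovery_pop.haplotypes, recovery_pop.marker_map, recovery_cohorts, cfg
        )
        assert recs
        top = min(recs, key=lambda r: (r.p_adj, r.p))
        assert top.significant and top.observed == 0

    def test_wide_window_fallback_matches_packed(self, recovery_pop, recovery_cohorts):
        # windows > 64 markers cannot be packed into one uint64 and use the
        # row-unique fallback; spot-check it against the string-tally oracle
        cfg = ScanConfig(window_size=70, cohort_mode="trio", step=30)
        recs = scan(
            recovery_pop.haplotypes, recovery_pop.marker_map, recovery_cohorts, cfg
        )
        assert recs
        window = recs[0].window
        assert window.size == 70
        oracle = window_haplotypes(recovery_pop.haplotypes, window)
        for r in recs:
            if r.window != window:
                continue
            count, q = oracle[r.allele_string]
            assert r.q == pytest.approx(q)

    def test_eligibility_thresholds_filter_tests(self, recovery_pop, recovery_cohorts):
        strict = ScanConfig(cohort_mode="trio", min_haplotype_freq=0.06)
        loose = ScanConfig(cohort_mode="trio", min_haplotype_freq=0.01)
        n_strict = len(
            scan(recovery_pop.haplotypes, recovery_pop.marker_map, recovery_cohorts, strict)
        )
        n_loose = len(
            scan(recovery_pop.haplotypes, recovery_pop.marker_map, recovery_cohorts, loose)
        )
        assert 0 < n_strict < n_loose

    def test_both_modes_label_records(self, multigen_pop):
        cohorts = build_cohorts(
            multigen_pop.pedigree, set(multigen_pop.haplotypes.animal_ids)
        )
        cfg = ScanConfig(cohort_mode="both", min_expected_homozygotes=0.2)
        recs = scan(multigen_pop.haplotypes, multigen_pop.marker_map, cohorts, cfg)
        assert {r.approach for r in recs} == {"trio", "pgp"}


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def _sig_record(mmap: MarkerMap, start: int, approach: str, p: float = 1e-6) -> HaplotypeRecord:
    w = Window(
        str(mmap.chrom[start]), start, start + 49,
        int(mmap.pos[start]), int(mmap.pos[start + 49]),
    )
    return HaplotypeRecord(
        window=w, allele_string="0" * 50, approach=approach, q=0.05,
        n=1000, n_offspring=800, observed=0, expected=2.5, p=p, p_adj=p * 10,
        significant=True,
    )


class TestBuildRegions:
    def test_overlap_merge(self):
        mmap = _map_one_chrom(200)
        recs = [_sig_record(mmap, 10, "trio"), _sig_record(mmap, 11, "trio")]
        regions = build_regions(recs, mmap, ScanConfig())
        assert len(regions) == 1
        assert regions[0].start_marker == 10
        assert regions[0].end_marker == 60

    def test_different_chromosomes_stay_apart(self):
        mmap = _concat_maps([_map_one_chrom(60, "1"), _map_one_chrom(60, "2")])
        recs = [_sig_record(mmap, 0, "trio"), _sig_record(mmap, 60, "trio")]
        assert len(build_regions(recs, mmap, ScanConfig())) == 2

    def test_no_significant_gives_empty(self):
        mmap = _map_one_chrom(100)
        r = _sig_record(mmap, 0, "trio")
        r.significant = False
        assert build_regions([r], mmap, ScanConfig()) == []

    def test_top_is_min_p(self):
        mmap = _map_one_chrom(200)
        a = _sig_record(mmap, 10, "trio", p=1e-4)
        b = _sig_record(mmap, 12, "pgp", p=1e-8)
        region = build_regions([a, b], mmap, ScanConfig())[0]
        assert region.top is b
        assert region.approaches == frozenset({"trio", "pgp"})

    def test_extension_clipped_to_chromosome(self):
        mmap = _map_one_chrom(100, spacing=1000)  # chromosome spans 1..100 kb
        region = build_regions([_sig_record(mmap, 0, "trio")], mmap, ScanConfig())[0]
        assert region.ext_start_bp == 1
        assert region.ext_end_bp == int(mmap.pos[-1])
        assert region.ext_start_bp <= region.start_bp
        assert region.ext_end_bp >= region.end_bp

    def test_union_arithmetic_seven_plus_nine_minus_five(self):
        # 7 trio windows, 9 pgp windows, 5 of them overlapping -> 11 regions
        mmap = _map_one_chrom(2500)
        trio_starts = [i * 200 for i in range(7)]
        shared = trio_starts[:5]
        pgp_starts = shared + [1400, 1600, 1800, 2000]
        recs = [_sig_record(mmap, s, "trio") for s in trio_starts]
        recs += [_sig_record(mmap, s, "pgp") for s in pgp_starts]
        regions = build_regions(recs, mmap, ScanConfig())
        assert len(regions) == 7 + 9 - 5
        both = [r for r in regions if r.approaches == {"trio", "pgp"}]
        assert len(both) == 5
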