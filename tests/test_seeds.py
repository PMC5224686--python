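"""Seed discovery: windows, site variants, conservation, nulls, calls."""

import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trfkit.io import (
    REQUIRED_TRIO,
    TAXONOMY_IDS,
    DataError,
    MatchType,
    UTRBlock,
    revcomp,
)
from trfkit import seeds as ts

KMER = st.text(alphabet="ACGT", min_size=7, max_size=7)


# ---------------------------------------------------------------------------
# Independent naive oracle (string slicing per species, no shared code)


def oracle_gene_count(kmer, blocks, rule, orientation="complementary"):
    """Full re-scan of every species in every block, written independently."""
    if orientation == "complementary":
        sites = [revcomp(kmer), revcomp(kmer[:6]) + "A"]
    else:
        sites = [kmer, kmer[:6] + "A"]
    genes = set()
    for block in blocks:
        if rule.reference not in block.rows:
            continue
        ref_gapped = block.rows[rule.reference]
        # map each ungapped index to its column
        cols = [i for i, ch in enumerate(ref_gapped) if ch != "-"]
        ref = ref_gapped.replace("-", "")
        for site in sites:
            for i in range(len(ref) - len(site) + 1):
                if ref[i : i + len(site)] != site:
                    continue
                lo, hi = cols[i], cols[i + len(site) - 1]
                carriers = set()
                for tax, row in block.rows.items():
                    if rule.aligned_columns:
                        chunk = "".join(
                            ch for ch in row[lo : hi + 1] if ch != "-"
                        )
                        if chunk == site:
                            carriers.add(tax)
                    elif site in row.replace("-", ""):
                        carriers.add(tax)
                if len(carriers) >= rule.min_species and rule.required <= carriers:
                    genes.add(block.gene_id)
    return len(genes)


# ---------------------------------------------------------------------------
# Windows


class TestSlidingWindows:
    def test_count_is_length_minus_six(self):
        seq = "".join(random.Random(0).choices("ACGT", k=18))
        assert len(ts.sliding_windows("t", seq)) == 12

    def test_first_and_last_offsets(self):
        seq = "ACGTACGTACGTACG"  # 15 nt
        ws = ts.sliding_windows("t", seq)
        assert (ws[0].offset, ws[0].kmer) == (1, seq[:7])
        assert (ws[-1].offset, ws[-1].kmer) == (9, seq[8:])

    def test_seven_nt_input_single_window(self):
        (w,) = ts.sliding_windows("t", "ACCTGGA")
        assert w.kmer == "ACCTGGA"

    def test_short_sequence_rejected(self):
        with pytest.raises(DataError):
            ts.sliding_windows("t", "ACGTAC")


class TestSiteVariants:
    def test_worked_example(self):
        v = ts.site_variants("ACCTGGA")
        assert v[MatchType.M7_M8] == "TCCAGGT"
        assert v[MatchType.M7_1A] == "CCAGGTA"
        assert v[MatchType.M8_1A] == "TCCAGGTA"

    @given(KMER)
    def test_8mer_extends_7mer_m8_with_a(self, kmer):
        v = ts.site_variants(kmer)
        assert v[MatchType.M8_1A] == v[MatchType.M7_M8] + "A"
        assert v[MatchType.M7_1A] == v[MatchType.M8_1A][1:]

    def test_palindromic_complement_core_fixed_point(self):
        # no odd-length reverse-complement palindrome exists, so the fixed
        # point shows up in the 6-nt core of the 1a variant instead
        window = "ACGCGTC"
        assert revcomp(window[:6]) == window[:6]
        assert ts.site_variants(window)[MatchType.M7_1A] == window[:6] + "A"

    def test_direct_orientation_literal(self):
        v = ts.site_variants("ACCTGGA", orientation="direct")
        assert v[MatchType.M7_M8] == "ACCTGGA"
        assert v[MatchType.M7_1A] == "ACCTGGA"[:6] + "A"

    def test_bad_alphabet_rejected(self):
        with pytest.raises(DataError):
            ts.site_variants("ACCTGGN")


# ---------------------------------------------------------------------------
# Hand-built conservation fixtures


def _block(gene, site, carriers, n_cols=60, insert_at=20, seed=0):
    """A block where `site` occupies shared columns in `carriers` only."""
    rng = random.Random(seed)
    rows = {}
    for tax in TAXONOMY_IDS:
        chars = [rng.choice("ACGT") for _ in range(n_cols)]
        span = chars[insert_at : insert_at + len(site)]
        if tax in carriers:
            chars[insert_at : insert_at + len(site)] = list(site)
        elif "".join(span) == site:
            chars[insert_at] = "A" if site[0] != "A" else "C"
        rows[tax] = "".join(chars)
    return UTRBlock(gene_id=gene, rows=rows)


TRIO = sorted(REQUIRED_TRIO)
OTHERS = [t for t in TAXONOMY_IDS if t not in REQUIRED_TRIO]


class TestFindSites:
    WINDOW = "ACCTGGA"
    SITE = "TCCAGGT"  # 7mer-m8 of the window

    def variants(self):
        return {MatchType.M7_M8: self.SITE}

    def test_site_in_16_species_with_trio_is_conserved(self):
        carriers = set(TRIO) | set(OTHERS[:13])
        block = _block("G1", self.SITE, carriers)
        recs = ts.find_sites_in_block(self.variants(), block, ts.ConservationRule())
        assert len(recs) == 1
        assert len(recs[0].species) == 16
        assert recs[0].utr_end - recs[0].utr_start + 1 == 7

    def test_fifteen_species_without_rat_not_conserved(self):
        carriers = {9606, 10090} | set(OTHERS[:13])  # 15 total, rat missing
        block = _block("G1", self.SITE, carriers, seed=1)
        # rat must carry the occurrence for it to be anchored at all; plant
        # it in rat but outside the shared columns
        rows = dict(block.rows)
        rat = rows[10116]
        rows[10116] = self.SITE + rat[7:]
        block = UTRBlock("G1", rows)
        recs = ts.find_sites_in_block(self.variants(), block, ts.ConservationRule())
        assert recs == []

    def test_fourteen_species_with_trio_below_threshold(self):
        carriers = set(TRIO) | set(OTHERS[:11])  # 14 total
        block = _block("G1", self.SITE, carriers, seed=2)
        recs = ts.find_sites_in_block(self.variants(), block, ts.ConservationRule())
        assert recs == []

    def test_msa_and_utr_coordinates_agree_without_gaps(self):
        carriers = set(TRIO) | set(OTHERS[:13])
        block = _block("G1", self.SITE, carriers, insert_at=10)
        (rec,) = ts.find_sites_in_block(self.variants(), block, ts.ConservationRule())
        assert (rec.msa_start, rec.msa_end) == (11, 17)
        assert (rec.utr_start, rec.utr_end) == (11, 17)

    def test_reference_absent_block_skipped_with_warning(self):
        block = _block("G1", self.SITE, set(TRIO))
        rows = {t: s for t, s in block.rows.items() if t != 10116}
        block = UTRBlock("G1", rows)
        with pytest.warns(UserWarning, match="reference"):
            assert ts.find_sites_in_block(self.variants(), block, ts.ConservationRule()) == []


class TestObservedCount:
    def test_counts_planted_genes(self, planted_windows, utr_data, rule, conservation_index):
        blocks, truth = utr_data
        for w in truth.windows:
            n = ts.observed_count(w.kmer, None, rule, index=conservation_index)
            assert n >= len(w.genes)

    def test_per_gene_dedup(self):
        window = "ACCTGGA"
        site = revcomp(window)
        carriers = set(TRIO) | set(OTHERS[:13])
        b1 = _block("G1", site, carriers, n_cols=80, insert_at=10, seed=3)
        # plant a second occurrence in the same gene
        rows = {
            t: (s[:50] + site + s[57:]) if t in carriers else s
            for t, s in b1.rows.items()
        }
        b1 = UTRBlock("G1", rows)
        assert ts.observed_count(window, [b1], ts.ConservationRule()) == 1

    def test_matches_naive_oracle_on_synthetic_blocks(
        self, utr_blocks, rule, conservation_index, planted_windows
    ):
        rng = random.Random(13)
        kmers = [w.kmer for w in planted_windows]
        kmers += ["".join(rng.choices("ACGT", k=7)) for _ in range(10)]
        for kmer in kmers:
            fast = ts.observed_count(kmer, None, rule, index=conservation_index)
            assert fast == oracle_gene_count(kmer, utr_blocks, rule)

    def test_index_agrees_with_per_block_search(self, utr_blocks, rule, planted_windows):
        kmer = planted_windows[0].kmer
        slow = ts.observed_count(kmer, utr_blocks, rule)
        fast = ts.observed_count(
            kmer, None, rule, index=ts.ConservationIndex(utr_blocks, rule)
        )
        assert slow == fast


class TestAlignedVsAnywhere:
    def test_anywhere_mode_counts_unanchored_matches(self):
        window = "ACCTGGA"
        site = revcomp(window)
        carriers = set(TRIO) | set(OTHERS[:12])  # 15
        block = _block("G1", site, carriers, n_cols=80, seed=5)
        # one more species carries the site at different columns
        extra = OTHERS[15]
        rows = dict(block.rows)
        rows[extra] = site + rows[extra][7:]
        block = UTRBlock("G1", rows)
        aligned = ts.ConservationRule()
        anywhere = ts.ConservationRule(aligned_columns=False, min_species=16)
        assert ts.observed_count(window, [block], aligned) == 1
        assert ts.observed_count(window, [block], anywhere) == 1
        stricter = ts.ConservationRule(min_species=16)
        assert ts.observed_count(window, [block], stricter) == 0


class TestOrientationEquivalence:
    def test_direct_on_revcomp_blocks_reproduces_complementary_m8(
        self, utr_blocks, rule, planted_windows
    ):
        # the m8 site is strand-symmetric: searching the literal window in
        # reverse-complemented UTRs equals searching its complement in the
        # originals; 1a variants are not (the A stays on the target 3' side)
        flipped = [
            UTRBlock(b.gene_id, {t: revcomp(s) for t, s in b.rows.items()})
            for b in utr_blocks[:120]
        ]
        for w in planted_windows:
            comp_site = ts.site_variants(w.kmer, "complementary")[MatchType.M7_M8]
            direct_site = ts.site_variants(w.kmer, "direct")[MatchType.M7_M8]
            a = {
                b.gene_id
                for b in utr_blocks[:120]
                if ts.find_sites_in_block({MatchType.M7_M8: comp_site}, b, rule)
            }
            b_ = {
                b.gene_id
                for b in flipped
                if ts.find_sites_in_block({MatchType.M7_M8: direct_site}, b, rule)
            }
            assert a == b_


# ---------------------------------------------------------------------------
# Nulls


class TestExpectedGenomicCount:
    def test_arithmetic(self, conservation_index, rule):
        # one background seq of 16 positions with exactly one site occurrence
        window = "ACCTGGA"
        site = revcomp(window)
        bg = [site + "T" * 15]  # 22 nt -> 16 positions, 1 occurrence
        exp = ts.expected_genomic_count(window, bg, None, rule, index=conservation_index)
        assert exp == pytest.approx(
            (1 / 16) * conservation_index.n_reference_positions
        )

    def test_uniform_background_frequency_near_4_to_minus_7(self, rule, conservation_index):
        rng = np.random.default_rng(3)
        bg = ["".join(rng.choice(list("ACGT"), 50_000)) for _ in range(10)]
        window = "ACGTCAG"
        exp = ts.expected_genomic_count(window, bg, None, rule, index=conservation_index)
        n_positions = sum(len(s) - 6 for s in bg)
        f = exp / conservation_index.n_reference_positions
        p = 0.25**7
        se = math.sqrt(p * (1 - p) / n_positions)
        assert abs(f - p) < 3 * se + 1e-12

    def test_absent_site_floors_at_zero_with_warning(self, rule, conservation_index):
        with pytest.warns(UserWarning, match="absent"):
            exp = ts.expected_genomic_count(
                "AAAAAAA", ["CCCCCCCCCCCC"], None, rule, index=conservation_index
            )
        assert exp == 0.0

    def test_empty_background_rejected(self, rule, conservation_index):
        with pytest.raises(DataError):
            ts.expected_genomic_count("AAAAAAA", [], None, rule, index=conservation_index)


class TestCompositionNull:
    def test_homopolymer_falls_back_to_self_with_warning(self, rule, conservation_index):
        with pytest.warns(UserWarning, match="single-permutation"):
            mean = ts.composition_null("AAAAAAA", None, rule, index=conservation_index)
        assert mean == ts.observed_count("AAAAAAA", None, rule, index=conservation_index)

    def test_near_homopolymer_enumerates_seven(self):
        perms = {"".join(p) for p in itertools.permutations("AAAAAAG")}
        assert len(perms) == 7

    def test_permutation_invariance_same_multiset(self, rule, conservation_index):
        a = ts.composition_null("ACCTGGA", None, rule, index=conservation_index,
                                exclude_self=False)
        b = ts.composition_null("AGGTCCA", None, rule, index=conservation_index,
                                exclude_self=False)
        assert a == pytest.approx(b)

    def test_planted_window_far_exceeds_composition_null(
        self, utr_data, rule, conservation_index
    ):
        _, truth = utr_data
        for w in truth.windows:
            obs = ts.observed_count(w.kmer, None, rule, index=conservation_index)
            null = ts.composition_null(w.kmer, None, rule, index=conservation_index)
            assert obs > 2 * null


class TestCallSeed:
    def _res(self, obs, exp, comp):
        w = ts.SeedWindow("t", 1, "ACCTGGA")
        return ts.SeedCallResult(w, obs, exp, comp)

    def test_clear_enrichment_called(self):
        assert ts.call_seed(self._res(100, 20.0, 30.0))

    def test_weak_composition_ratio_not_called(self):
        assert not ts.call_seed(self._res(40, 5.0, 35.0))

    def test_min_gene_floor(self):
        assert ts.call_seed(self._res(30, 1.0, 1.0), min_genes=25)
        assert not ts.call_seed(self._res(30, 1.0, 1.0), min_genes=35)


# ---------------------------------------------------------------------------
# Profiles and targets


class TestSeedProfile:
    def test_planted_offset_is_argmax_and_called(
        self, utr_data, read_libraries, background, rule, conservation_index, utr_blocks
    ):
        _, truth = utr_data
        _, lib_truth = read_libraries
        for w in truth.windows:
            trf = next(t for t in lib_truth.trfs if t.trf_id == w.trf_id)
            profile = ts.seed_profile(
                trf.trf_id, trf.sequence, utr_blocks, background, rule,
                index=conservation_index,
            )
            assert len(profile) == len(trf.sequence) - 6
            called = [r.window.offset for r in profile if r.called]
            assert called == [w.offset]
            best = max(profile, key=lambda r: r.observed)
            assert best.window.offset == w.offset

    def test_seed_detectable_at_either_trf_end(self, sim_config, read_libraries):
        from trfkit.simulate import (
            choose_planted_windows,
            simulate_utr_alignments,
        )

        _, truth = read_libraries
        trf = truth.trfs[0]
        last = len(trf.sequence) - 6
        windows = [
            choose_planted_windows(truth.trfs, sim_config, n_windows=1, offset=1)[0],
            choose_planted_windows(truth.trfs, sim_config, n_windows=1, offset=last)[0],
        ]
        windows[1] = type(windows[1])(
            trf_id=windows[1].trf_id + "#end", offset=windows[1].offset,
            kmer=windows[1].kmer,
        )
        cfg = type(sim_config)(seed=77, n_genes=120)
        blocks, utruth = simulate_utr_alignments(cfg, windows)
        rule = ts.ConservationRule()
        idx = ts.ConservationIndex(blocks, rule)
        for w in utruth.windows:
            assert ts.observed_count(w.kmer, None, rule, index=idx) >= len(w.genes)


class TestPredictTargets:
    def test_planted_genes_all_predicted(
        self, utr_data, rule, utr_blocks
    ):
        _, truth = utr_data
        w = truth.windows[0]
        targets = ts.predict_targets(
            [ts.SeedWindow(w.trf_id, w.offset, w.kmer)], utr_blocks, rule
        )
        assert set(w.genes) <= set(targets.genes)
        assert {r.gene_name for r in targets.sites} >= set(w.genes)

    def test_union_of_two_windows_deduplicates(self, utr_data, rule, utr_blocks):
        _, truth = utr_data
        w1, w2 = truth.windows[:2]
        union = ts.predict_targets(
            [
                ts.SeedWindow("x", w1.offset, w1.kmer),
                ts.SeedWindow("x", w2.offset, w2.kmer),
            ],
            utr_blocks,
            rule,
        )
        assert len(union.genes) == len(set(union.genes))
        assert set(w1.genes) | set(w2.genes) <= set(union.genes)

    def test_genes_hit_by_multiple_trfs_identifiable(self, utr_data, rule, utr_blocks):
        _, truth = utr_data
        sets = []
        for w in truth.windows:
            t = ts.predict_targets(
                [ts.SeedWindow(w.trf_id, w.offset, w.kmer)], utr_blocks, rule,
            )
            sets.append(t.genes)
        multi = set.intersection(*(set(s) for s in sets))
        # planted gene groups are disjoint, so shared hits are chance-level
        assert isinstance(multi, set)
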