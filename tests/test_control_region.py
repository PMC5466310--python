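import itertools

import numpy as np
import pytest

from mitochar import control_region as cr
from mitochar import genome_model as gm


def brute_repeats(s: str, unit_sizes, min_copies: float):
    """Exhaustive oracle: every maximal periodic stretch with a primitive
    unit and enough copies, enumerated from the definition."""
    n = len(s)
    hits = set()
    for k in unit_sizes:
        for start in range(n):
            for end in range(start + k + 1, n + 1):  # stretch s[start:end]
                length = end - start
                if any(s[i] != s[i + k] for i in range(start, end - k)):
                    continue
                # maximality
                if start > 0 and s[start - 1] == s[start - 1 + k]:
                    continue
                if end < n and s[end - k] == s[end]:
                    continue
                unit = s[start : start + k]
                if not cr._is_primitive(unit):
                    continue
                copies = length / k
                if copies < min_copies:
                    continue
                hits.add((cr._canonical_rotation(unit), copies, start + 1, end))
    return hits


def as_set(hits):
    return {(h.unit, h.copies, h.start, h.end) for h in hits}


class TestFindMotif:
    def test_by_inspection(self):
        hits = cr.find_motif("GGATAGATTT", "ATAGA")
        assert len(hits) == 1 and (hits[0].start, hits[0].end) == (3, 7)

    def test_absent(self):
        assert cr.find_motif("GGGGGG", "ATAGA") == []

    def test_overlapping_occurrences(self):
        hits = cr.find_motif("ATATATA", "ATA")
        assert [(h.start, h.end) for h in hits] == [(1, 3), (3, 5), (5, 7)]

    def test_reverse_strand_mapping(self):
        region = "CCCTCTATCCC"  # contains revcomp(ATAGA) = TCTAT
        hits = cr.find_motif(region, "ATAGA", both_strands=True)
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "R"
        assert gm.reverse_complement(region[h.start - 1 : h.end]) == "ATAGA"

    def test_ambiguous_motif_rejected(self):
        with pytest.raises(ValueError):
            cr.find_motif("ACGT", "ATN")

    def test_hits_reslice_to_motif(self, syn_genome, syn_truth):
        entry = next(t for t in syn_truth if t["kind"] == "cr_motif")
        rec = syn_genome.record("AT_rich_region")
        region = syn_genome.sequence[rec.start - 1 : rec.end]
        local = entry["start"] - rec.start + 1
        hits = cr.find_motif(region, "ATAGA", both_strands=True)
        assert [(h.start, h.strand) for h in hits] == [(local, "F")]


class TestMotifPolyT:
    def test_planted_composite(self):
        region = "GGCC" + "ATAGA" + "T" * 17 + "GACG"
        hit = cr.find_motif_poly_t(region, threshold=10)
        assert hit is not None and hit.poly_t_len == 17
        assert (hit.motif_hit.start, hit.motif_hit.end) == (5, 9)
        assert (hit.poly_t.start, hit.poly_t.end) == (10, 26)

    def test_short_run_below_threshold(self):
        region = "CCATAGATTTCC"
        assert cr.find_motif_poly_t(region, threshold=10) is None

    def test_threshold_zero_degenerates_to_find_motif(self):
        region = "CCATAGACCGG"
        hit = cr.find_motif_poly_t(region, threshold=0, both_strands=False)
        first = cr.find_motif(region, "ATAGA")[0]
        assert (hit.motif_hit.start, hit.motif_hit.end) == (first.start, first.end)

    def test_offset_tolerated(self):
        region = "ATAGA" + "CA" + "T" * 12
        hit = cr.find_motif_poly_t(region, threshold=10, max_offset=2)
        assert hit is not None and hit.poly_t_len == 12

    def test_recovers_generator_placement(self, syn_genome, syn_truth):
        rec = syn_genome.record("AT_rich_region")
        region = syn_genome.sequence[rec.start - 1 : rec.end]
        hit = cr.find_motif_poly_t(region)
        truth_m = next(t for t in syn_truth if t["kind"] == "cr_motif")
        truth_t = next(t for t in syn_truth if t["kind"] == "poly_t")
        assert hit.motif_hit.start == truth_m["start"] - rec.start + 1
        assert hit.poly_t_len == truth_t["copies"] == 17
        assert hit.poly_t.start == truth_t["start"] - rec.start + 1


class TestLongestHomopolymer:
    def test_by_inspection(self):
        hit = cr.longest_homopolymer("TTTATTTT", "T")
        assert (hit.copies, hit.start, hit.end) == (4.0, 5, 8)

    def test_all_same(self):
        hit = cr.longest_homopolymer("A" * 12, "A")
        assert hit.copies == 12.0 and (hit.start, hit.end) == (1, 12)

    def test_absent_base(self):
        assert cr.longest_homopolymer("CCCC", "A") is None

    def test_ties_first_occurrence(self):
        hit = cr.longest_homopolymer("AATAA", "A")
        assert (hit.start, hit.end) == (1, 2)

    def test_agreement_with_runlength_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 40))))
            for base in "ACGT":
                hit = cr.longest_homopolymer(s, base)
                # oracle: longest run by explicit enumeration
                best, best_i = 0, -1
                for i in range(len(s)):
                    j = i
                    while j < len(s) and s[j] == base:
                        j += 1
                    if j - i > best:
                        best, best_i = j - i, i
                if best == 0:
                    assert hit is None
                else:
                    assert (hit.copies, hit.start) == (float(best), best_i + 1)


class TestMicrosatellites:
    def test_at9(self):
        hits = cr.find_microsatellites("ATATATATATATATATAT", (2,), min_copies=3)
        assert as_set(hits) == {("AT", 9.0, 1, 18)}

    def test_partial_copies_below_threshold(self):
        assert cr.find_microsatellites("ATATA", (2,), min_copies=3) == []

    def test_homopolymer_only_under_unit_one(self):
        hits = cr.find_microsatellites("AAAAAA", (1, 2, 3), min_copies=3)
        assert as_set(hits) == {("A", 6.0, 1, 6)}

    def test_exhaustive_oracle_AT_alphabet(self):
        sizes = (1, 2, 3)
        for n in range(1, 11):
            for tup in itertools.product("AT", repeat=n):
                s = "".join(tup)
                assert as_set(cr.find_microsatellites(s, sizes, 3)) == brute_repeats(s, sizes, 3), s

    def test_random_acgt_against_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            s = "".join(rng.choice(list("ACGT"), size=12))
            assert as_set(cr.find_microsatellites(s, (1, 2, 3, 4), 3)) == brute_repeats(
                s, (1, 2, 3, 4), 3
            ), s

    def test_reverse_complement_mirrors_coordinates(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            s = "".join(rng.choice(list("ACGT"), size=30))
            fwd = cr.find_microsatellites(s, (1, 2, 3), 3)
            rev = cr.find_microsatellites(gm.reverse_complement(s), (1, 2, 3), 3)
            mirrored = {
                (cr._canonical_rotation(gm.reverse_complement(h.unit)), h.copies,
                 len(s) - h.end + 1, len(s) - h.start + 1)
                for h in rev
            }
            assert as_set(fwd) == mirrored

    def test_planted_at9_recovered(self, syn_genome, syn_truth):
        truth = next(t for t in syn_truth if t["kind"] == "microsatellite")
        rec = syn_genome.record("AT_rich_region")
        region = syn_genome.sequence[rec.start - 1 : rec.end]
        hits = cr.find_microsatellites(region, (2,), min_copies=9)
        local = (truth["start"] - rec.start + 1, truth["end"] - rec.start + 1)
        assert (hits[0].unit, hits[0].copies, hits[0].start, hits[0].end) == (
            "AT", 9.0, local[0], local[1],
        )


class TestTandemRepeats:
    def test_acg_times_three(self):
        hits = cr.find_tandem_repeats("ACGACGACG", 2, 5, 3)
        assert len(hits) == 1
        assert (hits[0].unit, hits[0].copies) == ("ACG", 3.0)

    def test_five_mer_times_four_spans_region(self):
        s = "ACGTC" * 4
        hits = cr.find_tandem_repeats(s, 2, 6, 3)
        assert any(h.unit == cr._canonical_rotation("ACGTC") and h.copies == 4.0 for h in hits)

    def test_max_unit_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            cr.find_tandem_repeats("ACGT", 2, 10, 3)

    def test_shuffled_region_matches_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            s = "".join(rng.choice(list("ACGT"), size=12))
            got = as_set(cr.find_tandem_repeats(s, 2, 4, 3))
            oracle = brute_repeats(s, (2, 3, 4), 3)
            # the scanner suppresses hits nested inside a longer-unit hit
            expected = {
                h for h in oracle
                if not any(
                    o != h and len(o[0]) > len(h[0]) and o[2] <= h[2] and h[3] <= o[3]
                    for o in oracle
                )
            }
            assert got == expected, s

    def test_hits_reslice_to_unit(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            s = "".join(rng.choice(list("ACGT"), size=25))
            for h in cr.find_tandem_repeats(s, 2, 5, 3):
                sliced = s[h.start - 1 : h.end]
                full = int(h.copies)
                # some rotation of the canonical unit tiles the slice
                assert any(
                    sliced.startswith((h.unit[i:] + h.unit[:i]) * full)
                    for i in range(len(h.unit))
                )


class TestSpacerMotifReport:
    def test_planted_spacer_motif_found(self, syn_genome, syn_truth):
        frame = cr.spacer_motif_report(syn_genome)
        truth = next(t for t in syn_truth if t["kind"] == "spacer_motif")
        rows = frame[(frame.Motif == "ATACTAA") & (frame.Kind == "motif")]
        assert len(rows) >= 1
        row = rows.iloc[0]
        assert row.Region == "spacer:trnS2(UCN)-nad1"
        assert (row.Start, row.End) == (truth["start"], truth["end"])

    def test_empty_motif_list(self, syn_genome):
        frame = cr.spacer_motif_report(syn_genome, motifs=())
        assert (frame.Kind == "motif").sum() <= len(
            frame[frame.Region.str.startswith("control_region")]
        )
        assert not any(frame.Region.str.startswith("spacer"))

    def test_table_only_mode_rejected(self, ref_genome):
        with pytest.raises(gm.SequenceUnavailableError):
            cr.spacer_motif_report(ref_genome)

    def test_control_region_elements_present(self, syn_genome):
        frame = cr.spacer_motif_report(syn_genome)
        cr_rows = frame[frame.Region.str.startswith("control_region")]
        kinds = set(cr_rows.Kind)
        assert {"motif", "homopolymer", "microsatellite"} <= kinds
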