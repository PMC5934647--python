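"""Site scanning, +1 preference, match length, competition model."""

import io
import random

import pytest

from is608design import target_scan as ts
from is608design.transposon_model import (
    Oligo,
    OligoPool,
    ParameterError,
    ParseError,
    revcomp,
)

from oracle import naive_find_sites


class TestScan:
    def test_no_occurrence_gives_empty_list(self):
        assert ts.scan({"s": "AGGAGGAGG"}) == []

    def test_planted_sites_on_top_strand(self):
        rng = random.Random(11)
        filler = "".join(rng.choice("AG") for _ in range(1000))  # TTAC-free
        seq = list(filler)
        inserts = [(100, "TTACC"), (400, "TTACC"), (700, "TTACC"),
                   (250, "TTACG"), (850, "TTACG")]
        for pos, motif in inserts:
            seq[pos : pos + 5] = motif
        seq = "".join(seq)
        sites = ts.scan({"chr": seq})
        assert len(sites) == 5
        assert [s.ct_start for s in sites] == sorted(p for p, _m in inserts)
        assert {s.plus1 for s in sites} == {"C", "G"}

    def test_agrees_with_naive_search_both_strands(self):
        rng = random.Random(5)
        for _ in range(200):
            n = rng.randint(10, 120)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            got_plus = [
                s.ct_start for s in ts.scan({"s": seq}, both_strands=False)
            ]
            expected = [i for i in naive_find_sites(seq, "TTAC") if i + 4 < n]
            assert got_plus == expected
            got_minus = sorted(
                s.ct_start
                for s in ts.scan({"s": seq}, both_strands=True)
                if s.strand == "-"
            )
            rc = revcomp(seq)
            expected_minus = sorted(
                n - q - 4
                for q in naive_find_sites(rc, "TTAC")
                if q + 4 < n
            )
            assert got_minus == expected_minus

    def test_upstream_context_and_plus1(self):
        seq = "AAGGCCGGTTACC" + "AGG"
        (site,) = ts.scan({"s": seq})
        assert site.ct_start == 8
        assert site.plus1 == "C"
        assert site.upstream == "AAGGCCGG"

    def test_rejects_bad_core_site(self):
        with pytest.raises(ParameterError):
            ts.scan({"s": "ATTACC"}, ct="TTA")


class TestPlus1Weight:
    def test_cytosine_is_best_purines_equal_worst(self):
        assert ts.plus1_weight("C") == 1.0
        assert ts.plus1_weight("A") == ts.plus1_weight("G")
        assert ts.plus1_weight("A") < ts.plus1_weight("T")
        for b in "ACGT":
            assert 0 < ts.plus1_weight(b) <= 1

    def test_invalid_base_rejected(self):
        with pytest.raises(ParseError):
            ts.plus1_weight("N")


class TestCoopCalibration:
    def test_shipped_defaults_satisfy_constraints(self):
        c = ts.CoopParams()
        assert c(8) / c(0) >= 40
        assert c(5) / c(0) <= 3

    def test_monotone_nondecreasing(self):
        c = ts.CoopParams()
        values = [c(m) for m in range(0, 14)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_violating_params_rejected_at_load(self):
        with pytest.raises(ts.CalibrationError):
            ts.CoopParams(h=1.0)  # too shallow: 5 matches would win too much
        with pytest.raises(ts.CalibrationError):
            ts.CoopParams(amp=5.0)  # too weak: 8 matches could not dominate


class TestMatchLen:
    def test_intended_site_matches_full_extension(self, design8):
        assert ts.match_len(design8.site, design8) == design8.ext_len == 8

    def test_random_competitor_below_cap(self, design8, pool8):
        tr = next(m for m in pool8 if m.id == "Tr")
        site = ts.site_from_oligo(tr, design8.site.ct_seq)
        assert 0 <= ts.match_len(site, design8) <= 4

    def test_five_match_site_counts_five(self, design8):
        ext = design8.extension
        # complementary window broken at the 6th extension position: the
        # longest register-correct run is then exactly 5
        rc = list(ext)
        rc[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[rc[5]]
        window5 = revcomp("".join(rc))
        upstream = "AGGAGGAGGAGG" + window5 + "GCA"
        site = ts.TargetSite(
            source_id="t5", ct_start=len(upstream), strand="+",
            ct_seq=design8.site.ct_seq, plus1="C", upstream=upstream,
        )
        assert ts.match_len(site, design8) == 5

    def test_insufficient_upstream_context_raises(self, design8):
        site = ts.TargetSite(
            source_id="short", ct_start=4, strand="+",
            ct_seq=design8.site.ct_seq, plus1="C", upstream="ACGT",
        )
        with pytest.raises(ParameterError):
            ts.match_len(site, design8)


class TestCompetition:
    def test_single_member_pool_gets_everything(self, design8, pool8):
        tic = next(m for m in pool8 if m.id == "Tic")
        scores = ts.competition(OligoPool(members=(tic,)), design8)
        assert scores[0].fraction == pytest.approx(1.0)

    def test_equimolar_complementary_vs_random(self, design8, pool8):
        by_id = {m.id: m for m in pool8}
        pool = OligoPool(members=(by_id["Tic"], by_id["Tr"]))
        scores = {s.site.source_id: s for s in ts.competition(pool, design8)}
        assert scores["Tic"].fraction >= 0.95
        assert scores["Tic"].match_len == 8

    def test_majority_at_twentyfold_excess(self, design8, pool8):
        by_id = {m.id: m for m in pool8}
        members = (Oligo(by_id["Tic"].seq, "Tic", 1.0),) + tuple(
            Oligo(by_id[f"Ts{i}"].seq, f"Ts{i}", 5.0) for i in range(1, 5)
        )
        scores = ts.competition(OligoPool(members=members), design8)
        tic = next(s for s in scores if s.site.source_id == "Tic")
        assert tic.fraction > 0.5

    def test_fractions_sum_to_one_and_scale_invariant(self, design8, pool8):
        scores = ts.competition(pool8, design8)
        assert sum(s.fraction for s in scores) == pytest.approx(1.0, abs=1e-9)
        scaled = OligoPool(
            members=tuple(Oligo(m.seq, m.id, m.rel_conc * 7.5) for m in pool8)
        )
        rescored = ts.competition(scaled, design8)
        for a, b in zip(scores, rescored):
            assert a.fraction == pytest.approx(b.fraction)

    def test_weight_decomposition(self, design8, pool8):
        for s in ts.competition(pool8, design8):
            assert s.weight == pytest.approx(
                s.plus1_weight * ts.coop(s.match_len)
            )

    def test_ambiguous_member_rejected(self, design8):
        bad = Oligo("AGG" + "TTAC" + "C" + "TTAC" + "CAGG", "dup")
        with pytest.raises(ParameterError):
            ts.competition(OligoPool(members=(bad,)), design8)


class TestReports:
    def test_bed_output_format(self, design8, pool8):
        scores = ts.competition(pool8, design8)
        buf = io.StringIO()
        ts.sites_to_bed(scores, buf)
        lines = buf.getvalue().strip().split("\n")
        assert len(lines) == len(pool8)
        first = lines[0].split("\t")
        assert len(first) == 6
        assert int(first[2]) - int(first[1]) == 4
        assert 0 <= int(first[4]) <= 1000

    def test_offtarget_table_bins_by_match_len(self, design8, locus_and_site):
        locus, _ = locus_and_site
        table = ts.offtarget_table({"locus": locus}, design8)
        assert set(table.columns) >= {"match_len", "plus1", "high_risk"}
        assert table.high_risk.sum() == 1  # only the intended site
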