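"""Design construction, structural unlocking, C_T resetting, validation."""

import warnings
from dataclasses import replace

import pytest

from is608design import target_scan as ts
from is608design.retarget_design import (
    DesignWarning,
    GlCtMap,
    apply_structural_unlocking,
    design_extension,
    reset_ct,
    validate_design,
    with_extension,
)
from is608design.ssfold import accessibility, fold
from is608design.transposon_model import ParameterError, revcomp


def _locus_with_window(window, linker="GCA", ct="TTAC"):
    """Locus whose design window (-15..-8 for defaults) is ``window``."""
    pad = "AGCAGGACGGAGCAGGACGG"  # TTAC-free filler
    locus = pad + window + linker + ct + "C" + "AGGAGGAGGAGGAGG"
    (site,) = ts.scan({"locus": locus})
    return locus, site


class TestDesignExtension:
    def test_extension_is_reverse_complement_of_window(self):
        locus, site = _locus_with_window("ACGTTGCA")
        d = design_extension(locus, site, 8, 3)
        assert d.extension == "TGCAACGT"
        assert d.target_window == "ACGTTGCA"

    def test_homopolymer_window(self):
        locus, site = _locus_with_window("AAAAAAAA")
        d = design_extension(locus, site, 8, 3)
        assert d.extension == "TTTTTTTT"

    def test_recognized_site_lengths(self, locus_and_site):
        locus, site = locus_and_site
        assert design_extension(locus, site, 8, 3).recognized_site_len == 12
        assert design_extension(locus, site, 13, 3).recognized_site_len == 17

    def test_register_anchors_and_antiparallel_order(self, design8):
        reg = design8.register
        assert reg.kind_at(16, -3) == "WC"
        assert reg.kind_at(17, -4) == "WC"
        assert reg.kind_at(42, -4) == "triplet"
        assert reg.kind_at(43, -3) == "triplet"
        # +44 pairs -(linker+5) = -8 and proceeds antiparallel
        assert reg.kind_at(44, -8) == "WC"
        assert reg.kind_at(51, -15) == "WC"

    def test_extension_feature_starts_at_plus44(self, design8):
        assert design8.junction.le_interval(44, 51) == \
            design8.junction.features["EXT"]

    def test_short_extension_warns_long_rejected(self, locus_and_site):
        locus, site = locus_and_site
        with pytest.warns(DesignWarning):
            design_extension(locus, site, 5, 3)
        with pytest.raises(ParameterError):
            design_extension(locus, site, 14, 3)
        with pytest.raises(ParameterError):
            design_extension(locus, site, 4, 3)

    def test_nondefault_linker_warns(self, locus_and_site):
        locus, site = locus_and_site
        with pytest.warns(DesignWarning):
            design_extension(locus, site, 8, 4)
        with pytest.raises(ParameterError):
            design_extension(locus, site, 8, 6)

    def test_site_too_close_to_five_prime_end(self):
        locus = "AG" + "TTAC" + "C" + "AGGAGGAGG"
        (site,) = ts.scan({"locus": locus})
        with pytest.raises(ParameterError):
            design_extension(locus, site, 8, 3)


class TestStructuralUnlocking:
    def test_accessible_design_gets_only_plus42_edit(self, design8):
        chk = design8.validation["checks"]["unlocking"]
        assert chk["pass"]
        assert chk["edits"] == [(42, "T")]
        assert design8.junction.le_base(42) == "T"
        assert design8.junction.le_base(43) == "T"

    def test_occluded_design_is_opened_within_mutable_window(self, hairpin_design):
        before = accessibility(
            fold(hairpin_design.junction.seq),
            hairpin_design.junction.features["EXT"],
        )
        assert before < 0.9
        unlocked = apply_structural_unlocking(hairpin_design)
        chk = unlocked.validation["checks"]["unlocking"]
        assert chk["pass"] and chk["accessibility"] >= 0.9
        edited = {pos for pos, _b in chk["edits"]}
        assert edited <= {42} | set(range(55, 61))
        assert any(55 <= pos <= 60 for pos in edited)

    def test_unlocking_never_touches_guide_palindrome_or_extension(
        self, hairpin_design
    ):
        unlocked = apply_structural_unlocking(hairpin_design)
        j0, j1 = hairpin_design.junction, unlocked.junction
        diffs = {
            pos
            for pos in range(1, len(j0.seq) - j0.le_offset + 1)
            if j0.le_base(pos) != j1.le_base(pos)
        }
        assert diffs <= {42} | set(range(55, 61))
        assert j1.feature_seq("EXT") == j0.feature_seq("EXT")
        assert j1.feature_seq("GL") == j0.feature_seq("GL")
        assert j1.feature_seq("IPL") == j0.feature_seq("IPL")

    def test_idempotent(self, hairpin_design):
        once = apply_structural_unlocking(hairpin_design)
        twice = apply_structural_unlocking(once)
        assert twice.junction.seq == once.junction.seq
        assert twice.validation["checks"]["unlocking"]["edits"] == []

    def test_unreachable_threshold_returns_failed_design(self, hairpin_design):
        # zero mutation budget on an occluded design: best effort, marked fail
        res = apply_structural_unlocking(hairpin_design, max_mut=0)
        chk = res.validation["checks"]["unlocking"]
        assert not chk["pass"]
        assert chk["accessibility"] < 0.9


class TestResetCt:
    def test_identity_reset_makes_no_edit(self, design8):
        d = reset_ct(design8, design8.site.ct_seq)
        assert d.junction.seq == design8.junction.seq

    def test_single_position_reset_edits_plus17(self, design8):
        new_ct = "GTAC"  # change at -4 only (T->G)
        d = reset_ct(design8, new_ct)
        assert d.site.ct_seq == new_ct
        assert d.junction.le_base(17) == "C"  # WC complement of G
        diffs = [
            p for p in range(1, 71)
            if d.junction.le_base(p) != design8.junction.le_base(p)
        ]
        assert diffs == [17]

    def test_double_reset_edits_restore_complementarity(self, design8):
        new_ct = "GAAC"  # changes at -4 (T->G) and -3 (T->A)
        d = reset_ct(design8, new_ct)
        diffs = sorted(
            p for p in range(1, 71)
            if d.junction.le_base(p) != design8.junction.le_base(p)
        )
        assert diffs == [16, 17]
        wc = {"A": "T", "T": "A", "G": "C", "C": "G"}
        assert d.junction.le_base(17) == wc[new_ct[0]]
        assert d.junction.le_base(16) == wc[new_ct[1]]
        assert d.register.kind_at(16, -3) == "WC"

    def test_unmapped_position_rejected_with_names(self, design8):
        with pytest.raises(ParameterError, match="-2"):
            reset_ct(design8, "TTGC")  # change at -2

    def test_custom_map_extends_resettable_positions(self, design8):
        gl_map = GlCtMap(entries={-4: 17, -3: 16, -2: 18})
        d = reset_ct(design8, "TTGC", gl_map)
        assert d.junction.le_base(18) == "C"

    def test_reset_commutes_with_extension_redesign(self, design8):
        a = with_extension(reset_ct(design8, "GTAC"), ext_len=8)
        b = reset_ct(with_extension(design8, ext_len=8), "GTAC")
        assert a.junction.seq == b.junction.seq
        assert a.site.ct_seq == b.site.ct_seq


class TestValidateDesign:
    def test_unlocked_default_design_passes_end_to_end(self, design8):
        assert design8.validation["overall_pass"]
        for name in (
            "accessibility",
            "self_complementarity",
            "unintended_ct",
            "register",
            "triplet_bases",
        ):
            assert design8.validation["checks"][name]["pass"], name

    def test_register_pairs_are_perfectly_complementary(self, design8):
        chk = design8.validation["checks"]["register"]
        assert chk["pass"] and chk["mismatches"] == []

    def test_planted_self_complementarity_fails(self, design8):
        j = design8.junction
        bait = revcomp(design8.extension[:6])
        seq = bait + j.seq[6:]  # overwrite 5' RE filler with the bait
        tampered = replace(design8, junction=replace(j, seq=seq))
        res = validate_design(tampered)
        assert not res.validation["checks"]["self_complementarity"]["pass"]

    def test_planted_ct_in_extension_fails(self, design8):
        j = design8.junction
        for offset, base in enumerate("TTAC"):
            j = j.with_le_base(44 + offset, base)
        tampered = replace(design8, junction=j)
        res = validate_design(tampered)
        assert not res.validation["checks"]["unintended_ct"]["pass"]

    def test_genome_scan_flags_only_intended_site(self, design8, locus_and_site):
        locus, _site = locus_and_site
        chk = design8.validation["checks"]["offtarget"]
        assert chk["pass"]
        assert chk["n_high_risk"] == 1  # the intended site itself
        assert chk["n_high_risk_offtarget"] == 0
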