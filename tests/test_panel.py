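"""Panel selection filters and duplex-MIP precursor assembly/digestion."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strlineage.dna import find_motif, revcomp
from strlineage.panel import (
    BACKBONE,
    MLY1_F,
    MLY1_R,
    ArmCriteria,
    PanelDesignError,
    StrLocus,
    assemble_precursor,
    check_amplicon,
    design_arms,
    digest_precursor,
    is_hypermutable,
    select_hypermutable_loci,
)


def locus(unit: str, count: int, lid: str = "L1") -> StrLocus:
    return StrLocus(
        locus_id=lid,
        chrom="chrX",
        start=1000,
        end=1000 + len(unit) * count,
        unit=unit,
        ref_repeat_count=count,
    )


class TestHypermutableSelection:
    @pytest.mark.parametrize(
        "unit,count,kept",
        [
            ("AC", 12, True),    # di-repeat above the strict >10 threshold
            ("AC", 11, True),
            ("AC", 10, False),   # boundary: "longer than 10" is strict
            ("AG", 11, True),
            ("AG", 10, False),
            ("A", 7, True),      # mono-repeat above the strict >6 threshold
            ("A", 6, False),
            ("G", 7, True),
            ("GT", 12, True),    # reverse complement of AC, unified
            ("CT", 12, True),    # reverse complement of AG
            ("T", 8, True),      # reverse complement of A
            ("C", 8, True),      # reverse complement of G
            ("AT", 30, False),   # unit type outside the selection rules
            ("CAG", 30, False),
        ],
    )
    def test_selection_rule(self, unit, count, kept):
        assert is_hypermutable(locus(unit, count)) is kept

    def test_revcomp_unification_can_be_disabled(self):
        assert is_hypermutable(locus("GT", 12), unify_revcomp=False) is False

    def test_filter_is_idempotent(self):
        loci = [locus("AC", c, f"L{c}") for c in range(8, 16)] + [
            locus("A", c, f"M{c}") for c in range(4, 10)
        ]
        once = select_hypermutable_loci(loci)
        assert select_hypermutable_loci(once) == once
        assert {l.locus_id for l in once} == {
            "L11", "L12", "L13", "L14", "L15", "M7", "M8", "M9"
        }

    def test_malformed_unit_reported_with_locus_id(self):
        with pytest.raises(PanelDesignError, match="BAD1"):
            StrLocus("BAD1", "chrX", 0, 4, "AX", 2)

    def test_non_primitive_unit_rejected(self):
        with pytest.raises(PanelDesignError, match="not primitive"):
            StrLocus("L9", "chrX", 0, 8, "ACAC", 2)


class TestAmpliconCheck:
    def test_good_150bp(self):
        seq = "ACGG" * 37 + "AC"  # 150 nt, no TTAA
        assert "TTAA" not in seq
        assert check_amplicon(seq).ok

    def test_ttaa_ruled_out(self):
        seq = "ACGG" * 30 + "TTAA" + "ACGG" * 6 + "AC"
        result = check_amplicon(seq)
        assert not result.ok and "TTAA" in result.reasons

    def test_length_window(self):
        assert check_amplicon("ACGG" * 20).reasons == ("length",)  # 80 nt
        assert check_amplicon("ACGG" * 30).ok                       # 120 nt, tol 30
        assert not check_amplicon("ACGG" * 30, tol=10).ok

    def test_non_dna_raises(self):
        with pytest.raises(PanelDesignError):
            check_amplicon("ACGTX" * 30)


FW = "ACGTACGTACGTACGTACGT"       # 20 nt, MlyI-free
RV = "TGACTGCATCAGGCATTGCA"       # 20 nt, MlyI-free


class TestPrecursorAssembly:
    def test_element_order_and_constants(self):
        p = assemble_precursor("L1", FW, RV)
        expected = (
            MLY1_F + FW + "NNN" + BACKBONE + "NNN" + revcomp(RV) + revcomp(MLY1_R)
        )
        assert p.full_sequence == expected

    def test_fixed_overhead_allows_44nt_of_arms(self):
        # constants: 23 + 23 + 54 + 2*3 = 106, so 20+20 arms give 146 <= 150
        p = assemble_precursor("L1", FW, RV)
        assert len(p.full_sequence) == 106 + len(FW) + len(RV) == 146

    def test_overlong_precursor_rejected(self):
        with pytest.raises(PanelDesignError, match="exceeds"):
            assemble_precursor("L1", FW + "ACGTA", RV + "ACGTA")  # 156 nt

    @pytest.mark.parametrize("bad", ["GAGTC", "GACTC"])
    def test_mlyi_site_in_arm_rejected(self, bad):
        with pytest.raises(PanelDesignError, match="MlyI"):
            assemble_precursor("L1", "ACGTACG" + bad + "ACGTACGT", RV)

    def test_randomized_umi_bases_do_not_count_as_sites(self):
        # the MlyI scan is on the designed sequence: N never completes a site
        p = assemble_precursor("L1", "ACGTACGTACGTACGTGAGT", RV)
        assert digest_precursor(p).startswith("ACGTACGTACGTACGTGAGT")


class TestDigestion:
    def test_150nt_precursor_yields_about_105(self):
        fw = FW + "AC"
        rv = RV + "GA"
        p = assemble_precursor("L1", fw, rv)  # 150 nt
        assert len(p.full_sequence) == 150
        assert abs(len(digest_precursor(p)) - 105) <= 3

    def test_adapters_removed_arms_and_backbone_intact(self):
        p = assemble_precursor("L1", FW, RV)
        active = digest_precursor(p)
        assert active == FW + "NNN" + BACKBONE + "NNN" + revcomp(RV)
        assert MLY1_F not in active and revcomp(MLY1_R) not in active

    def test_cut_positions_match_manual_site_scan(self):
        # manual GAGTC(N5) arithmetic on the printed adapters
        p = assemble_precursor("L1", FW, RV)
        full = p.full_sequence
        site = full.index("GAGTC")
        left_cut = site + 5 + 5
        assert left_cut == len(MLY1_F) == 23
        rc_site = full.rindex("GACTC")
        right_cut = rc_site - 5
        assert right_cut == len(full) - len(MLY1_R)
        assert digest_precursor(p) == full[left_cut:right_cut]

    def test_missing_adapter_errors(self):
        p = assemble_precursor("L1", FW, RV)
        broken = type(p)(
            locus_id=p.locus_id,
            fw_arm=p.fw_arm,
            rv_arm=p.rv_arm,
            full_sequence=p.full_sequence[1:],
            active_sequence=p.active_sequence,
        )
        with pytest.raises(PanelDesignError):
            digest_precursor(broken)


arm_strategy = st.text(alphabet="ACGT", min_size=18, max_size=22)


@settings(max_examples=60, deadline=None)
@given(fw=arm_strategy, rv=arm_strategy)
def test_digest_assemble_roundtrip_property(fw, rv):
    """digest(assemble(arms)) preserves arms and backbone for any valid arms."""
    try:
        p = assemble_precursor("L", fw, rv)
    except PanelDesignError:
        return  # arm carried or created an MlyI site / exceeded length
    active = digest_precursor(p)
    assert active == fw + "NNN" + BACKBONE + "NNN" + revcomp(rv)
    assert len(p.full_sequence) <= 150
    total_sites = len(find_motif(p.full_sequence, "GAGTC")) + len(
        find_motif(p.full_sequence, "GACTC")
    )
    assert total_sites == 2


def test_design_arms_heuristic_respects_criteria():
    left = "GGATCCATTGCACGTACGTACGTAGGCT"
    right = "CAGTTGCACCGATATCGGTACGATCCGA"
    loc = StrLocus("L1", "chrX", 0, 26, "AC", 13, left, right)
    arms = design_arms(loc)
    assert arms is not None
    fw, rv, amplicon = arms
    crit = ArmCriteria()
    assert crit.accepts(fw) and crit.accepts(rv)
    assert fw in left and rv in right
    # the amplicon spans from the forward arm across the repeat to the
    # reverse arm, and cannot exceed flanks + repeat
    assert fw in amplicon and rv in amplicon and loc.repeat_sequence in amplicon
    assert len(amplicon) <= len(left) + 26 + len(right)


def test_design_arms_targets_amplicon_length():
    rng_flank_l = "GGATCCATTGCACGTACGTACGTAGGCTCAGTTGCACCGATATCGGTACGATCCGAGGATCCATTGCACG"
    rng_flank_r = "CAGTTGCACCGATATCGGTACGATCCGAGGATCCATTGCACGTACGTACGTAGGCTCAGTTGCACCGATA"
    loc = StrLocus("L2", "chrX", 0, 26, "AC", 13, rng_flank_l, rng_flank_r)
    arms = design_arms(loc, amplicon_target=150)
    assert arms is not None
    assert abs(len(arms[2]) - 150) <= 5


def test_design_arms_returns_none_for_hopeless_flanks():
    loc = StrLocus("L1", "chrX", 0, 26, "AC", 13, "A" * 30, "T" * 30)
    assert design_arms(loc) is None
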