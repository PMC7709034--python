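"""Threshold-based calling, suspect deletions, NUMT demotion, and export."""

import numpy as np
import pytest

import mitoval as mv
from mitoval.calling import (
    DEFAULT_SUSPECT_DELETIONS,
    Thresholds,
    apply_suspect_deletions,
    call_position,
    flag_nav,
)
from mitoval.pileup import PositionCounts
from mitoval.simulate import DepthModel, SimScenario, simulate_pileup

from conftest import flat_pileup, transition, variant_positions

TH = Thresholds()


def pc(position, counts, insertions=None):
    return PositionCounts(position, counts, insertions or {})


class TestThresholds:
    def test_defaults_match_study_parameters(self):
        assert (TH.php_min, TH.ins_min, TH.del_min) == (0.10, 0.30, 0.40)
        assert TH.min_depth == 20
        assert TH.strand_bias_review == 0.89
        assert TH.mv_min_count == 3

    @pytest.mark.parametrize(
        "kwargs", [{"php_min": 0.5, "ins_min": 0.3}, {"min_depth": 0}, {"php_min": 0}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Thresholds(**kwargs)


class TestCallPosition:
    def test_substitution_at_95_percent(self):
        calls = call_position(pc(100, {"A": (3, 2), "G": (48, 47)}), "A", TH)
        assert [c.rendered for c in calls] == ["100G"]
        assert calls[0].status == "confirmed"

    def test_heteroplasmy_at_12_percent(self):
        calls = call_position(pc(100, {"A": (44, 44), "G": (6, 6)}), "A", TH)
        assert [c.rendered for c in calls] == ["100R"]
        assert calls[0].frequency == pytest.approx(0.12)

    def test_below_min_depth_no_call(self):
        calls = call_position(pc(100, {"G": (10, 9)}), "A", TH)
        assert calls == []

    def test_deletion_at_45_percent(self):
        calls = call_position(pc(100, {"A": (28, 27), "del": (23, 22)}), "A", TH)
        assert [c.rendered for c in calls] == ["100del"]

    def test_extreme_strand_bias_flags_review_not_drop(self):
        # insertion at 73% of depth but nearly all on one strand
        x = pc(100, {"A": (50, 50)}, {"C": (71, 2)})
        calls = call_position(x, "A", TH)
        assert [c.rendered for c in calls] == ["100.1C"]
        assert calls[0].status == "review"
        assert calls[0].strand_bias > 0.89

    @pytest.mark.parametrize(
        "minor,expected_called",
        [(10, True), (9, False)],  # exactly 10% of 100 reads is inclusive
    )
    def test_php_threshold_inclusive(self, minor, expected_called):
        x = pc(50, {"A": (100 - minor, 0), "G": (minor, 0)})
        calls = call_position(x, "A", TH)
        assert bool(calls) is expected_called

    def test_deletion_threshold_inclusive_at_exactly_40(self):
        x = pc(50, {"A": (60, 0), "del": (40, 0)})
        assert [c.rendered for c in call_position(x, "A", TH)] == ["50del"]

    def test_insertion_threshold_inclusive_at_exactly_30(self):
        x = pc(50, {"A": (100, 0)}, {"C": (30, 0)})
        calls = call_position(x, "A", TH)
        assert [c.rendered for c in calls] == ["50.1C"]
        assert calls[0].dominant_fraction == 1.0

    def test_multi_allele_site_reports_top_two_with_note(self):
        x = pc(60, {"A": (50, 0), "G": (30, 0), "T": (20, 0)})
        calls = call_position(x, "A", TH)
        assert [c.rendered for c in calls] == ["60R"]
        assert "multi-allele" in calls[0].evidence

    def test_multibase_dominant_insertion_expands_indices(self):
        x = pc(80, {"A": (50, 50)}, {"CC": (30, 25), "C": (10, 5)})
        calls = call_position(x, "A", TH)
        assert [c.rendered for c in calls] == ["80.1C", "80.2C"]
        assert calls[0].dominant_fraction == pytest.approx(55 / 70)


class TestAssembleHaplotype:
    def test_reference_identity_pileup_has_no_calls(self, ref_small, panel_small):
        p = flat_pileup(ref_small, depth=100)
        h = mv.assemble_haplotype(p, ref_small, panel_small)
        assert h.calls == []
        assert h.coverage_mask == set()

    def test_recovers_30_simulated_substitutions_exactly(self, ref_full, panel_full):
        positions = variant_positions(ref_full, 30, start=211, step=503)
        hap = [f"{p}{transition(ref_full.base(p))}" for p in positions]
        sc = SimScenario(
            reference=ref_full, panel=panel_full, haplotypes=[hap],
            depth=DepthModel(median=100, amplicon_sigma=0), error=None,
            stochastic=False, seed=0,
        )
        pileup, _ = simulate_pileup(sc)
        h = mv.assemble_haplotype(pileup, ref_full, panel_full)
        assert h.rendered() == sorted(hap, key=lambda s: int(s[:-1]))

    def test_missing_amplicon_masks_its_span(self, ref_small, panel_small):
        victim = panel_small.amplicons[4]
        p = flat_pileup(ref_small, depth=100)
        only_victim = set(victim.positions(ref_small.length))
        for other in panel_small.amplicons:
            if other.id != victim.id:
                only_victim -= set(other.positions(ref_small.length))
        for pos in victim.positions(ref_small.length):
            del p.positions[pos]
        h = mv.assemble_haplotype(p, ref_small, panel_small)
        assert h.coverage_mask == set(victim.positions(ref_small.length))
        assert only_victim <= h.coverage_mask

    def test_empty_pileup_fully_masked(self, ref_small):
        h = mv.assemble_haplotype(mv.Pileup("empty"), ref_small)
        assert h.calls == []
        assert len(h.coverage_mask) == ref_small.length

    def test_monotonicity_in_php_min_and_min_depth(self, ref_small, panel_small):
        sc = SimScenario(
            reference=ref_small, panel=panel_small,
            haplotypes=[[f"150{transition(ref_small.base(150))}"]],
            variant_fractions={f"150{transition(ref_small.base(150))}": 0.15},
            depth=DepthModel(median=60), seed=21,
        )
        pileup, _ = simulate_pileup(sc)
        base = mv.assemble_haplotype(pileup, ref_small, panel_small, Thresholds())
        stricter = mv.assemble_haplotype(
            pileup, ref_small, panel_small, Thresholds(php_min=0.25)
        )
        het = lambda h: {c.rendered for c in h.calls if c.name.kind == "heteroplasmy"}
        assert het(stricter) <= het(base)
        deeper = mv.assemble_haplotype(
            pileup, ref_small, panel_small, Thresholds(min_depth=80)
        )
        assert base.coverage_mask <= deeper.coverage_mask


class TestSuspectDeletions:
    def _hap_with(self, *names):
        return mv.calling.haplotype_from_strings("s", list(names))

    def test_309del_suppressed_but_audited(self):
        h = apply_suspect_deletions(self._hap_with("263G", "309del"))
        assert "309del" not in h.rendered()
        audit = [c for c in h.calls if c.status == "suppressed_suspect"]
        assert [c.rendered for c in audit] == ["309del"]

    def test_defaults_cover_the_polyc_tract_ends(self):
        assert DEFAULT_SUSPECT_DELETIONS == {"309del", "315del", "16193del"}

    def test_non_suspect_haplotype_unchanged(self):
        h = self._hap_with("263G", "489del")
        assert apply_suspect_deletions(h).rendered() == ["263G", "489del"]

    def test_empty_suspect_list_is_identity(self):
        h = self._hap_with("309del")
        assert apply_suspect_deletions(h, set()).rendered() == ["309del"]


class TestFlagNav:
    def _pileup_at(self, pos, counts):
        return mv.Pileup("s", {pos: PositionCounts(pos, counts)})

    def test_heteroplasmy_with_catalog_minor_becomes_N(self, ref_full):
        # 31% T minor at 8943 with T catalogued as a nuclear-insert allele
        p = self._pileup_at(8943, {"C": (35, 34), "T": (16, 15)})
        h = mv.assemble_haplotype(p, ref_full)
        h.coverage_mask.clear()
        [call] = h.calls
        assert call.name.kind == "heteroplasmy"
        flagged = flag_nav(h, p, {8943: "T"})
        assert [c.rendered for c in flagged.calls] == ["8943N"]
        assert flagged.calls[0].status == "uncalled_N"
        assert "8943N" in flagged.rendered()  # N markers stay in the haplotype

    def test_no_catalog_hits_identity(self):
        p = self._pileup_at(100, {"C": (35, 34), "T": (16, 15)})
        h = mv.calling.haplotype_from_strings("s", ["100Y"])
        assert flag_nav(h, p, {}).rendered() == ["100Y"]

    def test_dominant_catalog_allele_is_a_true_variant(self, ref_small):
        # catalogued allele at 95%: substitution, not NUMT carry-in
        pos = 150
        alt = transition(ref_small.base(pos))
        p = self._pileup_at(pos, {alt: (48, 47), ref_small.base(pos): (3, 2)})
        h = mv.assemble_haplotype(p, ref_small)
        h.coverage_mask.clear()
        flagged = flag_nav(h, p, {pos: alt})
        assert flagged.rendered() == [f"{pos}{alt}"]


class TestExport:
    def test_zero_call_haplotype_exports_annotation_only(self, ref_small):
        h = mv.assemble_haplotype(mv.Pileup("s"), ref_small)
        text = mv.export_haplotype(h)
        assert text.startswith("# masked")
        assert f"1-{ref_small.length}" in text

    def test_common_hvii_motif_rendering(self):
        h = mv.calling.haplotype_from_strings("s", ["263G", "309.1C", "315.1C"])
        assert mv.export_haplotype(h) == "263G 309.1C 315.1C"

    def test_suppressed_calls_leave_the_export(self):
        h = apply_suspect_deletions(
            mv.calling.haplotype_from_strings("s", ["263G", "309del"])
        )
        assert mv.export_haplotype(h) == "263G"

    def test_vcf_is_parseable_and_faithful(self, tmp_path, ref_full):
        cyvcf2 = pytest.importorskip("cyvcf2")
        names = ["263G", "309.1C", "8943N", "1000del"]
        h = mv.calling.haplotype_from_strings("s", names)
        out = tmp_path / "h.vcf"
        mv.export_vcf(h, ref_full, out)
        records = list(cyvcf2.VCF(str(out)))
        assert len(records) == 4
        sub = next(r for r in records if r.ID == "263G")
        assert sub.POS == 263 and sub.ALT == ["G"]
        dele = next(r for r in records if r.ID == "1000del")
        assert dele.POS == 999 and len(dele.REF) == 2 and len(dele.ALT[0]) == 1
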