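"""Element classification: categories, Ty1/Ty2 assignment, hybrids."""

import pytest

from _oracles import random_dna
from tyscape.align import reverse_complement
from tyscape.classify import (
    assign_ty1_ty2,
    classify_ltr_context,
    classify_strain,
    detect_hybrid,
    summarize_coding,
)
from tyscape.genome import GenomeAssembly
from tyscape.scan import QueryPanel, scan_ltrs
from tyscape.synthetic import CategoryCounts, PlantSpec, make_hybrid, simulate_strain_panel


def _plant(rng, element_seq, margin=20_000, strand="+"):
    bg = random_dna(rng, 2 * margin)
    if strand == "-":
        element_seq = reverse_complement(element_seq)
    return GenomeAssembly("s", {"chr1": bg[:margin] + element_seq + bg[margin:]})


@pytest.fixture(scope="module")
def classified_small_panel(small_panel_detected):
    return small_panel_detected[1]


class TestCategories:
    @pytest.mark.parametrize("category", ["solo_ltr", "relic", "full"])
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planted_category_recovered(self, templates, panel, params, rng, category, strand):
        asm = _plant(rng, templates["Ty1"].element_sequence(category), strand=strand)
        hits = scan_ltrs(asm, panel, params)
        elements = classify_ltr_context(hits, asm, panel, params)
        assert len(elements) == 1
        el = elements[0]
        assert el.category == category
        assert el.strand == strand
        if category == "full":
            assert {h.context for h in el.ltr_hits} == {"coding_5prime", "coding_3prime"}
        elif category == "solo_ltr":
            assert el.ltr_hits[0].context == "solo"
        else:
            assert el.ltr_hits[0].context == "relic_adjacent"

    def test_every_hit_ends_with_one_context(self, small_panel_detected):
        hits_by_strain, elements_by_strain = small_panel_detected
        for strain, hits in hits_by_strain.items():
            assert all(h.context != "unassigned" for h in hits)
            seen = set()
            for el in elements_by_strain[strain]:
                for h in el.ltr_hits:
                    assert id(h) not in seen, "hit shared between elements"
                    seen.add(id(h))

    def test_full_recovery_on_noise_free_panel(self, small_panel, small_panel_detected):
        from tyscape.evaluate import score_recovery

        _, elements = small_panel_detected
        for strain in small_panel.strains:
            score = score_recovery(small_panel.truth_for(strain), elements[strain])
            assert score.precision == 1.0
            assert score.recall == 1.0


class TestAssignTy1Ty2:
    def test_element_equal_to_reference_assigned_with_margin(self, templates, panel, params, rng):
        asm = _plant(rng, templates["Ty1"].full_sequence)
        hits = scan_ltrs(asm, panel, params)
        el = classify_ltr_context(hits, asm, panel, params)[0]
        family, margin = assign_ty1_ty2(el, asm, panel, params)
        assert family == "Ty1"
        assert margin > 0

    def test_equidistant_element_flagged_ambiguous(self, templates, panel, params, rng):
        """With both reference sets identical by construction, every margin
        is zero and the element keeps a flagged family."""
        asm = _plant(rng, templates["Ty1"].full_sequence)
        hits = scan_ltrs(asm, panel, params)
        el = classify_ltr_context(hits, asm, panel, params)[0]
        degenerate = QueryPanel(
            ltr=panel.ltr, tya=panel.tya, tyb=panel.tyb,
            ty1_refs={"r": templates["Ty1"].full_sequence},
            ty2_refs={"r": templates["Ty1"].full_sequence},
        )
        family, margin = assign_ty1_ty2(el, asm, degenerate, params)
        assert margin == 0
        assert el.ambiguous_family

    def test_missing_reference_set_rejected(self, templates, panel, params, rng):
        asm = _plant(rng, templates["Ty1"].full_sequence)
        hits = scan_ltrs(asm, panel, params)
        el = classify_ltr_context(hits, asm, panel, params)[0]
        broken = QueryPanel(ltr=panel.ltr, tya=panel.tya, tyb=panel.tyb)
        with pytest.raises(ValueError):
            assign_ty1_ty2(el, asm, broken, params)

    def test_panel_assignment_accuracy_at_divergence(self, templates, panel, params):
        """Planted Ty1/Ty2 elements at 5% divergence are all assigned to the
        right family."""
        spec = PlantSpec(
            seed=44, n_strains=2, genome_length=150_000, divergence_rate=0.05,
            counts={"Ty1": CategoryCounts(full=2), "Ty2": CategoryCounts(full=2)},
            variant_full_counts={},
        )
        pan = simulate_strain_panel(spec, templates=templates)
        for strain, asm in pan.strains.items():
            hits = scan_ltrs(asm, panel, params)
            elements = classify_strain(hits, asm, panel, params)
            truth = {t.start: t.family for t in pan.truth_for(strain)}
            fulls = [el for el in elements if el.category == "full"]
            assert len(fulls) == 4
            for el in fulls:
                expected = min(truth, key=lambda s: abs(s - el.start))
                assert el.family == truth[expected]


class TestDetectHybrid:
    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("kind,expected", [("full", "full_hybrid"), ("short", "short_hybrid")])
    def test_planted_hybrids_labeled(self, templates, panel, params, rng, kind, expected, strand):
        hybrid = make_hybrid(templates["Ty1"], templates["Ty2"], kind)
        asm = _plant(rng, hybrid.full_sequence, strand=strand)
        hits = scan_ltrs(asm, panel, params)
        elements = classify_strain(hits, asm, panel, params)
        fulls = [el for el in elements if el.category == "full"]
        assert len(fulls) == 1
        assert fulls[0].hybrid_status == expected

    def test_pure_ty1_not_flagged(self, templates, panel, params, rng):
        asm = _plant(rng, templates["Ty1"].full_sequence)
        hits = scan_ltrs(asm, panel, params)
        el = classify_strain(hits, asm, panel, params)[0]
        assert el.hybrid_status == "none"

    def test_hybrid_call_invariant_to_position(self, templates, panel, params, rng):
        hybrid = make_hybrid(templates["Ty1"], templates["Ty2"], "full")
        for margin in (8_000, 30_000):
            asm = _plant(rng, hybrid.full_sequence, margin=margin)
            hits = scan_ltrs(asm, panel, params)
            fulls = [
                el for el in classify_strain(hits, asm, panel, params)
                if el.category == "full"
            ]
            assert fulls[0].hybrid_status == "full_hybrid"


class TestSummarizeCoding:
    def test_zero_ty2_flagged_not_division_error(self, templates, panel, params, rng):
        asm = _plant(rng, templates["Ty1"].full_sequence)
        hits = scan_ltrs(asm, panel, params)
        elements = classify_strain(hits, asm, panel, params)
        table = summarize_coding({"s": elements})
        assert table.loc["s", "ratio_flag"] == "no_Ty2"
        assert table.loc["s", "ty1_ty2_ratio"] == float("inf")

    def test_relic_only_strain_counts(self, templates, panel, params, rng):
        asm = _plant(rng, templates["Ty1"].element_sequence("relic"))
        hits = scan_ltrs(asm, panel, params)
        elements = classify_strain(hits, asm, panel, params)
        table = summarize_coding({"s": elements})
        assert table.loc["s", "Ty1_full"] == 0
        assert table.loc["s", "relics"] == 1
        assert table.loc["s", "ratio_flag"] == "no_coding"

    def test_coding_ltrs_are_subset_of_total(self, small_panel_detected):
        hits_by_strain, elements_by_strain = small_panel_detected
        table = summarize_coding(elements_by_strain)
        for strain in hits_by_strain:
            coding = sum(
                table.loc[strain, f"{f}_coding_ltrs"]
                for f in ("Ty1", "Ty2", "Ty3", "Ty4", "Ty5")
            )
            assert coding <= len(hits_by_strain[strain])
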