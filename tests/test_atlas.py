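"""Insertion atlas: flanks, mapping, loci, spectra, clustering."""

import numpy as np
import pandas as pd
import pytest
import skbio

from _oracles import random_dna
from tyscape import atlas
from tyscape.classify import TyElement
from tyscape.genome import GenomeAssembly, GenomeFeature
from tyscape.evaluate import locus_truth_labels, rand_index
from tyscape.synthetic import CategoryCounts, PlantSpec, simulate_strain_panel


def _element(start, end, strain="s", contig="chr1", family="Ty1", category="full"):
    return TyElement(
        strain=strain, contig=contig, start=start, end=end, strand="+",
        family=family, category=category,
    )


def _mapped(strain, family, pos, coding=False, contig="chr1"):
    return atlas.MappedInsertion(
        strain=strain, family=family, contig=contig, position=pos,
        is_coding=coding, category="full" if coding else "solo_ltr",
        element_id=f"{strain}:{pos}",
    )


class TestExtractFlanks:
    def test_center_element_yields_full_flanks(self, rng):
        seq = random_dna(rng, 12_000)
        asm = GenomeAssembly("s", {"chr1": seq})
        el = _element(6_000, 6_300)
        left, right = atlas.extract_flanks(el, asm, 2_500)
        assert left.sequence == seq[3_500:6_000]
        assert right.sequence == seq[6_300:8_800]
        assert not left.truncated and not right.truncated

    def test_element_at_origin_has_empty_left_flank(self, rng):
        asm = GenomeAssembly("s", {"chr1": random_dna(rng, 5_000)})
        left, right = atlas.extract_flanks(_element(0, 300), asm, 2_500)
        assert left.sequence == ""
        assert left.truncated

    def test_concatenation_reconstructs_slice(self, rng):
        seq = random_dna(rng, 9_000)
        asm = GenomeAssembly("s", {"chr1": seq})
        el = _element(4_000, 4_500)
        left, right = atlas.extract_flanks(el, asm, 2_500)
        assert left.sequence + seq[el.start : el.end] + right.sequence == seq[1_500:7_000]


class TestMaskAndMap:
    def test_verbatim_flank_maps_uniquely_and_exactly(self, panel, params, rng):
        ref_seq = random_dna(rng, 50_000)
        reference = GenomeAssembly("ref", {"chr1": ref_seq})
        flank = atlas.Flank(ref_seq[20_000:22_500], "left", False)
        res = atlas.mask_and_map(flank, panel, reference, params)
        assert res.status == "unique"
        assert res.position == 22_500

    def test_right_flank_junction_position(self, panel, params, rng):
        ref_seq = random_dna(rng, 50_000)
        reference = GenomeAssembly("ref", {"chr1": ref_seq})
        flank = atlas.Flank(ref_seq[30_000:32_500], "right", False)
        res = atlas.mask_and_map(flank, panel, reference, params)
        assert res.status == "unique"
        assert res.position == 30_000

    def test_pure_ty_flank_is_unmapped(self, templates, panel, params, rng):
        reference = GenomeAssembly("ref", {"chr1": random_dna(rng, 30_000)})
        flank = atlas.Flank(templates["Ty1"].full_sequence[:2_500], "left", False)
        res = atlas.mask_and_map(flank, panel, reference, params)
        assert res.status == "unmapped"

    def test_duplicated_reference_segment_is_ambiguous(self, panel, params, rng):
        segment = random_dna(rng, 2_500)
        ref_seq = (
            random_dna(rng, 10_000) + segment + random_dna(rng, 10_000)
            + segment + random_dna(rng, 10_000)
        )
        reference = GenomeAssembly("ref", {"chr1": ref_seq})
        res = atlas.mask_and_map(atlas.Flank(segment, "left", False), panel, reference, params)
        assert res.status == "ambiguous"


class TestClusterLoci:
    def test_nearby_junctions_merge(self):
        loci = atlas.cluster_loci([_mapped("a", "Ty1", 1000), _mapped("b", "Ty1", 1003)], 40)
        assert len(loci) == 1
        assert loci[0].occupancy == {"a", "b"}

    def test_same_position_different_family_stays_split(self):
        loci = atlas.cluster_loci([_mapped("a", "Ty1", 1000), _mapped("b", "Ty2", 1000)], 40)
        assert len(loci) == 2

    def test_strain_contributes_once_per_locus(self):
        loci = atlas.cluster_loci(
            [_mapped("a", "Ty1", 1000), _mapped("a", "Ty1", 1010)], 40
        )
        assert len(loci) == 1
        assert len(loci[0].occupancy) == 1

    def test_partition_invariant_to_input_order(self):
        inserts = [
            _mapped("a", "Ty1", 100), _mapped("b", "Ty1", 130),
            _mapped("c", "Ty2", 500), _mapped("a", "Ty1", 5_000),
        ]
        fwd = atlas.cluster_loci(inserts, 40)
        rev = atlas.cluster_loci(inserts[::-1], 40)
        key = lambda loci: sorted(
            tuple(sorted((m.strain, m.position) for m in l.members)) for l in loci
        )
        assert key(fwd) == key(rev)


class TestSpectrum:
    def test_single_private_locus_masses_at_one(self):
        m = pd.DataFrame([[True], [False]], index=["a", "b"], columns=["l1"])
        spec = atlas.occupancy_spectrum(m)
        assert spec.loc[1] == 1.0
        assert spec.sum() == pytest.approx(1.0)

    def test_saturated_matrix_masses_at_n(self):
        m = pd.DataFrame(True, index=["a", "b", "c"], columns=["l1", "l2"])
        spec = atlas.occupancy_spectrum(m)
        assert spec.loc[3] == pytest.approx(1.0)

    def test_spectrum_sums_to_one_both_modes(self, rng):
        m = pd.DataFrame(
            rng.random((5, 12)) < 0.5, index=[f"s{i}" for i in range(5)],
            columns=[f"l{j}" for j in range(12)],
        )
        m.iloc[0, 0] = True  # keep at least one occupied locus
        for mode in ("insertions", "loci"):
            assert atlas.occupancy_spectrum(m, mode).sum() == pytest.approx(1.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            atlas.occupancy_spectrum(pd.DataFrame(index=["a"]))


class TestPolIII:
    def test_no_annotation_gives_zero(self):
        loci = atlas.cluster_loci([_mapped("a", "Ty1", 1000)], 40)
        assert atlas.polIII_proximity(loci, []) == 0.0

    def test_all_adjacent_gives_one(self):
        loci = atlas.cluster_loci([_mapped("a", "Ty1", 1000), _mapped("a", "Ty2", 9000)], 40)
        genes = [
            GenomeFeature("chr1", 1_200, 1_272, "+", "t1"),
            GenomeFeature("chr1", 8_500, 8_572, "+", "t2"),
        ]
        assert atlas.polIII_proximity(loci, genes, window=1_000) == 1.0


class TestClusterStrains:
    def test_identical_rows_merge_at_height_zero(self):
        m = pd.DataFrame(
            [[1, 0, 1], [1, 0, 1], [0, 1, 0]], dtype=bool,
            index=["a", "b", "c"], columns=["l1", "l2", "l3"],
        )
        newick, order, _ = atlas.cluster_strains(m)
        tree = skbio.TreeNode.read([newick])
        ab = tree.lca(["a", "b"])
        assert {t.name for t in ab.tips()} == {"a", "b"}
        assert sum(t.length for t in ab.children) == pytest.approx(0.0)

    def test_block_structure_recovers_planted_clades(self, rng):
        block = np.zeros((6, 20), dtype=bool)
        block[:3, :10] = True
        block[3:, 10:] = True
        m = pd.DataFrame(block, index=[f"s{i}" for i in range(6)],
                         columns=[f"l{j}" for j in range(20)])
        newick, _, _ = atlas.cluster_strains(m)
        tree = skbio.TreeNode.read([newick])
        clade_a = {t.name for t in tree.lca(["s0", "s1", "s2"]).tips()}
        clade_b = {t.name for t in tree.lca(["s3", "s4", "s5"]).tips()}
        assert clade_a == {"s0", "s1", "s2"}
        assert clade_b == {"s3", "s4", "s5"}

    def test_row_permutation_leaves_clusters_unchanged(self):
        """Tie-free profiles cluster identically whatever the row order
        (with exact distance ties the smallest-index merge rule makes the
        order matter, so the fixture is drawn until tie-free)."""
        from scipy.spatial.distance import pdist

        r = np.random.default_rng(0)
        while True:
            m = pd.DataFrame(
                r.random((5, 15)) < 0.4, index=[f"s{i}" for i in range(5)],
                columns=[f"l{j}" for j in range(15)],
            )
            d = pdist(m.to_numpy(), metric="jaccard")
            if np.isfinite(d).all() and len(np.unique(d)) == len(d):
                break
        newick_a, _, _ = atlas.cluster_strains(m)
        shuffled = m.sample(frac=1.0, random_state=3)
        newick_b, _, _ = atlas.cluster_strains(shuffled)
        ta = skbio.TreeNode.read([newick_a])
        tb = skbio.TreeNode.read([newick_b])
        assert ta.compare_rfd(tb) == 0.0


class TestEndToEndAtlas:
    def test_locus_partition_matches_truth(self, small_panel, small_panel_detected, panel, params):
        """Detected locus partition equals the planted locus_id partition."""
        _, elements = small_panel_detected
        mapped = []
        for strain, asm in small_panel.strains.items():
            m, tally = atlas.map_elements(elements[strain], asm, panel, small_panel.reference, params)
            assert tally["unmapped"] == 0
            mapped.extend(m)
        loci = atlas.cluster_loci(mapped)
        det = [l.locus_id for l in loci for _ in l.members]
        flat = [m for l in loci for m in l.members]
        truth = locus_truth_labels(flat, small_panel.loci)
        assert rand_index(det, truth) == 1.0
        # conservation: insertions survive clustering
        assert sum(len(l.members) for l in loci) == len(mapped)
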