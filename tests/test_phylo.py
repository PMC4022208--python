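"""Segments, progressive alignment, HKY85 distances, NJ trees, subfamilies."""

import math

import numpy as np
import pytest
import skbio

from _oracles import SimpleTree, hky85_pair, random_dna
from tyscape import phylo
from tyscape.align import global_identity, reverse_complement
from tyscape.classify import classify_strain
from tyscape.genome import GenomeAssembly
from tyscape.scan import scan_ltrs


def _plant(rng, element_seq, strand="+", margin=15_000):
    bg = random_dna(rng, 2 * margin)
    if strand == "-":
        element_seq = reverse_complement(element_seq)
    return GenomeAssembly("s", {"chr1": bg[:margin] + element_seq + bg[margin:]})


def _segments_for(template, panel, params, rng, strand="+", category="full"):
    asm = _plant(rng, template.element_sequence(category), strand=strand)
    hits = scan_ltrs(asm, panel, params)
    elements = classify_strain(hits, asm, panel, params)
    return phylo.extract_segments(elements, asm)


class TestExtractSegments:
    def test_tya300_equals_template_head(self, templates, panel, params, rng):
        segs = _segments_for(templates["Ty1"], panel, params, rng)
        tya = [s for s in segs.segments if s.kind == "TYA300"]
        tyb = [s for s in segs.segments if s.kind == "TYB300"]
        assert len(tya) == 1 and len(tyb) == 1
        assert tya[0].sequence == templates["Ty1"].tya[:300]
        assert tyb[0].sequence == templates["Ty1"].tyb[-300:]

    def test_minus_strand_yields_same_segment(self, templates, panel, params, rng):
        plus = _segments_for(templates["Ty2"], panel, params, rng, strand="+")
        minus = _segments_for(templates["Ty2"], panel, params, rng, strand="-")
        get = lambda ss, kind: next(s.sequence for s in ss.segments if s.kind == kind)
        assert get(plus, "TYA300") == get(minus, "TYA300")
        assert get(plus, "TYB300") == get(minus, "TYB300")

    def test_relic_yields_tya300_only(self, templates, panel, params, rng):
        segs = _segments_for(templates["Ty1"], panel, params, rng, category="relic")
        kinds = [s.kind for s in segs.segments]
        assert kinds == ["TYA300"]


class TestAlignSegments:
    def test_identical_sequences_align_gap_free(self, rng):
        seq = random_dna(rng, 120)
        aligned = phylo.align_segments({"a": seq, "b": seq, "c": seq})
        assert all(v == seq for v in aligned.values())

    def test_two_sequences_match_pairwise_alignment(self, rng):
        a = random_dna(rng, 100)
        b = a[:40] + a[55:]  # 15-nt deletion
        aligned = phylo.align_segments({"a": a, "b": b})
        assert len(aligned["a"]) == len(aligned["b"])
        assert aligned["a"].replace("-", "") == a
        assert aligned["b"].replace("-", "") == b
        assert len(aligned["a"]) >= 100

    def test_column_count_at_least_max_input(self, rng):
        seqs = {f"s{i}": random_dna(rng, 80 + 10 * i) for i in range(4)}
        aligned = phylo.align_segments(seqs)
        cols = {len(v) for v in aligned.values()}
        assert len(cols) == 1
        assert cols.pop() >= max(len(v) for v in seqs.values())

    def test_single_segment_returned_as_is(self, rng):
        seq = random_dna(rng, 50)
        assert phylo.align_segments({"a": seq}) == {"a": seq}


def _jc_pair():
    """600-column pair with equal pooled base frequencies, transition
    proportion equal to half the transversion proportion, and total
    mismatch fraction 0.1 — the Jukes-Cantor limit of HKY85."""
    cols = []
    for base, n in (("A", 135), ("C", 135), ("G", 135), ("T", 135)):
        cols += [(base, base)] * n
    cols += [("A", "G")] * 10 + [("C", "T")] * 10
    cols += [("A", "C")] * 10 + [("G", "T")] * 10 + [("A", "T")] * 10 + [("C", "G")] * 10
    a = "".join(x for x, _ in cols)
    b = "".join(y for _, y in cols)
    return a, b


class TestHKY85:
    def test_identical_rows_zero(self, rng):
        seq = random_dna(rng, 200)
        assert phylo.hky85_distance(seq, seq) == 0.0

    def test_jukes_cantor_limit(self):
        a, b = _jc_pair()
        expected = -0.75 * math.log(1 - 4 * 0.1 / 3)
        assert phylo.hky85_distance(a, b) == pytest.approx(expected, abs=1e-9)

    def test_saturation_returns_infinity(self):
        a = "A" * 100 + "C" * 100
        b = "G" * 100 + "T" * 100
        assert phylo.hky85_distance(a, b) == math.inf

    def test_gap_columns_excluded(self, rng):
        seq = random_dna(rng, 100)
        gapped = "--" + seq[2:]
        assert phylo.hky85_distance(seq, gapped) == 0.0

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError):
            phylo.hky85_distance("----", "AAAA")

    def test_recovers_simulated_distance(self):
        """Mean estimate over 100 HKY85-simulated pairs (d=0.2, kappa=4,
        10,000 sites) lands within 0.01 of the truth."""
        r = np.random.default_rng(99)
        pi = np.array([0.3, 0.2, 0.2, 0.3])
        estimates = [
            phylo.hky85_distance(*hky85_pair(0.2, 4.0, pi, 10_000, r))
            for _ in range(100)
        ]
        assert abs(np.mean(estimates) - 0.2) <= 0.01

    def test_symmetry_and_monotonicity(self, rng):
        a = random_dna(rng, 400)
        prev = 0.0
        for n_sub in (4, 12, 24, 40):
            b = list(a)
            flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
            for p in range(n_sub):
                b[10 * p] = flip[b[10 * p]]
            b = "".join(b)
            d = phylo.hky85_distance(a, b)
            assert d == phylo.hky85_distance(b, a)
            assert d >= prev
            prev = d


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["a", "b", "c"]
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = skbio.TreeNode.read([phylo.nj_tree(labels, d)])
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert tips["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert tips["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_additive_six_taxon_round_trip(self):
        """NJ recovers topology and path lengths exactly from an additive
        matrix generated on a known tree."""
        edges = {
            ("a", "u"): 0.11, ("b", "u"): 0.23, ("u", "v"): 0.15,
            ("c", "v"): 0.31, ("v", "w"): 0.09, ("d", "w"): 0.27,
            ("w", "x"): 0.13, ("e", "x"): 0.19, ("f", "x"): 0.05,
        }
        oracle = SimpleTree(edges)
        leaves = ["a", "b", "c", "d", "e", "f"]
        d = oracle.matrix(leaves)
        tree = skbio.TreeNode.read([phylo.nj_tree(leaves, d)])
        for i, x in enumerate(leaves):
            for y in leaves[i + 1 :]:
                got = tree.find(x).distance(tree.find(y))
                assert got == pytest.approx(d[leaves.index(x), leaves.index(y)], abs=1e-9)

    def test_label_permutation_invariance(self, rng):
        edges = {
            ("a", "u"): 0.2, ("b", "u"): 0.1, ("u", "v"): 0.3,
            ("c", "v"): 0.25, ("d", "v"): 0.15,
        }
        oracle = SimpleTree(edges)
        leaves = ["a", "b", "c", "d"]
        d = oracle.matrix(leaves)
        t1 = skbio.TreeNode.read([phylo.nj_tree(leaves, d)])
        perm = [2, 0, 3, 1]
        t2 = skbio.TreeNode.read(
            [phylo.nj_tree([leaves[i] for i in perm], d[np.ix_(perm, perm)])]
        )
        assert t1.compare_rfd(t2) == 0.0

    def test_agrees_with_independent_nj_implementation(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        labels = [f"t{i}" for i in range(7)]
        base = rng.random((7, 7))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        ours = skbio.TreeNode.read([phylo.nj_tree(labels, d)])
        theirs = skbio_nj(DistanceMatrix(d, labels))
        assert ours.compare_rfd(theirs) == 0.0

    def test_infinite_distance_rejected_by_name(self):
        d = np.array([[0.0, np.inf, 1.0], [np.inf, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="alpha"):
            phylo.nj_tree(["alpha", "beta", "gamma"], d)


class TestSubfamilies:
    def test_exemplar_match_labeled(self, templates, panel, params):
        seg = phylo.Segment("e1|TYA300", "s", "TYA300", templates["Ty1"].tya[:300])
        calls = phylo.call_subfamilies(
            phylo.SegmentSet([seg]),
            phylo.exemplars_from_panel(panel, "TYA300"),
            phylo.exemplars_from_panel(panel, "TYB300"),
        )
        assert calls.iloc[0]["label"] == "Ty1"

    def test_variant_at_92_percent_becomes_novel_cluster(self, templates, panel, params):
        """A TYA segment at 0.92 identity to Ty1 falls below the subfamily
        threshold and opens its own cluster, separate from Ty1."""
        segs = [
            phylo.Segment("e1|TYA300", "s1", "TYA300", templates["Ty102"].tya[:300]),
            phylo.Segment("e2|TYA300", "s2", "TYA300", templates["Ty102"].tya[:300]),
            phylo.Segment("e3|TYA300", "s1", "TYA300", templates["Ty1"].tya[:300]),
        ]
        calls = phylo.call_subfamilies(
            phylo.SegmentSet(segs),
            phylo.exemplars_from_panel(panel, "TYA300"),
            phylo.exemplars_from_panel(panel, "TYB300"),
        )
        labels = dict(zip(calls["segment_id"], calls["label"]))
        assert labels["e3|TYA300"] == "Ty1"
        assert labels["e1|TYA300"].startswith("novel")
        assert labels["e1|TYA300"] == labels["e2|TYA300"]

    def test_short_hybrid_tyb_segments_cluster_apart(self, templates, panel, params):
        from tyscape.synthetic import make_hybrid

        hybrid = make_hybrid(templates["Ty1"], templates["Ty2"], "short")
        segs = [
            phylo.Segment("h1|TYB300", "s1", "TYB300", hybrid.tyb[-300:]),
            phylo.Segment("h2|TYB300", "s2", "TYB300", hybrid.tyb[-300:]),
            phylo.Segment("p1|TYB300", "s1", "TYB300", templates["Ty1"].tyb[-300:]),
            phylo.Segment("p2|TYB300", "s2", "TYB300", templates["Ty2"].tyb[-300:]),
        ]
        calls = phylo.call_subfamilies(
            phylo.SegmentSet(segs),
            phylo.exemplars_from_panel(panel, "TYA300"),
            phylo.exemplars_from_panel(panel, "TYB300"),
        )
        labels = dict(zip(calls["segment_id"], calls["label"]))
        assert labels["h1|TYB300"] == labels["h2|TYB300"] == "short_hybrid"
        assert labels["p1|TYB300"] == "Ty1"
        assert labels["p2|TYB300"] == "Ty2"

    def test_empty_exemplars_rejected(self):
        with pytest.raises(ValueError):
            phylo.call_subfamilies(phylo.SegmentSet([]), {}, {})

    def test_tyb_tree_separates_ty1_and_ty2_clades(self, templates):
        """TYB300 trees show the clear-cut Ty1-vs-Ty2 phylogenetic split."""
        rng = np.random.default_rng(5)
        from tyscape.synthetic import mutate_at_rate

        seqs = {}
        for i in range(4):
            seqs[f"ty1x{i}"] = mutate_at_rate(templates["Ty1"].tyb[-300:], 0.02, rng)
            seqs[f"ty2x{i}"] = mutate_at_rate(templates["Ty2"].tyb[-300:], 0.02, rng)
        aligned = phylo.align_segments(seqs)
        labels, d = phylo.distance_matrix(aligned)
        tree = skbio.TreeNode.read([phylo.nj_tree(labels, d)])
        dist = {}
        for a in labels:
            for b in labels:
                if a < b:
                    dist[(a, b)] = tree.find(a).distance(tree.find(b))
        intra = [v for (a, b), v in dist.items() if a[:3] == b[:3]]
        inter = [v for (a, b), v in dist.items() if a[:3] != b[:3]]
        assert max(intra) < min(inter)
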