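"""Stage 2: promote LTR hits to categorized Ty elements.

An LTR pair with interior TYA and TYB in consistent orientation becomes a
full element; an isolated LTR with adjacent TYA but no TYB and no terminal
LTR is a relic; an isolated LTR with no coding context is a solo-LTR; coding
sequence without a resolvable element is a fragment.  Ty1-vs-Ty2 identity of
a coding element is decided by the best alignment score against a reference
set of characterized non-hybrid elements, and Ty1/2 recombination hybrids are
flagged from the family-of-origin of their TYA, TYB and terminal LTR-U3
segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import (
    AlignmentParams,
    SubjectIndex,
    global_score,
    reverse_complement,
    seeded_search,
    smith_waterman,
)
from .genome import GenomeAssembly
from .scan import FAMILIES, LTRHit, QueryPanel

# max gap (nt) between an LTR inner edge and its adjacent coding sequence:
# wide enough to tolerate hybrid LTRs whose 5' part matches another family,
# narrow enough that two independently planted neighbours never look adjacent
ADJACENT_GAP = 120
# LTR hits abutting a constituent LTR within this gap are absorbed into the
# element (two-family hits over one physical hybrid LTR)
ABSORB_GAP = 20
PAIR_MIN_SPAN = 4_000  # between LTR outer edges of a full element
PAIR_MAX_SPAN = 8_000
INTERIOR_WINDOW = 6_000  # coding search window interior to an LTR


@dataclass
class CodingHit:
    """A located TYA or TYB similarity hit."""

    contig: str
    start: int
    end: int
    strand: str
    family: str
    kind: str  # "tya" | "tyb"
    score: int
    identity: float
    used: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TyElement:
    """A categorized Ty annotation spanning all constituent parts."""

    strain: str
    contig: str
    start: int
    end: int
    strand: str
    family: str
    category: str  # full | solo_ltr | relic | fragment
    subfamily_label: str = ""
    hybrid_status: str = "none"  # none | full_hybrid | short_hybrid | indistinguishable
    ltr_hits: list[LTRHit] = field(default_factory=list)
    coding_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    assignment_margin: int | None = None
    ambiguous_family: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def element_id(self) -> str:
        return f"{self.strain}:{self.contig}:{self.start}-{self.end}"


def _sister(family: str) -> str | None:
    return {"Ty1": "Ty2", "Ty2": "Ty1"}.get(family)


def scan_coding(
    assembly: GenomeAssembly, panel: QueryPanel, params: AlignmentParams
) -> list[CodingHit]:
    """Genome-wide TYA/TYB similarity hits, cross-family collisions resolved.

    Within the closely related Ty1/Ty2 pair both queries hit the same coding
    sequence; overlapping hits of the same kind keep the best-scoring family.
    """
    hits: list[CodingHit] = []
    for contig, seq in assembly.contigs.items():
        index = SubjectIndex(seq, params.seed_length)
        for family in FAMILIES:
            for kind, query in (("tya", panel.tya.get(family)), ("tyb", panel.tyb.get(family))):
                if not query:
                    continue
                for aln in seeded_search(query, index, params, query_id=family, subject_id=contig):
                    hits.append(
                        CodingHit(
                            contig, aln.subject_start, aln.subject_end, aln.strand,
                            family, kind, aln.score, aln.identity,
                        )
                    )
    # resolve overlaps of the same kind between families (best score wins)
    hits.sort(key=lambda h: (h.contig, h.kind, h.start, -h.score, h.family))
    resolved: list[CodingHit] = []
    for h in hits:
        clash = False
        for r in resolved:
            if r.contig == h.contig and r.kind == h.kind and r.strand == h.strand:
                ov = max(0, min(r.end, h.end) - max(r.start, h.start))
                if 2 * ov >= min(r.end - r.start, h.end - h.start):
                    clash = True
                    break
        if not clash:
            resolved.append(h)
    resolved.sort(key=lambda h: (h.contig, h.start))
    return resolved


def _find_adjacent(
    coding: list[CodingHit], contig: str, strand: str, kind: str,
    edge: int, side: str, families: set[str],
) -> CodingHit | None:
    """Coding hit of *kind* whose start (side='after') or end (side='before')
    lies within ADJACENT_GAP of *edge*."""
    best: CodingHit | None = None
    for h in coding:
        if h.contig != contig or h.strand != strand or h.kind != kind or h.used:
            continue
        if h.family not in families:
            continue
        if side == "after" and 0 <= h.start - edge <= ADJACENT_GAP:
            pass
        elif side == "before" and 0 <= edge - h.end <= ADJACENT_GAP:
            pass
        else:
            continue
        if best is None or h.score > best.score:
            best = h
    return best


def classify_ltr_context(
    hits: list[LTRHit],
    assembly: GenomeAssembly,
    panel: QueryPanel,
    params: AlignmentParams | None = None,
    coding: list[CodingHit] | None = None,
) -> list[TyElement]:
    """Classify every LTR hit of one strain into elements.

    Returns elements sorted by coordinate; each input hit's ``context``
    field is updated in place and ends with exactly one label.
    """
    params = params or AlignmentParams()
    if coding is None:
        coding = scan_coding(assembly, panel, params)
    elements: list[TyElement] = []
    used: set[int] = set()
    order = sorted(range(len(hits)), key=lambda i: (hits[i].contig, hits[i].start))

    def fams(f: str) -> set[str]:
        s = _sister(f)
        return {f, s} if s else {f}

    # -- pass 1: pair 5'/3' LTRs into full elements ------------------------
    for ii in order:
        if ii in used:
            continue
        a = hits[ii]
        for jj in order:
            if jj in used or jj == ii:
                continue
            b = hits[jj]
            if (
                b.contig != a.contig or b.family != a.family
                or b.strand != a.strand or b.start <= a.start
            ):
                continue
            span = b.end - a.start
            if span < PAIR_MIN_SPAN:
                continue
            if span > PAIR_MAX_SPAN:
                break
            if a.strand == "+":
                tya = _find_adjacent(coding, a.contig, "+", "tya", a.end, "after", fams(a.family))
                tyb = _find_adjacent(coding, a.contig, "+", "tyb", b.start, "before", fams(a.family))
                ordered = tya and tyb and tya.end <= tyb.start + ADJACENT_GAP
            else:
                tyb = _find_adjacent(coding, a.contig, "-", "tyb", a.end, "after", fams(a.family))
                tya = _find_adjacent(coding, a.contig, "-", "tya", b.start, "before", fams(a.family))
                ordered = tya and tyb and tyb.end <= tya.start + ADJACENT_GAP
            if not ordered:
                continue
            tya.used = True
            tyb.used = True
            five, three = (a, b) if a.strand == "+" else (b, a)
            five.context = "coding_5prime"
            three.context = "coding_3prime"
            elements.append(
                TyElement(
                    strain=a.strain, contig=a.contig, start=a.start, end=b.end,
                    strand=a.strand, family=a.family, category="full",
                    ltr_hits=[a, b],
                    coding_intervals={"tya": tya.interval, "tyb": tyb.interval},
                )
            )
            used.add(ii)
            used.add(jj)
            break

    # -- absorb sibling hits over the same physical (hybrid) LTR -----------
    for ii in order:
        if ii in used:
            continue
        h = hits[ii]
        for el in elements:
            if el.contig != h.contig or el.strand != h.strand:
                continue
            for part in list(el.ltr_hits):
                gap = max(part.start - h.end, h.start - part.end)
                if gap <= ABSORB_GAP and h.family != part.family:
                    h.context = part.context
                    el.ltr_hits.append(h)
                    el.start = min(el.start, h.start)
                    el.end = max(el.end, h.end)
                    used.add(ii)
                    break
            if ii in used:
                break

    # -- pass 2: relics, broken elements, solo-LTRs ------------------------
    for ii in order:
        if ii in used:
            continue
        h = hits[ii]
        interior_edge = h.end if h.strand == "+" else h.start
        side = "after" if h.strand == "+" else "before"
        tya = _find_adjacent(coding, h.contig, h.strand, "tya", interior_edge, side, fams(h.family))
        if tya is not None:
            next_edge = tya.end if h.strand == "+" else tya.start
            tyb = _find_adjacent(coding, h.contig, h.strand, "tyb", next_edge, side, fams(h.family))
            tya.used = True
            lo = min(h.start, tya.start)
            hi = max(h.end, tya.end)
            if tyb is None:
                h.context = "relic_adjacent"
                elements.append(
                    TyElement(
                        strain=h.strain, contig=h.contig, start=lo, end=hi,
                        strand=h.strand, family=h.family, category="relic",
                        ltr_hits=[h], coding_intervals={"tya": tya.interval},
                    )
                )
            else:
                tyb.used = True
                h.context = "coding_5prime"
                elements.append(
                    TyElement(
                        strain=h.strain, contig=h.contig,
                        start=min(lo, tyb.start), end=max(hi, tyb.end),
                        strand=h.strand, family=h.family, category="fragment",
                        ltr_hits=[h],
                        coding_intervals={"tya": tya.interval, "tyb": tyb.interval},
                    )
                )
            used.add(ii)
            continue
        # a lone 3' LTR downstream of orphaned TYB?
        outer_edge = h.start if h.strand == "+" else h.end
        tyb_side = "before" if h.strand == "+" else "after"
        tyb = _find_adjacent(coding, h.contig, h.strand, "tyb", outer_edge, tyb_side, fams(h.family))
        if tyb is not None:
            tyb.used = True
            h.context = "coding_3prime"
            parts = {"tyb": tyb.interval}
            tya_edge = tyb.start if h.strand == "+" else tyb.end
            tya = _find_adjacent(coding, h.contig, h.strand, "tya", tya_edge, tyb_side, fams(h.family))
            lo = min(h.start, tyb.start)
            hi = max(h.end, tyb.end)
            if tya is not None:
                tya.used = True
                parts["tya"] = tya.interval
                lo = min(lo, tya.start)
                hi = max(hi, tya.end)
            elements.append(
                TyElement(
                    strain=h.strain, contig=h.contig, start=lo, end=hi,
                    strand=h.strand, family=h.family, category="fragment",
                    ltr_hits=[h], coding_intervals=parts,
                )
            )
            used.add(ii)
            continue
        h.context = "solo"
        elements.append(
            TyElement(
                strain=h.strain, contig=h.contig, start=h.start, end=h.end,
                strand=h.strand, family=h.family, category="solo_ltr",
                ltr_hits=[h],
            )
        )
        used.add(ii)

    # -- pass 3: leftover coding hits without any LTR ----------------------
    leftovers = [h for h in coding if not h.used]
    leftovers.sort(key=lambda h: (h.contig, h.strand, h.start))
    chain: list[CodingHit] = []

    def flush(chain: list[CodingHit]) -> None:
        if not chain:
            return
        fam = max(chain, key=lambda c: c.score).family
        elements.append(
            TyElement(
                strain=assembly.strain, contig=chain[0].contig,
                start=chain[0].start, end=chain[-1].end,
                strand=chain[0].strand, family=fam, category="fragment",
                coding_intervals={c.kind: c.interval for c in chain},
            )
        )

    for h in leftovers:
        if chain and (
            h.contig != chain[-1].contig
            or h.strand != chain[-1].strand
            or h.start - chain[-1].end > ADJACENT_GAP
        ):
            flush(chain)
            chain = []
        chain.append(h)
        h.used = True
    flush(chain)

    elements.sort(key=lambda e: (e.contig, e.start, e.end))
    return elements


def _best_ref_score(seq: str, refs: dict[str, str], params: AlignmentParams) -> int:
    best = 0
    for ref in refs.values():
        for aln in seeded_search(seq, ref, params):
            if aln.score > best:
                best = aln.score
    return best


def assign_ty1_ty2(
    element: TyElement,
    assembly: GenomeAssembly,
    panel: QueryPanel,
    params: AlignmentParams | None = None,
) -> tuple[str, int]:
    """Best-score family assignment of a Ty1/Ty2 coding element.

    The element's coding sequence is aligned against every characterized
    Ty1 and Ty2 reference; the family of the best score wins.  A zero
    margin keeps the lexicographically first family and flags the element
    as ambiguous.
    """
    params = params or AlignmentParams()
    if not panel.ty1_refs or not panel.ty2_refs:
        raise ValueError("Ty1/Ty2 assignment needs a non-empty reference set")
    seq = assembly[element.contig]
    if element.coding_intervals:
        lo = min(s for s, _ in element.coding_intervals.values())
        hi = max(e for _, e in element.coding_intervals.values())
    else:
        lo, hi = element.start, element.end
    coding_seq = seq[lo:hi]
    if not coding_seq:
        raise ValueError("element has no coding sequence to assign")
    s1 = _best_ref_score(coding_seq, panel.ty1_refs, params)
    s2 = _best_ref_score(coding_seq, panel.ty2_refs, params)
    if s1 > s2:
        family, margin = "Ty1", s1 - s2
    elif s2 > s1:
        family, margin = "Ty2", s2 - s1
    else:
        family, margin = "Ty1", 0
    element.family = family
    element.assignment_margin = margin
    element.ambiguous_family = margin == 0
    return family, margin


def _part_family(part_seq: str, ty1_part: str, ty2_part: str, params: AlignmentParams, use_global: bool = False) -> str:
    if use_global:
        s1 = global_score(part_seq, ty1_part, params)
        s2 = global_score(part_seq, ty2_part, params)
    else:
        s1 = smith_waterman(part_seq, ty1_part, params).score
        s2 = smith_waterman(part_seq, ty2_part, params).score
    return "Ty1" if s1 >= s2 else "Ty2"


def detect_hybrid(
    element: TyElement,
    assembly: GenomeAssembly,
    panel: QueryPanel,
    params: AlignmentParams | None = None,
) -> str:
    """Classify an element's Ty1/2 hybrid status from its parts.

    TYA, TYB and the terminal 240-nt LTR-U3 are each assigned to Ty1 or Ty2
    by best alignment score.  Ty1 TYA with Ty2 TYB and Ty2 U3 is a full
    hybrid; an otherwise pure Ty1 whose last 60 nt of TYB score Ty2 is a
    short hybrid.  When only a >=300-nt 3' segment is available and it
    scores Ty2, the element cannot be told apart from a real Ty2
    (``indistinguishable``).
    """
    params = params or AlignmentParams()
    if element.family not in ("Ty1", "Ty2"):
        element.hybrid_status = "none"
        return "none"
    seq = assembly[element.contig]

    def oriented(lo: int, hi: int) -> str:
        s = seq[max(0, lo):hi]
        return s if element.strand == "+" else reverse_complement(s)

    tya_iv = element.coding_intervals.get("tya")
    tyb_iv = element.coding_intervals.get("tyb")
    if tya_iv is None and tyb_iv is not None:
        if tyb_iv[1] - tyb_iv[0] >= 300:
            fam = _part_family(oriented(*tyb_iv), panel.tyb["Ty1"], panel.tyb["Ty2"], params)
            if fam == "Ty2":
                element.hybrid_status = "indistinguishable"
                return "indistinguishable"
        element.hybrid_status = "none"
        return "none"
    if tya_iv is None or tyb_iv is None:
        element.notes.append("hybrid check skipped: coding parts missing")
        element.hybrid_status = "none"
        return "none"

    tya_fam = _part_family(oriented(*tya_iv), panel.tya["Ty1"], panel.tya["Ty2"], params)
    tyb_fam = _part_family(oriented(*tyb_iv), panel.tyb["Ty1"], panel.tyb["Ty2"], params)

    # terminal U3 of the 3' LTR, in element orientation
    u3_fam = None
    three_prime = [h for h in element.ltr_hits if h.context == "coding_3prime"]
    if three_prime:
        ltr3_start = min(h.start for h in three_prime)
        ltr3_end = max(h.end for h in three_prime)
        if element.strand == "+":
            u3_seq = seq[max(0, ltr3_end - 240):ltr3_end]
        else:
            u3_seq = reverse_complement(seq[ltr3_start:ltr3_start + 240])
        u3_fam = _part_family(
            u3_seq, panel.ltr["Ty1"][-240:], panel.ltr["Ty2"][-240:], params
        )
        # the 60-nt TYB tail immediately interior to the 3' LTR
        if element.strand == "+":
            tail = seq[max(0, ltr3_start - 60):ltr3_start]
        else:
            tail = reverse_complement(seq[ltr3_end:ltr3_end + 60])
        tail_fam = _part_family(
            tail, panel.tyb["Ty1"][-60:], panel.tyb["Ty2"][-60:], params, use_global=True
        )
    else:
        tail_fam = None

    status = "none"
    if tya_fam == "Ty1" and tyb_fam == "Ty2" and u3_fam == "Ty2":
        status = "full_hybrid"
    elif tya_fam == "Ty1" and tyb_fam == "Ty1" and tail_fam == "Ty2":
        status = "short_hybrid"
    element.hybrid_status = status
    return status


def classify_strain(
    hits: list[LTRHit],
    assembly: GenomeAssembly,
    panel: QueryPanel,
    params: AlignmentParams | None = None,
) -> list[TyElement]:
    """Full stage-2 pass for one strain: context, Ty1/Ty2 identity, hybrids."""
    params = params or AlignmentParams()
    elements = classify_ltr_context(hits, assembly, panel, params)
    for el in elements:
        if el.family in ("Ty1", "Ty2") and el.coding_intervals:
            assign_ty1_ty2(el, assembly, panel, params)
        if el.category in ("full", "relic", "fragment") and el.family in ("Ty1", "Ty2"):
            detect_hybrid(el, assembly, panel, params)
        if not el.subfamily_label:
            el.subfamily_label = el.family
    return elements


def summarize_coding(elements_by_strain: dict[str, list[TyElement]]) -> pd.DataFrame:
    """Per-strain coding-LTR counts, relic counts and the Ty1/Ty2 ratio.

    ``ty1_ty2_ratio`` is the count of potentially active full Ty1 elements
    over full Ty2 elements; a zero denominator yields +inf with the
    ``ratio_flag`` column set to ``no_Ty2`` (``no_coding`` when both are
    absent) instead of a division error.  Relics are excluded from the
    active counts and listed separately.
    """
    rows = {}
    for strain, elements in elements_by_strain.items():
        row: dict[str, object] = {f"{f}_coding_ltrs": 0 for f in FAMILIES}
        row.update({f"{f}_full": 0 for f in FAMILIES})
        row["relics"] = 0
        row["fragments"] = 0
        for el in elements:
            if el.category == "full":
                n_coding = sum(
                    1 for h in el.ltr_hits if h.context in ("coding_5prime", "coding_3prime")
                )
                row[f"{el.family}_coding_ltrs"] += n_coding
                row[f"{el.family}_full"] += 1
            elif el.category == "relic":
                row["relics"] += 1
            elif el.category == "fragment":
                row["fragments"] += 1
        n1, n2 = row["Ty1_full"], row["Ty2_full"]
        if n1 == 0 and n2 == 0:
            row["ty1_ty2_ratio"] = float("nan")
            row["ratio_flag"] = "no_coding"
        elif n2 == 0:
            row["ty1_ty2_ratio"] = float("inf")
            row["ratio_flag"] = "no_Ty2"
        else:
            row["ty1_ty2_ratio"] = n1 / n2
            row["ratio_flag"] = ""
        rows[strain] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "strain"
    return table


def write_elements_gff3(elements: list[TyElement], path) -> None:
    """GFF3 with LTR_retrotransposon / solo_LTR parents and LTR children."""
    type_map = {
        "full": "LTR_retrotransposon",
        "relic": "LTR_retrotransposon",
        "fragment": "LTR_retrotransposon",
        "solo_ltr": "solo_LTR",
    }
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for n, el in enumerate(elements):
            eid = f"element{n:04d}"
            attrs = (
                f"ID={eid};family={el.family};category={el.category};"
                f"subfamily={el.subfamily_label};hybrid={el.hybrid_status}"
            )
            fh.write(
                f"{el.contig}\ttyscape\t{type_map[el.category]}\t{el.start + 1}"
                f"\t{el.end}\t.\t{el.strand}\t.\t{attrs}\n"
            )
            for k, h in enumerate(el.ltr_hits):
                fh.write(
                    f"{h.contig}\ttyscape\tlong_terminal_repeat\t{h.start + 1}"
                    f"\t{h.end}\t{h.score}\t{h.strand}\t.\t"
                    f"ID={eid}.ltr{k};Parent={eid};context={h.context}\n"
                )
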