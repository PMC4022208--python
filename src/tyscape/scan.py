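"""Stage 1: detect LTR copies of the five Ty families in an assembly.

Each family's LTR query is searched against every contig on both strands;
overlapping hits of different families are resolved to the best-scoring
family.  Per-strain, per-family counts summarize the LTR census.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentParams, SubjectIndex, seeded_search
from .genome import GenomeAssembly
from .synthetic import FAMILIES, TyTemplate

CONTEXTS = ("unassigned", "coding_5prime", "coding_3prime", "solo", "relic_adjacent")


@dataclass
class QueryPanel:
    """Family query sequences plus the Ty1/Ty2 reference set.

    The reference set holds characterized full-length elements (hybrids
    excluded) used for best-score family assignment.
    """

    ltr: dict[str, str]
    tya: dict[str, str]
    tyb: dict[str, str]
    ty1_refs: dict[str, str] = field(default_factory=dict)
    ty2_refs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f for f in FAMILIES if f not in self.ltr]
        if missing:
            raise ValueError(f"LTR query missing for families: {missing}")

    @classmethod
    def from_templates(cls, templates: dict[str, TyTemplate]) -> "QueryPanel":
        ltr = {f: templates[f].ltr for f in FAMILIES}
        tya = {f: templates[f].tya for f in FAMILIES}
        tyb = {f: templates[f].tyb for f in FAMILIES}
        ty1_refs = {
            key: tpl.full_sequence
            for key, tpl in templates.items()
            if tpl.family == "Ty1" and not key.startswith("hybrid")
        }
        ty2_refs = {
            key: tpl.full_sequence
            for key, tpl in templates.items()
            if tpl.family == "Ty2" and not key.startswith("hybrid")
        }
        return cls(ltr=ltr, tya=tya, tyb=tyb, ty1_refs=ty1_refs, ty2_refs=ty2_refs)

    @classmethod
    def from_fasta(cls, path) -> "QueryPanel":
        """Load a panel from FASTA with headers ``family|role|id``.

        Roles: LTR, TYA, TYB, REF (REF sequences join the family's
        reference set).
        """
        ltr: dict[str, str] = {}
        tya: dict[str, str] = {}
        tyb: dict[str, str] = {}
        ty1_refs: dict[str, str] = {}
        ty2_refs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 3:
                raise ValueError(f"panel header {rec.id!r} is not family|role|id")
            family, role, qid = parts
            seq = str(rec.seq).upper()
            if role == "LTR":
                ltr[family] = seq
            elif role == "TYA":
                tya[family] = seq
            elif role == "TYB":
                tyb[family] = seq
            elif role == "REF":
                (ty1_refs if family == "Ty1" else ty2_refs)[qid] = seq
            else:
                raise ValueError(f"unknown panel role {role!r}")
        return cls(ltr=ltr, tya=tya, tyb=tyb, ty1_refs=ty1_refs, ty2_refs=ty2_refs)

    def to_fasta(self, path) -> None:
        records = []
        for family in FAMILIES:
            for role, mapping in (("LTR", self.ltr), ("TYA", self.tya), ("TYB", self.tyb)):
                if family in mapping:
                    records.append(
                        SeqRecord(Seq(mapping[family]), id=f"{family}|{role}|q1", description="")
                    )
        for qid, seq in self.ty1_refs.items():
            records.append(SeqRecord(Seq(seq), id=f"Ty1|REF|{qid}", description=""))
        for qid, seq in self.ty2_refs.items():
            records.append(SeqRecord(Seq(seq), id=f"Ty2|REF|{qid}", description=""))
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")


@dataclass
class LTRHit:
    """One detected LTR copy."""

    strain: str
    contig: str
    start: int
    end: int
    strand: str
    family: str
    score: int
    identity: float
    context: str = "unassigned"
    ambiguous_family: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlap(self, other: "LTRHit") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _resolve_cross_family(hits: list[LTRHit]) -> list[LTRHit]:
    """Where hits of different families overlap >= 50%, keep the best score.

    Ties keep the lexicographically smallest family name and are flagged.
    """
    hits = sorted(hits, key=lambda h: (h.contig, h.start, h.end, h.family))
    dropped = [False] * len(hits)
    for i in range(len(hits)):
        if dropped[i]:
            continue
        for j in range(i + 1, len(hits)):
            if dropped[j]:
                continue
            a, b = hits[i], hits[j]
            if b.contig != a.contig or b.start >= a.end:
                break
            if a.family == b.family:
                continue
            ov = a.overlap(b)
            if ov * 2 >= min(a.end - a.start, b.end - b.start):
                if a.score > b.score:
                    dropped[j] = True
                elif b.score > a.score:
                    dropped[i] = True
                    break
                else:
                    keep, drop = (i, j) if a.family < b.family else (j, i)
                    hits[keep].ambiguous_family = True
                    dropped[drop] = True
                    if drop == i:
                        break
    return [h for h, d in zip(hits, dropped) if not d]


def scan_ltrs(
    assembly: GenomeAssembly,
    panel: QueryPanel,
    params: AlignmentParams | None = None,
    keep_fragments: bool = False,
) -> list[LTRHit] | tuple[list[LTRHit], list[LTRHit]]:
    """Detect all LTR copies in an assembly.

    Hits shorter than ``params.min_length`` are dropped from counts; pass
    ``keep_fragments=True`` to also receive them as a side table.
    """
    params = params or AlignmentParams()
    if len(assembly) == 0:
        raise ValueError(f"assembly {assembly.strain!r} has no contigs")
    hits: list[LTRHit] = []
    fragments: list[LTRHit] = []
    frag_params = AlignmentParams(
        **{
            **params.__dict__,
            "min_length": max(20, params.seed_length * 2),
            "min_score": min(params.min_score, 25),
        }
    ) if keep_fragments else None
    for contig, seq in assembly.contigs.items():
        index = SubjectIndex(seq, params.seed_length)
        for family in FAMILIES:
            use = frag_params if keep_fragments else params
            for aln in seeded_search(panel.ltr[family], index, use, query_id=family, subject_id=contig):
                hit = LTRHit(
                    strain=assembly.strain, contig=contig,
                    start=aln.subject_start, end=aln.subject_end,
                    strand=aln.strand, family=family,
                    score=aln.score, identity=aln.identity,
                )
                if (
                    aln.aligned_length >= params.min_length
                    and aln.score >= params.min_score
                ):
                    hits.append(hit)
                else:
                    fragments.append(hit)
    hits = _resolve_cross_family(hits)
    hits.sort(key=lambda h: (h.contig, h.start, h.end))
    if keep_fragments:
        fragments.sort(key=lambda h: (h.contig, h.start, h.end))
        return hits, fragments
    return hits


def count_by_family(hits_by_strain: dict[str, list[LTRHit]]) -> pd.DataFrame:
    """Strains x families LTR count table with a total column."""
    rows = {}
    for strain, hits in hits_by_strain.items():
        counts = {f: 0 for f in FAMILIES}
        for h in hits:
            counts[h.family] += 1
        counts["total"] = sum(counts.values())
        rows[strain] = counts
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "strain"
    return table[list(FAMILIES) + ["total"]]


def write_hits_bed(hits: list[LTRHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\t{h.family}:{h.strain}:{h.context}"
                f"\t{h.score}\t{h.strand}\n"
            )
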