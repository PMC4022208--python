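"""Stage 3: anchor insertions onto a reference and build the insertion atlas.

Every detected element's 2,500-nt flanks are masked for Ty-related sequence
and mapped back to a reference genome; the element-side flank end gives the
insertion junction.  Junctions of the same family within a small window merge
into loci, yielding per-family presence/absence matrices, occupancy spectra,
Pol III (tRNA gene) proximity and hierarchical strain clusterings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .align import AlignmentParams, SubjectIndex, mask_regions, seeded_search
from .classify import TyElement
from .genome import GenomeAssembly, GenomeFeature
from .scan import FAMILIES, QueryPanel

FLANK_LEN = 2500
LOCUS_WINDOW = 40  # covers target-site duplication plus mapping jitter
POLIII_WINDOW = 1000
MAP_MARGIN = 30  # best-vs-second score margin for a unique placement
ANCHOR_SLACK = 50  # element-side alignment end must reach this close to the junction
MIN_FLANK = 200


@dataclass
class Flank:
    sequence: str
    side: str  # "left" | "right" (assembly orientation)
    truncated: bool


def extract_flanks(
    element: TyElement, assembly: GenomeAssembly, flank_len: int = FLANK_LEN
) -> tuple[Flank, Flank]:
    """Up to ``flank_len`` nt on each side of the element, truncation flagged."""
    seq = assembly[element.contig]
    lo = max(0, element.start - flank_len)
    hi = min(len(seq), element.end + flank_len)
    left = Flank(seq[lo:element.start], "left", element.start - lo < flank_len)
    right = Flank(seq[element.end:hi], "right", hi - element.end < flank_len)
    return left, right


@dataclass
class MapResult:
    status: str  # "unique" | "ambiguous" | "unmapped"
    contig: str | None = None
    position: int | None = None
    strand: str | None = None


def _mask_ty(flank: str, panel: QueryPanel, params: AlignmentParams) -> str:
    """Mask any panel similarity inside a flank (aggressive thresholds)."""
    mask_params = replace_params(params, min_length=30, min_score=25, min_identity=0.6)
    intervals = []
    queries = []
    for family in FAMILIES:
        for mapping in (panel.ltr, panel.tya, panel.tyb):
            if family in mapping:
                queries.append(mapping[family])
    for q in queries:
        for aln in seeded_search(q, flank, mask_params):
            intervals.append(aln.subject_interval)
    return mask_regions(flank, intervals)


def replace_params(params: AlignmentParams, **kw) -> AlignmentParams:
    return AlignmentParams(**{**params.__dict__, **kw})


def mask_and_map(
    flank: Flank,
    panel: QueryPanel,
    reference: GenomeAssembly,
    params: AlignmentParams | None = None,
    margin: int = MAP_MARGIN,
) -> MapResult:
    """Mask Ty sequence in a flank and place it uniquely on the reference.

    The placement is unique when the best element-side-anchored alignment
    beats the runner-up by ``margin`` and covers at least half of the
    unmasked flank bases; the reported position is the reference coordinate
    of the element-side flank end (the insertion junction).
    """
    params = params or AlignmentParams()
    masked = _mask_ty(flank.sequence, panel, params)
    n_unmasked = sum(1 for c in masked if c != "N")
    if n_unmasked < MIN_FLANK:
        return MapResult("unmapped")
    L = len(masked)
    anchored = []
    if isinstance(reference, dict):  # pre-built contig -> SubjectIndex
        contig_iter = reference.items()
    else:
        contig_iter = (
            (name, SubjectIndex(seq, params.seed_length))
            for name, seq in reference.contigs.items()
        )
    for contig, seq in contig_iter:
        for aln in seeded_search(masked, seq, params, subject_id=contig):
            if flank.side == "left":
                if aln.query_end < L - ANCHOR_SLACK:
                    continue
                pos = (
                    aln.subject_end + (L - aln.query_end)
                    if aln.strand == "+"
                    else aln.subject_start - (L - aln.query_end)
                )
            else:
                if aln.query_start > ANCHOR_SLACK:
                    continue
                pos = (
                    aln.subject_start - aln.query_start
                    if aln.strand == "+"
                    else aln.subject_end + aln.query_start
                )
            anchored.append((aln.score, contig, pos, aln.strand, aln))
    if not anchored:
        return MapResult("unmapped")
    anchored.sort(key=lambda t: -t[0])
    best = anchored[0]
    if len(anchored) > 1 and best[0] - anchored[1][0] < margin:
        return MapResult("ambiguous")
    aln = best[4]
    if (aln.query_end - aln.query_start) < 0.5 * n_unmasked:
        return MapResult("ambiguous")
    return MapResult("unique", best[1], int(best[2]), best[3])


@dataclass
class MappedInsertion:
    strain: str
    family: str
    contig: str
    position: int
    is_coding: bool
    category: str
    element_id: str


CODING_CATEGORIES = ("full", "relic", "fragment")


def map_elements(
    elements: list[TyElement],
    assembly: GenomeAssembly,
    panel: QueryPanel,
    reference: GenomeAssembly,
    params: AlignmentParams | None = None,
    flank_len: int = FLANK_LEN,
    margin: int = MAP_MARGIN,
) -> tuple[list[MappedInsertion], dict[str, int]]:
    """Map one strain's elements; falls back to the right flank when the
    left one is masked away, truncated or ambiguous."""
    params = params or AlignmentParams()
    mapped: list[MappedInsertion] = []
    tally = {"unique": 0, "ambiguous": 0, "unmapped": 0}
    indexes = {
        name: SubjectIndex(seq, params.seed_length)
        for name, seq in reference.contigs.items()
    }
    for el in elements:
        left, right = extract_flanks(el, assembly, flank_len)
        result = MapResult("unmapped")
        for flank in (left, right):
            if len(flank.sequence) < MIN_FLANK:
                continue
            result = mask_and_map(flank, panel, indexes, params, margin)
            if result.status == "unique":
                break
        tally[result.status] += 1
        if result.status == "unique":
            mapped.append(
                MappedInsertion(
                    strain=el.strain, family=el.family, contig=result.contig,
                    position=result.position, is_coding=el.category in CODING_CATEGORIES,
                    category=el.category, element_id=el.element_id,
                )
            )
    return mapped, tally


@dataclass
class InsertionLocus:
    locus_id: str
    family: str
    contig: str
    position: int  # median junction
    window: tuple[int, int]
    occupancy: set[str] = field(default_factory=set)
    coding_occupancy: set[str] = field(default_factory=set)
    members: list[MappedInsertion] = field(default_factory=list)
    near_polIII: bool = False


def cluster_loci(
    mapped: list[MappedInsertion], window: int = LOCUS_WINDOW
) -> list[InsertionLocus]:
    """Single-linkage merge of same-family junctions within ``window`` nt."""
    loci: list[InsertionLocus] = []
    by_key: dict[tuple[str, str], list[MappedInsertion]] = {}
    for m in mapped:
        by_key.setdefault((m.family, m.contig), []).append(m)
    counter = 0
    for (family, contig) in sorted(by_key):
        group = sorted(by_key[(family, contig)], key=lambda m: (m.position, m.strain))
        chain: list[MappedInsertion] = []
        for m in group:
            if chain and m.position - chain[-1].position > window:
                loci.append(_finish_locus(chain, family, contig, counter))
                counter += 1
                chain = []
            chain.append(m)
        if chain:
            loci.append(_finish_locus(chain, family, contig, counter))
            counter += 1
    return loci


def _finish_locus(
    members: list[MappedInsertion], family: str, contig: str, idx: int
) -> InsertionLocus:
    positions = sorted(m.position for m in members)
    median = positions[len(positions) // 2]
    locus = InsertionLocus(
        locus_id=f"{family}_{contig}_{idx:04d}",
        family=family, contig=contig, position=median,
        window=(positions[0], positions[-1] + 1),
        members=list(members),
    )
    for m in members:
        locus.occupancy.add(m.strain)
        if m.is_coding:
            locus.coding_occupancy.add(m.strain)
    return locus


def presence_absence_matrix(
    loci: list[InsertionLocus], strains: list[str], family: str,
    coding_only: bool = False,
) -> pd.DataFrame:
    """Strains x loci boolean occupancy table for one family."""
    fam_loci = [l for l in loci if l.family == family]
    mat = pd.DataFrame(False, index=list(strains), columns=[l.locus_id for l in fam_loci])
    for l in fam_loci:
        occupants = l.coding_occupancy if coding_only else l.occupancy
        for s in occupants:
            if s in mat.index:
                mat.loc[s, l.locus_id] = True
    return mat


def occupancy_spectrum(matrix: pd.DataFrame, mode: str = "insertions") -> pd.Series:
    """Distribution of insertions (or loci) over locus occupancy 1..n_strains.

    ``insertions`` weights each occupancy class by the number of insertion
    events it holds, normalized by the total number of insertions, so the
    spectrum sums to 1.  ``loci`` normalizes plain locus counts instead.
    """
    if matrix.shape[1] == 0:
        raise ValueError("empty presence/absence matrix")
    occ = matrix.sum(axis=0).astype(int)
    n_strains = matrix.shape[0]
    spectrum = pd.Series(0.0, index=range(1, n_strains + 1))
    counts = occ.value_counts()
    for k, n_loci in counts.items():
        if k == 0:
            continue
        spectrum.loc[k] = k * n_loci if mode == "insertions" else n_loci
    total = occ.sum() if mode == "insertions" else (occ > 0).sum()
    return spectrum / total


def polIII_proximity(
    loci: list[InsertionLocus],
    annotation: list[GenomeFeature],
    window: int = POLIII_WINDOW,
) -> float:
    """Fraction of loci whose window lies within ``window`` nt of a Pol III
    gene; also sets each locus's ``near_polIII`` flag."""
    if not loci:
        return 0.0
    near = 0
    for locus in loci:
        flag = any(
            g.contig == locus.contig
            and locus.window[0] - window <= g.end
            and g.start <= locus.window[1] + window
            for g in annotation
        )
        locus.near_polIII = flag
        near += flag
    return near / len(loci)


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(idx: int) -> str:
        if idx < n:
            return labels[idx]
        row = link[idx - n]
        a, b = int(row[0]), int(row[1])
        h = float(row[2])
        return (
            f"({render(a)}:{max(0.0, h - heights[a]):.6f},"
            f"{render(b)}:{max(0.0, h - heights[b]):.6f})"
        )

    for i, row in enumerate(link):
        heights[n + i] = float(row[2])
    return render(n + len(link) - 1) + ";"


def cluster_strains(matrix: pd.DataFrame) -> tuple[str, list[str], list[str]]:
    """Average-linkage Jaccard clustering of strains (rows) and loci (columns).

    Returns (strain dendrogram as Newick with heights, strain order, locus
    order).  Degenerate identical rows merge at height 0.
    """
    if matrix.shape[0] < 2:
        raise ValueError("strain clustering needs at least 2 strains")
    rows = matrix.to_numpy(dtype=bool)
    d = pdist(rows, metric="jaccard")
    d = np.nan_to_num(d, nan=0.0)  # two all-zero rows are identical profiles
    link = hierarchy.linkage(d, method="average")
    strain_order = [matrix.index[i] for i in hierarchy.leaves_list(link)]
    newick = _linkage_to_newick(link, list(matrix.index))
    if matrix.shape[1] >= 2:
        dc = np.nan_to_num(pdist(rows.T, metric="jaccard"), nan=0.0)
        clink = hierarchy.linkage(dc, method="average")
        locus_order = [matrix.columns[i] for i in hierarchy.leaves_list(clink)]
    else:
        locus_order = list(matrix.columns)
    return newick, strain_order, locus_order


def write_loci_bed(loci: list[InsertionLocus], path) -> None:
    ordered = sorted(loci, key=lambda l: (l.contig, l.position, l.family))
    with open(path, "w") as fh:
        for l in ordered:
            fh.write(
                f"{l.contig}\t{l.window[0]}\t{l.window[1]}\t"
                f"{l.family}:{l.locus_id}\t{len(l.occupancy)}\t+\n"
            )
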