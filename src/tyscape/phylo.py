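"""Stage 4: TYA300/TYB300 segments, HKY85 distances, NJ trees, subfamilies.

The 300-nt coding segments immediately interior to the 5' and 3' LTRs are
the best-assembled, most discriminating parts of Ty1/Ty2 coding elements.
They are extracted strand-normalized, aligned progressively, compared under
the HKY85 substitution model (computed through the Tamura-Nei closed form
with its equal-transition-rate constraint), and clustered with neighbor
joining.  Subfamily labels come from nearest-exemplar identity; segments
below the identity threshold to every exemplar found novel clusters, and
TYB300 segments with a Ty1 body but a Ty2 60-nt tail are called short
hybrids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import nw_profile
from .align import AlignmentParams, global_identity, reverse_complement
from .classify import TyElement
from .genome import GenomeAssembly
from .scan import QueryPanel

SEGMENT_LEN = 300
SUBFAMILY_IDENTITY = 0.95
SHORT_HYBRID_TAIL = 60


@dataclass(frozen=True)
class Segment:
    segment_id: str
    strain: str
    kind: str  # "TYA300" | "TYB300"
    sequence: str


@dataclass
class SegmentSet:
    segments: list[Segment]
    skipped: list[str] = None

    def __post_init__(self):
        if self.skipped is None:
            self.skipped = []

    def of_kind(self, kind: str) -> dict[str, str]:
        return {s.segment_id: s.sequence for s in self.segments if s.kind == kind}


def extract_segments(
    elements: list[TyElement],
    assembly: GenomeAssembly,
    segment_len: int = SEGMENT_LEN,
) -> SegmentSet:
    """TYA300/TYB300 segments from located elements, strand-normalized.

    TYA300 starts immediately interior to the 5' LTR; TYB300 ends
    immediately interior to the 3' LTR.  Relics (no 3' LTR) yield TYA300
    only; elements whose coding region is shorter than the segment are
    skipped and logged.
    """
    segments: list[Segment] = []
    skipped: list[str] = []
    for el in elements:
        if el.category not in ("full", "relic"):
            continue
        seq = assembly[el.contig]
        five = [h for h in el.ltr_hits if h.context in ("coding_5prime", "relic_adjacent")]
        three = [h for h in el.ltr_hits if h.context == "coding_3prime"]
        coding_span = 0
        if el.coding_intervals:
            coding_span = max(e for _, e in el.coding_intervals.values()) - min(
                s for s, _ in el.coding_intervals.values()
            )
        if coding_span < segment_len:
            skipped.append(f"{el.element_id}: coding region shorter than {segment_len} nt")
            continue
        if five:
            if el.strand == "+":
                edge = max(h.end for h in five)
                tya300 = seq[edge : edge + segment_len]
            else:
                edge = min(h.start for h in five)
                tya300 = reverse_complement(seq[max(0, edge - segment_len) : edge])
            if len(tya300) == segment_len:
                segments.append(Segment(f"{el.element_id}|TYA300", el.strain, "TYA300", tya300))
            else:
                skipped.append(f"{el.element_id}: TYA300 truncated")
        if three and "tyb" in el.coding_intervals:
            if el.strand == "+":
                edge = min(h.start for h in three)
                tyb300 = seq[max(0, edge - segment_len) : edge]
            else:
                edge = max(h.end for h in three)
                tyb300 = reverse_complement(seq[edge : edge + segment_len])
            if len(tyb300) == segment_len:
                segments.append(Segment(f"{el.element_id}|TYB300", el.strain, "TYB300", tyb300))
            else:
                skipped.append(f"{el.element_id}: TYB300 truncated")
    return SegmentSet(segments=segments, skipped=skipped)


# ---------------------------------------------------------------------------
# progressive multiple alignment

_SYM = {c: i for i, c in enumerate("ACGT-N")}
# column-score matrix: +1 identical bases, -1 mismatching bases, 0 vs gap/N
_SCORE = np.zeros((6, 6))
_SCORE[:4, :4] = -1.0
np.fill_diagonal(_SCORE[:4, :4], 1.0)

_GAP_OPEN = 2.0
_GAP_EXT = 1.0


def _profile(rows: list[str]) -> np.ndarray:
    length = len(rows[0])
    prof = np.zeros((length, 6))
    for row in rows:
        for i, c in enumerate(row):
            prof[i, _SYM.get(c, 5)] += 1.0
    return prof / len(rows)


def _merge(rows_a: dict[str, str], rows_b: dict[str, str]) -> dict[str, str]:
    pa = _profile(list(rows_a.values()))
    pb = _profile(list(rows_b.values()))
    S = pa @ _SCORE @ pb.T
    ops = nw_profile(S, _GAP_OPEN, _GAP_EXT)
    out: dict[str, list[str]] = {k: [] for k in list(rows_a) + list(rows_b)}
    i = j = 0
    for op in ops:
        if op == 0:
            for k, row in rows_a.items():
                out[k].append(row[i])
            for k, row in rows_b.items():
                out[k].append(row[j])
            i += 1
            j += 1
        elif op == 1:  # consume a column of b; gap in a's rows
            for k in rows_a:
                out[k].append("-")
            for k, row in rows_b.items():
                out[k].append(row[j])
            j += 1
        else:
            for k, row in rows_a.items():
                out[k].append(row[i])
            for k in rows_b:
                out[k].append("-")
            i += 1
    return {k: "".join(v) for k, v in out.items()}


def _kmer_distance(a: str, b: str, k: int = 6) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def align_segments(seqs: dict[str, str]) -> dict[str, str]:
    """Progressive multiple alignment ("once a gap, always a gap").

    The guide tree is UPGMA on k-mer distances; each progressive step is a
    global affine profile-profile alignment.  Deterministic: labels are
    processed in sorted order.
    """
    labels = sorted(seqs)
    if len(labels) == 0:
        return {}
    if len(labels) == 1:
        return {labels[0]: seqs[labels[0]]}
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(seqs[labels[i]], seqs[labels[j]])
    link = hierarchy.linkage(squareform(dm, checks=False), method="average")
    clusters: dict[int, dict[str, str]] = {
        i: {labels[i]: seqs[labels[i]]} for i in range(n)
    }
    for idx, row in enumerate(link):
        a, b = int(row[0]), int(row[1])
        clusters[n + idx] = _merge(clusters.pop(a), clusters.pop(b))
    final = clusters[n + len(link) - 1]
    return {k: final[k] for k in labels}


# ---------------------------------------------------------------------------
# HKY85 distances (Tamura-Nei closed form, equal transition rates)


def hky85_distance(a: str, b: str) -> float:
    """Pairwise substitutions/site under HKY85 between two aligned rows.

    Columns with a gap or N in either row are excluded (pairwise deletion);
    base frequencies are pooled empirically from the pair.  Saturation
    (a non-positive logarithm argument) returns +inf.
    """
    pairs = [
        (x, y)
        for x, y in zip(a, b)
        if x in "ACGT" and y in "ACGT"
    ]
    if not pairs:
        raise ValueError("no comparable columns between rows")
    n = len(pairs)
    counts = {c: 0 for c in "ACGT"}
    p1 = p2 = q = 0
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
        if x != y:
            pair = {x, y}
            if pair == {"A", "G"}:
                p1 += 1
            elif pair == {"C", "T"}:
                p2 += 1
            else:
                q += 1
    total = 2 * n
    gA, gC, gG, gT = (counts[c] / total for c in "ACGT")
    gR = gA + gG
    gY = gC + gT
    P1, P2, Q = p1 / n, p2 / n, q / n
    if gR == 0 or gY == 0:
        return math.inf if (P1 or P2 or Q) else 0.0
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    dist = 0.0
    for kx, wx in (
        (k1, 1 - (P1 / k1 if k1 > 0 else 0.0) - Q / (2 * gR)),
        (k2, 1 - (P2 / k2 if k2 > 0 else 0.0) - Q / (2 * gY)),
        (k3, 1 - Q / (2 * gR * gY)),
    ):
        if kx <= 0:
            continue
        if wx <= 0:
            return math.inf
        dist -= kx * math.log(wx)
    return dist


def distance_matrix(aligned: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Symmetric zero-diagonal HKY85 distance matrix over aligned rows."""
    labels = sorted(aligned)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hky85_distance(aligned[labels[i]], aligned[labels[j]])
    return labels, d


# ---------------------------------------------------------------------------
# neighbor joining


def _fmt(x: float) -> str:
    return f"{x:.9f}".rstrip("0").rstrip(".") or "0"


def nj_tree(labels: list[str], d: np.ndarray) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick tree.

    Tying Q-criterion pairs join the lexicographically smallest pair;
    negative branch lengths are clamped to 0 with the deficit moved to the
    sister branch.  Infinite distances are rejected by name.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(d)):
        i, j = np.argwhere(~np.isfinite(d))[0]
        raise ValueError(f"non-finite distance between {labels[i]!r} and {labels[j]!r}")
    # active nodes: newick fragment, representative (smallest leaf) for ties
    nodes = [(lab, lab) for lab in labels]
    D = d.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qv = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((nodes[i][1], nodes[j][1])))
                cand = (qv, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_newick = f"({nodes[i][0]}:{_fmt(li)},{nodes[j][0]}:{_fmt(lj)})"
        new_rep = min(nodes[i][1], nodes[j][1])
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append((new_newick, new_rep))
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    lengths = [li, lj, lk]
    for a in range(3):
        if lengths[a] < 0:
            deficit = lengths[a]
            lengths[a] = 0.0
            others = [b for b in range(3) if b != a]
            # move the deficit to the longer sister branch
            t = max(others, key=lambda b: lengths[b])
            lengths[t] += deficit
    return (
        f"({nodes[i][0]}:{_fmt(lengths[0])},{nodes[j][0]}:{_fmt(lengths[1])},"
        f"{nodes[k][0]}:{_fmt(lengths[2])});"
    )


# ---------------------------------------------------------------------------
# subfamily calling


def exemplars_from_panel(panel: QueryPanel, kind: str, segment_len: int = SEGMENT_LEN) -> dict[str, str]:
    """Family exemplar segments taken from the query panel templates."""
    out = {}
    source = panel.tya if kind == "TYA300" else panel.tyb
    for family, seq in sorted(source.items()):
        out[family] = seq[:segment_len] if kind == "TYA300" else seq[-segment_len:]
    return out


def call_subfamilies(
    segment_set: SegmentSet,
    exemplars_tya: dict[str, str],
    exemplars_tyb: dict[str, str],
    threshold: float = SUBFAMILY_IDENTITY,
    params: AlignmentParams | None = None,
) -> pd.DataFrame:
    """Label each segment by nearest exemplar identity; open novel clusters.

    TYB300 segments whose first 240 nt assign to Ty1 while the final 60 nt
    assign to Ty2 are called ``short_hybrid`` before exemplar matching.
    Segments below the identity threshold to every exemplar are clustered
    among themselves by single linkage at the same threshold and labeled
    ``novel1``, ``novel2``, ...
    """
    params = params or AlignmentParams()
    if not exemplars_tya and not exemplars_tyb:
        raise ValueError("empty exemplar set")
    rows = []
    novel: list[Segment] = []
    for seg in sorted(segment_set.segments, key=lambda s: s.segment_id):
        exemplars = exemplars_tya if seg.kind == "TYA300" else exemplars_tyb
        label = None
        if (
            seg.kind == "TYB300"
            and "Ty1" in exemplars
            and "Ty2" in exemplars
        ):
            head = seg.sequence[:-SHORT_HYBRID_TAIL]
            tail = seg.sequence[-SHORT_HYBRID_TAIL:]
            head_fam = max(
                ("Ty1", "Ty2"),
                key=lambda f: global_identity(head, exemplars[f][:-SHORT_HYBRID_TAIL], params),
            )
            tail_fam = max(
                ("Ty1", "Ty2"),
                key=lambda f: global_identity(tail, exemplars[f][-SHORT_HYBRID_TAIL:], params),
            )
            if head_fam == "Ty1" and tail_fam == "Ty2":
                label = "short_hybrid"
        best_label = None
        best_ident = -1.0
        for name, ex in exemplars.items():
            ident = global_identity(seg.sequence, ex, params)
            if ident > best_ident:
                best_ident = ident
                best_label = name
        if label is None:
            if best_ident >= threshold:
                label = best_label
            else:
                label = "__novel__"
                novel.append(seg)
        rows.append(
            dict(
                segment_id=seg.segment_id, strain=seg.strain, kind=seg.kind,
                label=label, nearest=best_label, identity=round(best_ident, 4),
            )
        )
    # single-linkage clustering of novel segments at the same threshold
    if novel:
        parent = {s.segment_id: s.segment_id for s in novel}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(novel)):
            for j in range(i + 1, len(novel)):
                if novel[i].kind != novel[j].kind:
                    continue
                if global_identity(novel[i].sequence, novel[j].sequence, params) >= threshold:
                    parent[find(novel[i].segment_id)] = find(novel[j].segment_id)
        roots: dict[str, str] = {}
        for s in novel:
            root = find(s.segment_id)
            if root not in roots:
                roots[root] = f"novel{len(roots) + 1}"
        for row in rows:
            if row["label"] == "__novel__":
                row["label"] = roots[find(row["segment_id"])]
    return pd.DataFrame(rows)
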