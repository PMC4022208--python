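"""Local-alignment engine used by every detection stage.

Two routes to the same answer: :func:`smith_waterman` is the exact affine-gap
dynamic program; :func:`seeded_search` is a megablast-style seed-and-extend
heuristic (exact k-mer seeding, x-drop prefilter, banded DP around the seed
diagonals) suitable for megabase subjects.  Whenever the true alignment
contains at least one exact seed word, the seeded route reports the same
score as the exact DP.

N and lowercase (soft-masked) bases are unmatchable: they score as mismatches
and are excluded from both the numerator and the denominator of identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import sw_banded, sw_full, ungapped_extend

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# extra diagonals allowed around a seed cluster when running banded DP
BAND_PAD = 32
# subject-coordinate slack added around a seed cluster window
WINDOW_PAD = 64
# ungapped-extension score a seed cluster must reach before banded DP is run
PREFILTER_CAP = 25
# hits closer than this many nt (same query, same strand) are merged
MERGE_GAP = 20


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (A0 C1 G2 T3, other/lower = 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and reporting parameters for the alignment engine.

    Defaults are megablast-like (+1/-1) so that ~90%-identity homologs are
    found while cross-family noise stays below the reporting thresholds.
    A gap of length L costs ``gap_open + L * gap_extend``.
    """

    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = 2
    gap_extend: int = 1
    seed_length: int = 11
    x_drop: int = 20
    min_score: int = 30
    min_identity: float = 0.70
    min_length: int = 80

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.mismatch_score >= 0:
            raise ValueError("mismatch_score must be negative")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("need gap_open >= gap_extend >= 0")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must lie in [0, 1]")
        if self.seed_length < 8:
            raise ValueError("seed_length must be >= 8")


@dataclass
class LocalAlignment:
    """A located local alignment of a query against a subject."""

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str  # strand of subject relative to query
    score: int
    identity: float
    aligned_length: int

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def subject_interval(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)

    @property
    def is_empty(self) -> bool:
        return self.score == 0 and self.aligned_length == 0


def _identity(matches: int, cols: int, ncols: int) -> float:
    comparable = cols - ncols
    return matches / comparable if comparable > 0 else 0.0


def smith_waterman(
    a: str, b: str, params: AlignmentParams | None = None,
    query_id: str = "query", subject_id: str = "subject",
) -> LocalAlignment:
    """Exact maximal-score local alignment of *a* against *b* (affine gaps).

    A score of 0 (no positive-scoring cell) yields the empty-alignment
    sentinel: zero-length intervals at the origin.
    """
    params = params or AlignmentParams()
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    score, a0, a1, b0, b1, matches, cols, ncols = sw_full(
        encode(a), encode(b),
        params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend,
    )
    if score <= 0:
        return LocalAlignment(query_id, subject_id, 0, 0, 0, 0, "+", 0, 0.0, 0)
    return LocalAlignment(
        query_id, subject_id, a0, a1, b0, b1, "+",
        int(score), _identity(matches, cols, ncols), int(cols),
    )


def mask_regions(seq: str, intervals) -> str:
    """Replace the given half-open intervals with 'N'; idempotent."""
    if not intervals:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = len(seq)
    for start, end in intervals:
        if start < 0 or end > n or end < start:
            raise ValueError(f"interval [{start}, {end}) out of bounds for length {n}")
        arr[start:end] = ord("N")
    return arr.tobytes().decode("ascii")


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes and a validity mask (no unmatchable base)."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, np.int64), np.empty(0, bool)
    m = n - k + 1
    h = np.zeros(m, np.int64)
    valid = np.ones(m, bool)
    for i in range(k):
        c = codes[i : i + m]
        h = h * 4 + np.where(c < 4, c, 0)
        valid &= c < 4
    return h, valid


class SubjectIndex:
    """Precomputed k-mer index of a subject sequence, reusable across queries."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        self.codes = encode(seq)
        h, v = _kmer_hashes(self.codes, k)
        self.hashes = np.where(v, h, np.int64(-1))


def _collect_seeds(q_codes: np.ndarray, subject: SubjectIndex):
    """(qpos, spos) pairs of exact k-mer matches between query and subject."""
    qh, qv = _kmer_hashes(q_codes, subject.k)
    sh = subject.hashes
    if qh.size == 0 or sh.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    lookup: dict[int, list[int]] = {}
    for pos in np.nonzero(qv)[0]:
        lookup.setdefault(int(qh[pos]), []).append(int(pos))
    uniq = np.fromiter(lookup.keys(), dtype=np.int64, count=len(lookup))
    cand = np.nonzero(np.isin(sh, uniq))[0]
    qpos_out: list[int] = []
    spos_out: list[int] = []
    for spos in cand:
        for qpos in lookup[int(sh[spos])]:
            qpos_out.append(qpos)
            spos_out.append(int(spos))
    return np.asarray(qpos_out, np.int64), np.asarray(spos_out, np.int64)


def _cluster_seeds(qpos: np.ndarray, spos: np.ndarray, qlen: int):
    """Group seeds into candidate regions by diagonal band and subject gap."""
    diag = spos - qpos
    order = np.lexsort((spos, diag))
    clusters = []
    cur: list[int] = []
    max_gap = max(200, qlen)
    for idx in order:
        if cur:
            prev = cur[-1]
            if diag[idx] - diag[prev] > BAND_PAD or (
                diag[idx] == diag[prev] and spos[idx] - spos[prev] > max_gap
            ):
                clusters.append(cur)
                cur = []
            elif diag[idx] != diag[prev] and abs(spos[idx] - spos[prev]) > max_gap:
                clusters.append(cur)
                cur = []
        cur.append(int(idx))
    if cur:
        clusters.append(cur)
    return diag, clusters


def _align_cluster(q_codes, s_codes, qpos, spos, diag, members, params):
    """Run banded DP over one seed cluster; returns kernel tuple or None."""
    dmin = int(min(diag[i] for i in members))
    dmax = int(max(diag[i] for i in members))
    smin = int(min(spos[i] for i in members))
    smax = int(max(spos[i] for i in members))
    qlen = q_codes.shape[0]
    qmin = int(min(qpos[i] for i in members))
    qmax = int(max(qpos[i] for i in members))
    wstart = max(0, smin - qmin - WINDOW_PAD)
    wend = min(s_codes.shape[0], smax + params.seed_length + (qlen - qmax) + WINDOW_PAD)
    window = s_codes[wstart:wend]
    dlo = dmin - wstart - BAND_PAD
    dhi = dmax - wstart + BAND_PAD
    dlo = max(dlo, -(qlen - 1))
    dhi = min(dhi, window.shape[0] - 1)
    if dhi < dlo:
        return None
    res = sw_banded(
        q_codes, window, dlo, dhi,
        params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend,
    )
    score, a0, a1, b0, b1, matches, cols, ncols = res
    if score <= 0:
        return None
    return score, a0, a1, wstart + b0, wstart + b1, matches, cols, ncols


def _passes(params: AlignmentParams, score, identity, cols) -> bool:
    return (
        score >= params.min_score
        and identity >= params.min_identity
        and cols >= params.min_length
    )


def seeded_search(
    query: str, subject: str, params: AlignmentParams | None = None,
    query_id: str = "query", subject_id: str = "subject",
) -> list[LocalAlignment]:
    """Find all reportable local alignments of *query* in *subject*.

    Both strands are searched; hit coordinates are always given on the
    forward subject, and query coordinates on the forward query.  Hits of
    the same query and strand that overlap or nearly abut are merged to the
    widest hit.  Results are sorted by subject coordinate.
    """
    params = params or AlignmentParams()
    if isinstance(subject, SubjectIndex):
        if subject.k != params.seed_length:
            raise ValueError("subject index built with a different seed length")
        index = subject
    else:
        if not subject:
            raise ValueError("seeded_search requires non-empty sequences")
        index = SubjectIndex(subject, params.seed_length)
    if not query:
        raise ValueError("seeded_search requires non-empty sequences")
    s_codes = index.codes
    qlen = len(query)
    hits: list[LocalAlignment] = []
    prefilter = min(params.min_score, PREFILTER_CAP)
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        q_codes = encode(q)
        qpos, spos = _collect_seeds(q_codes, index)
        if qpos.size == 0:
            continue
        diag, clusters = _cluster_seeds(qpos, spos, qlen)
        for members in clusters:
            mid = members[len(members) // 2]
            ug = ungapped_extend(
                q_codes, s_codes, qpos[mid], spos[mid], params.seed_length,
                params.match_score, params.mismatch_score, params.x_drop,
            )
            if ug < prefilter:
                continue
            res = _align_cluster(q_codes, s_codes, qpos, spos, diag, members, params)
            if res is None:
                continue
            score, a0, a1, b0, b1, matches, cols, ncols = res
            identity = _identity(matches, cols, ncols)
            if not _passes(params, score, identity, cols):
                continue
            if strand == "-":
                a0, a1 = qlen - a1, qlen - a0
            hits.append(
                LocalAlignment(
                    query_id, subject_id, int(a0), int(a1), int(b0), int(b1),
                    strand, int(score), identity, int(cols),
                )
            )
    hits = _merge_hits(hits)
    hits.sort(key=lambda h: (h.subject_start, h.subject_end, h.strand))
    return hits


def _merge_hits(hits: list[LocalAlignment]) -> list[LocalAlignment]:
    """Merge same-strand hits separated by < MERGE_GAP nt into the widest hit."""
    out: list[LocalAlignment] = []
    for strand in ("+", "-"):
        group = sorted(
            (h for h in hits if h.strand == strand),
            key=lambda h: (h.subject_start, h.subject_end),
        )
        cur: LocalAlignment | None = None
        for h in group:
            if cur is None:
                cur = h
                continue
            if h.subject_start < cur.subject_end + MERGE_GAP:
                best = cur if cur.score >= h.score else h
                cur = replace(
                    best,
                    query_start=min(cur.query_start, h.query_start),
                    query_end=max(cur.query_end, h.query_end),
                    subject_start=min(cur.subject_start, h.subject_start),
                    subject_end=max(cur.subject_end, h.subject_end),
                    score=max(cur.score, h.score),
                    aligned_length=max(cur.aligned_length, h.aligned_length),
                )
            else:
                out.append(cur)
                cur = h
        if cur is not None:
            out.append(cur)
    return out


def global_identity(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Identity of the global affine alignment of two sequences.

    Matching columns over comparable columns (gap columns count against,
    N-containing columns are dropped from both sides of the fraction).
    """
    params = params or AlignmentParams()
    from ._kernels import nw_full

    _, matches, cols, ncols = nw_full(
        encode(a), encode(b),
        params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend,
    )
    return _identity(matches, cols, ncols)


def global_score(a: str, b: str, params: AlignmentParams | None = None) -> int:
    """Score of the global affine alignment of two sequences."""
    params = params or AlignmentParams()
    from ._kernels import nw_full

    score, _, _, _ = nw_full(
        encode(a), encode(b),
        params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend,
    )
    return int(score)


def write_hits_bed(hits, path, name_func=None) -> None:
    """Write alignments as 6-column BED (name = family:query_id by default)."""
    with open(path, "w") as fh:
        for h in hits:
            name = name_func(h) if name_func else h.query_id
            fh.write(
                f"{h.subject_id}\t{h.subject_start}\t{h.subject_end}"
                f"\t{name}\t{h.score}\t{h.strand}\n"
            )
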