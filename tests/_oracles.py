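"""Independent brute-force oracles used to verify the package's algorithms.

These deliberately share no code with the implementation: plain-Python
dynamic programming for local alignment, a matrix-exponential HKY85
sequence simulator, and path-length distances on explicit trees.
"""

import numpy as np

UNMATCHABLE = set("Nacgtn")


def local_affine_score(a: str, b: str, match=1, mismatch=-1, gap_open=2, gap_extend=1) -> int:
    """Best local alignment score with affine gaps (gap of L costs open+L*ext).

    N/lowercase score as mismatches, matching the engine's convention.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    h_prev = [0.0] * (m + 1)
    f = [neg] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = [0.0] * (m + 1)
        e = neg
        ca = a[i - 1]
        for j in range(1, m + 1):
            e = max(e - gap_extend, h_cur[j - 1] - gap_open - gap_extend)
            f[j] = max(f[j] - gap_extend, h_prev[j] - gap_open - gap_extend)
            cb = b[j - 1]
            ok = ca == cb and ca not in UNMATCHABLE and cb not in UNMATCHABLE
            s = match if ok else mismatch
            h_cur[j] = max(0.0, h_prev[j - 1] + s, e, f[j])
            if h_cur[j] > best:
                best = h_cur[j]
        h_prev = h_cur
    return int(best)


def mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute positions until the given fraction of sites is untouched."""
    bases = "ACGT"
    n_sub = int(round((1 - identity) * len(seq)))
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([c for c in bases if c != out[p]])
    return "".join(out)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def hky85_pair(
    d: float, kappa: float, pi: np.ndarray, length: int, rng: np.random.Generator
) -> tuple[str, str]:
    """Ancestor/descendant pair simulated under HKY85 at distance d.

    The rate matrix is built explicitly and scaled to one expected
    substitution per site per unit time, then exponentiated.
    """
    from scipy.linalg import expm

    bases = "ACGT"
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = kappa * pi[j] if (i, j) in transitions else pi[j]
            Q[i, j] = rate
    Q[np.diag_indices(4)] = -Q.sum(axis=1)
    mu = -np.dot(pi, np.diag(Q))  # expected substitutions per site per unit time
    Q /= mu
    P = expm(Q * d)
    anc_idx = rng.choice(4, size=length, p=pi)
    child_idx = np.array([rng.choice(4, p=P[i]) for i in anc_idx])
    anc = "".join(bases[i] for i in anc_idx)
    child = "".join(bases[i] for i in child_idx)
    return anc, child


class SimpleTree:
    """Explicit weighted tree for building additive distance matrices."""

    def __init__(self, edges: dict[tuple[str, str], float]):
        self.adj: dict[str, list[tuple[str, float]]] = {}
        for (a, b), w in edges.items():
            self.adj.setdefault(a, []).append((b, w))
            self.adj.setdefault(b, []).append((a, w))

    def distance(self, a: str, b: str) -> float:
        seen = {a: 0.0}
        stack = [a]
        while stack:
            node = stack.pop()
            if node == b:
                return seen[node]
            for nxt, w in self.adj[node]:
                if nxt not in seen:
                    seen[nxt] = seen[node] + w
                    stack.append(nxt)
        raise KeyError(b)

    def matrix(self, leaves: list[str]) -> np.ndarray:
        n = len(leaves)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = self.distance(leaves[i], leaves[j])
        return d
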