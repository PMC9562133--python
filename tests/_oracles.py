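"""Independent brute-force oracles used to validate the implementations.

These are deliberately written without the package's lookup tables or
algebraic shortcuts: plain string handling, exhaustive enumeration, and
direct dynamic programming, so agreement with the package is meaningful.
"""

from __future__ import annotations

import itertools
import math

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _AA[_stop] = "*"


def ng86_brute(cds1: str, cds2: str):
    """NG86 by direct enumeration on two ungapped, stop-free, in-frame CDS.

    Returns (S, N, Sd, Nd, Ka, Ks) with nan for saturated corrections.
    """
    assert len(cds1) == len(cds2) and len(cds1) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i : i + 3], cds2[i : i + 3]
        # difference counts over all orderings of differing positions
        diff_pos = [p for p in range(3) if c1[p] != c2[p]]
        if diff_pos:
            path_sd = []
            path_nd = []
            for order in itertools.permutations(diff_pos):
                cur = c1
                sd = nd = 0
                dead = False
                for p in order:
                    nxt = cur[:p] + c2[p] + cur[p + 1 :]
                    if _AA[nxt] == "*":
                        dead = True
                        break
                    if _AA[nxt] == _AA[cur]:
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                if not dead:
                    path_sd.append(sd)
                    path_nd.append(nd)
            if not path_sd:
                continue  # codon pair entirely excluded
            Sd += sum(path_sd) / len(path_sd)
            Nd += sum(path_nd) / len(path_nd)
        # fractional site counts, averaged over the two codons
        s_pair = 0.0
        for codon in (c1, c2):
            s_codon = 0.0
            for p in range(3):
                for b in "ACGT":
                    if b == codon[p]:
                        continue
                    mutant = codon[:p] + b + codon[p + 1 :]
                    if _AA[mutant] == _AA[codon] and _AA[mutant] != "*":
                        s_codon += 1.0 / 3.0
            s_pair += s_codon
        S += s_pair / 2.0
        N += 3.0 - s_pair / 2.0

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ks = jc(Sd / S) if S > 0 else float("nan")
    ka = jc(Nd / N) if N > 0 else float("nan")
    return S, N, Sd, Nd, ka, ks


def gotoh_score(p1: str, p2: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap alignment score (Gotoh three-state DP).

    Gap cost convention matches Biopython's PairwiseAligner: a gap of
    length L costs gap_open + (L-1)*gap_extend; terminal gaps are charged.
    """
    n, m = len(p1), len(p2)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in p2 (vertical)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in p1 (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = matrix[p1[i - 1], p2[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def tandem_brute(genes, homologous_pairs, max_gap=1):
    """All-pairs adjacency test plus union-find clustering.

    ``genes``: list of (gene_id, chromosome, start); ranks derived by
    sorting starts per chromosome.  ``homologous_pairs``: set of
    frozensets.  Returns a set of frozensets (the clusters).
    """
    rank = {}
    by_chrom = {}
    for gid, chrom, start in genes:
        by_chrom.setdefault(chrom, []).append((start, gid))
    for chrom, lst in by_chrom.items():
        for i, (_s, gid) in enumerate(sorted(lst)):
            rank[gid] = (chrom, i)

    parent = {gid: gid for gid, _c, _s in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ids = [g[0] for g in genes]
    tandem = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if frozenset((a, b)) not in homologous_pairs:
                continue
            ca, ra = rank[a]
            cb, rb = rank[b]
            if ca == cb and abs(ra - rb) <= max_gap:
                tandem.add(frozenset((a, b)))
                parent[find(a)] = find(b)
    clusters = {}
    for pair in tandem:
        for gid in pair:
            clusters.setdefault(find(gid), set()).add(gid)
    return {frozenset(members) for members in clusters.values()}


def hypergeom_tail_enum(N: int, n: int, m: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, n, m) by enumerating all C(N, m) draws."""
    population = list(range(N))
    marked = set(range(n))
    hits = 0
    total = 0
    for draw in itertools.combinations(population, m):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total
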