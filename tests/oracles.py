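"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is a deliberately simple, quadratic-or-worse reference
computation sharing no code with the library paths it validates.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}


def smith_waterman_score(query: str, subject: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Affine-gap local alignment score by the Gotoh dynamic program.

    Gap of length k costs ``gap_open + k * gap_extend`` (the first gapped
    position pays open+extend), matching the screening engine's convention.
    Substitutions score by BLOSUM62 with the X column zeroed.
    """
    matrix = substitution_matrices.load("BLOSUM62")
    alphabet = matrix.alphabet

    def sub(a: str, b: str) -> float:
        if a == "X" or b == "X":
            return 0.0
        a = a if a in alphabet else "X"
        b = b if b in alphabet else "X"
        if a == "X" or b == "X":
            return 0.0
        return float(matrix[a, b])

    n, m = len(query), len(subject)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in query (consume subject)
    F = np.full((n + 1, m + 1), neg)  # gap in subject (consume query)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend)
            H[i, j] = max(
                0.0,
                H[i - 1, j - 1] + sub(query[i - 1], subject[j - 1]),
                E[i, j],
                F[i, j],
            )
            best = max(best, H[i, j])
    return best


def interval_clusters(intervals: list[tuple[int, int]], range_nt: int) -> list[tuple[int, int]]:
    """Cluster intervals by transitive closure of 'overlap or gap <= range'.

    Brute-force union-find over the full pairwise adjacency graph; returns
    sorted cluster hulls.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    for i in range(n):
        s1, e1 = intervals[i]
        for j in range(i + 1, n):
            s2, e2 = intervals[j]
            gap = max(s1, s2) - min(e1, e2) - 1
            if gap <= range_nt:
                union(i, j)
    hulls: dict[int, list[int]] = {}
    for i in range(n):
        hulls.setdefault(find(i), []).append(i)
    out = []
    for members in hulls.values():
        out.append(
            (
                min(intervals[k][0] for k in members),
                max(intervals[k][1] for k in members),
            )
        )
    return sorted(out)


def six_frame_orfs(nt: str, min_len_aa: int) -> set[tuple]:
    """Exhaustive six-frame ORF scan (independent of the library scanner).

    Returns a set of ``(strand, frame, start, end, length_aa, kind)`` tuples
    in forward-sequence coordinates.
    """
    out = set()
    L = len(nt)
    for strand in ("+", "-"):
        s = nt if strand == "+" else str(Seq(nt).reverse_complement())
        for frame in range(3):
            positions = list(range(frame, L - 2, 3))
            codons = [s[p : p + 3] for p in positions]
            idx = 0
            seg = []
            segments = []
            for k, codon in enumerate(codons):
                if codon in _STOPS:
                    segments.append((seg, True))
                    seg = []
                else:
                    seg.append(k)
            segments.append((seg, False))
            for seg, stopped in segments:
                if not seg:
                    continue
                n_codons = len(seg)
                a, b = positions[seg[0]] + 1, positions[seg[-1]] + 3
                if n_codons >= min_len_aa:
                    out.add(_orient(strand, frame, a, b, n_codons, "open_coding_region", L))
                atg = next((k for k in seg if codons[k] == "ATG"), None)
                if atg is not None:
                    coding = seg[-1] - atg + 1
                    if coding >= min_len_aa:
                        end = b + 3 if stopped else b
                        out.add(
                            _orient(strand, frame, positions[atg] + 1, end, coding, "atg_initiated", L)
                        )
    return out


def _orient(strand, frame, start, end, length_aa, kind, L):
    if strand == "-":
        start, end = L - end + 1, L - start + 1
    return (strand, frame, start, end, length_aa, kind)


def chain_by_gap(intervals: list[tuple[int, int]], distance: int) -> list[list[int]]:
    """Single-linkage chaining of sorted intervals by successive gap <= distance.

    Returns index groups in ascending start order.
    """
    order = sorted(range(len(intervals)), key=lambda k: intervals[k])
    chains: list[list[int]] = []
    chain_end = None
    for k in order:
        s, e = intervals[k]
        if chains and s - chain_end - 1 <= distance:
            chains[-1].append(k)
            chain_end = max(chain_end, e)
        else:
            chains.append([k])
            chain_end = e
    return chains


def all_pairs_mrca_depth(tree, labels: list[str]) -> float:
    """Deepest pairwise MRCA depth among the labelled tips (dendropy tree)."""

    def age(node) -> float:
        if node.is_leaf():
            return 0.0
        return max(age(ch) + (ch.edge.length or 0.0) for ch in node.child_nodes())

    depth = 0.0
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            mrca = tree.mrca(taxon_labels=[a, b])
            depth = max(depth, age(mrca))
    return depth
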