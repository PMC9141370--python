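"""Smith–Waterman local alignment of short peptides with affine gaps.

Scoring mirrors protein BLAST defaults: BLOSUM62, gap existence 11, gap
extension 1 (a gap of length L costs 11 + L). The similarity reported to the
filter cascade is 100 x (aligned residue pairs with a positive BLOSUM62
score) / query length — identity gives 100, an alignment with no positive
pairs gives 0, and the value is bounded in [0, 100] because a query residue
can be aligned at most once.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import substitution_matrices

GAP_OPEN = 11
GAP_EXTEND = 1

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> int:
    return int(_BLOSUM62[a, b])


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    pairs: tuple[tuple[int, int], ...]  # aligned (query_idx, subject_idx), 0-based
    query_span: tuple[int, int]  # 1-based inclusive
    subject_span: tuple[int, int]


def smith_waterman(query: str, subject: str,
                   gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND,
                   ) -> LocalAlignment:
    """Best-scoring local alignment (Gotoh affine-gap recurrence).

    Ties are broken toward the smallest (i, j) end cell and, during traceback,
    by preferring diagonal moves over gaps — deterministic and immaterial to
    the score.
    """
    n, m = len(query), len(subject)
    NEG = float("-inf")
    # H: best ending in a match/mismatch; E: gap in subject (query consumed);
    # F: gap in query
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          F[i][j - 1] - gap_extend)
            diag = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            H[i][j] = max(0.0, diag + blosum62(qi, subject[j - 1]))
            cell = max(H[i][j], E[i][j], F[i][j])
            if cell > best:
                best, bi, bj = cell, i, j
    if best <= 0:
        return LocalAlignment(0, (), (0, 0), (0, 0))
    # traceback from the best cell
    pairs: list[tuple[int, int]] = []
    i, j = bi, bj
    state = max(("H", "E", "F"), key=lambda s: {"H": H, "E": E, "F": F}[s][i][j])
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            pairs.append((i - 1, j - 1))
            prev = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            if prev == 0:
                i, j = i - 1, j - 1
                break
            for s, mat in (("H", H), ("E", E), ("F", F)):
                if mat[i - 1][j - 1] == prev:
                    state = s
                    break
            i, j = i - 1, j - 1
        elif state == "E":
            if E[i][j] == H[i - 1][j] - gap_open - gap_extend:
                state = "H"
            i -= 1
        else:
            if F[i][j] == H[i][j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
    pairs.reverse()
    if not pairs:
        return LocalAlignment(int(best), (), (0, 0), (0, 0))
    qspan = (pairs[0][0] + 1, pairs[-1][0] + 1)
    sspan = (pairs[0][1] + 1, pairs[-1][1] + 1)
    return LocalAlignment(int(best), tuple(pairs), qspan, sspan)


def positive_pairs(query: str, subject: str, aln: LocalAlignment) -> int:
    return sum(1 for qi, sj in aln.pairs if blosum62(query[qi], subject[sj]) > 0)


def similarity_score(query: str, subject: str) -> tuple[float, LocalAlignment]:
    """(similarity on the 0-100 scale, underlying alignment)."""
    aln = smith_waterman(query, subject)
    if not aln.pairs:
        return 0.0, aln
    return 100.0 * positive_pairs(query, subject, aln) / len(query), aln
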