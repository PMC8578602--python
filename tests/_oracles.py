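"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the package's dynamic-programming code paths: the
alignment oracle enumerates every global alignment of two short sequences
and scores each one directly.
"""

from __future__ import annotations

from functools import lru_cache

DIAG, UP, LEFT = "d", "u", "l"
_RANK = {DIAG: 0, UP: 1, LEFT: 2}


def enumerate_alignments(n: int, m: int):
    """All global alignments of lengths (n, m) as move strings."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if i == 0 and j == 0:
            return [""]
        outs = []
        if i > 0 and j > 0:
            outs += [s + DIAG for s in rec(i - 1, j - 1)]
        if i > 0:
            outs += [s + UP for s in rec(i - 1, j)]
        if j > 0:
            outs += [s + LEFT for s in rec(i, j - 1)]
        return outs

    return rec(n, m)


def score_moves(moves: str, seqA: str, seqB: str, score_fn, gap_open: float,
                gap_extend: float) -> float:
    """Score one alignment: substitution scores minus affine gap costs.

    Each maximal run of L consecutive gap moves (all-up or all-left) costs
    gap_open + gap_extend * L; a run of ups directly followed by lefts is
    two separate gaps.
    """
    total = 0.0
    i = j = 0
    run = None
    for mv in moves:
        if mv == DIAG:
            total += score_fn(seqA[i], seqB[j])
            i += 1
            j += 1
            run = None
        else:
            if mv != run:
                total -= gap_open
                run = mv
            total -= gap_extend
            if mv == UP:
                i += 1
            else:
                j += 1
    return total


def moves_to_pairs(moves: str):
    pairs = []
    i = j = 0
    for mv in moves:
        if mv == DIAG:
            pairs.append((i + 1, j + 1))
            i += 1
            j += 1
        elif mv == UP:
            i += 1
        else:
            j += 1
    return pairs


def brute_force_align(seqA: str, seqB: str, score_fn, gap_open: float,
                      gap_extend: float):
    """Optimal score and the tie-broken optimal alignment's pairs.

    Ties among optimal alignments are resolved by preferring diagonal, then
    up, then left moves, scanning from the alignment's end — the same
    convention the package's traceback uses.
    """
    best_score = None
    best_moves = None
    for moves in enumerate_alignments(len(seqA), len(seqB)):
        s = score_moves(moves, seqA, seqB, score_fn, gap_open, gap_extend)
        if best_score is None or s > best_score - 1e-12:
            key = [_RANK[m] for m in reversed(moves)]
            if best_score is None or s > best_score + 1e-12:
                best_score, best_moves, best_key = s, moves, key
            elif key < best_key:
                best_moves, best_key = moves, key
    return best_score, moves_to_pairs(best_moves)
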