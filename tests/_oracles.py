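"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's seed-chain-extend and cached
aligner code paths: a plain affine-gap Smith-Waterman dynamic program
with traceback, small enough to trust by inspection.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_protein(
    query: str,
    target: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
):
    """Exhaustive local alignment of proteins under BLOSUM62 affine gaps.

    Returns (score, query_interval, target_interval, identity) of the
    optimal local alignment, ties broken toward the lowest end cell.
    """
    n, m = len(query), len(target)
    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG)  # gap in target (query consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in query
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up(X), 3 left(Y)
    best, best_cell = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[query[i - 1], target[j - 1]]
            diag = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1], 0.0) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            M[i, j] = diag
            cell = max(diag, X[i, j], Y[i, j], 0.0)
            if cell == diag and diag > 0:
                ptr[i, j] = 1
            elif cell == X[i, j]:
                ptr[i, j] = 2
            elif cell == Y[i, j]:
                ptr[i, j] = 3
            if cell > best:
                best, best_cell = cell, (i, j)
    # traceback from the best cell
    i, j = best_cell
    qi_end, tj_end = i, j
    matches = cols = 0
    state = ptr[i, j]
    while i > 0 and j > 0 and state != 0:
        if state == 1:
            cols += 1
            matches += query[i - 1] == target[j - 1]
            i, j = i - 1, j - 1
            if max(M[i, j], X[i, j], Y[i, j], 0.0) == 0.0:
                break
            state = ptr[i, j] if M[i, j] >= max(X[i, j], Y[i, j]) else (2 if X[i, j] >= Y[i, j] else 3)
        elif state == 2:
            cols += 1
            i -= 1
            state = ptr[i, j]
        else:
            cols += 1
            j -= 1
            state = ptr[i, j]
    identity = matches / cols if cols else 0.0
    return best, (i, qi_end), (j, tj_end), identity
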