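"""Independent oracles used by the test suite.

These deliberately avoid the formulations used inside the package: the
local-alignment oracle enumerates alignments as runs of diagonal moves
and explicit gap runs (no affine three-state recursion), the motif
oracle slides a window, and the distance oracles evaluate closed forms
directly.
"""

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_oracle(query: str, subject: str, gap_open: int = 11,
              gap_extend: int = 1) -> float:
    """Best local alignment score by exhaustive run enumeration.

    E[i][j] = best score of any alignment ending with query[i-1] or a gap
    run at subject position j; gap runs of length k cost open + k*extend
    and are enumerated explicitly, so no affine state machine is
    involved.
    """
    m, n = len(query), len(subject)
    E = [[0.0] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = BLOSUM62[query[i - 1], subject[j - 1]]
            cand = [max(E[i - 1][j - 1], 0.0) + sub]
            for k in range(1, i):
                cand.append(E[i - k][j] - gap_open - gap_extend * k)
            for k in range(1, j):
                cand.append(E[i][j - k] - gap_open - gap_extend * k)
            E[i][j] = max(cand)
            if E[i][j] > best:
                best = E[i][j]
    return best


def itim_oracle(tail: str) -> list[tuple[int, str]]:
    """Sliding-window scan for the ITIM consensus, 1-based positions."""
    hits = []
    for i in range(len(tail) - 5):
        w = tail[i:i + 6]
        if (w[0] in "SIVL" and w[2] == "Y" and w[5] in "IVL"):
            hits.append((i + 1, w))
    return hits


def mask_oracle(a: str, b: str, valid: str) -> list[int]:
    return [i for i in range(len(a))
            if a[i].upper() in valid and b[i].upper() in valid]
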