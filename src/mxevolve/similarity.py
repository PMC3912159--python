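"""Exon similarity scoring.

The detector thresholds candidate exons on a similarity fraction defined as

    score(a, b) = (# aligned columns with a positive BLOSUM62 value)
                  / max(len(a), len(b))

over a global (Needleman-Wunsch/Gotoh) alignment with affine gap costs
(open 11, extend 1, i.e. a gap of length k costs 11 + k).  Because several
alignments can share the optimal alignment score while differing in how many
of their columns score positive, the DP optimises the pair
(alignment score, positive-column count) lexicographically; the reported
fraction is therefore a deterministic function of the two sequences and is
symmetric in its arguments.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

from .errors import SearchError

GAP_OPEN = 11   # charged when a gap is opened, on top of the first extend
GAP_EXTEND = 1  # charged per gap column

_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA = _BLOSUM.alphabet


@lru_cache(maxsize=1)
def _tables() -> tuple[dict, dict]:
    """(pair -> integer substitution score, pair -> 1 if positive)."""
    sub, pos = {}, {}
    for x in _AA:
        for y in _AA:
            s = int(_BLOSUM[x, y])
            sub[(x, y)] = s
            pos[(x, y)] = 1 if s > 0 else 0
    return sub, pos


# Lexicographic (score, positives) packed into one int: value = score*K + pos,
# with K larger than any achievable positive-column count.
_K = 4096
_NEG = -(10 ** 12)


def aligned_positive_columns(a: str, b: str) -> int:
    """Positive-scoring column count of the optimal global affine alignment,
    maximised secondarily over score-tied alignments."""
    sub, pos = _tables()
    n, m = len(a), len(b)
    open_ext = (GAP_OPEN + GAP_EXTEND) * _K
    ext = GAP_EXTEND * _K

    # three-state Gotoh over packed values
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]   # a[i-1] ~ b[j-1]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]   # gap in b
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]   # gap in a
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = -open_ext - ext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -open_ext - ext * (j - 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            bj = b[j - 1]
            step = sub[(ai, bj)] * _K + pos[(ai, bj)]
            best_prev = Mi1[j - 1]
            if Xi1[j - 1] > best_prev:
                best_prev = Xi1[j - 1]
            if Yi1[j - 1] > best_prev:
                best_prev = Yi1[j - 1]
            Mi[j] = best_prev + step
            x = Mi1[j] - open_ext
            x2 = Xi1[j] - ext
            Xi[j] = x if x > x2 else x2
            y = Mi[j - 1] - open_ext
            y2 = Yi[j - 1] - ext
            Yi[j] = y if y > y2 else y2
    best = max(M[n][m], X[n][m], Y[n][m])
    return ((best % _K) + _K) % _K


def score_exon_similarity(a: str, b: str) -> float:
    """Similarity fraction in [0, 1] between two exon translations."""
    if not a or not b:
        raise SearchError("score_exon_similarity: empty input sequence")
    a, b = a.upper(), b.upper()
    for s in (a, b):
        bad = set(s) - set(_AA)
        if bad:
            raise SearchError(f"score_exon_similarity: residues {sorted(bad)} "
                              f"not in the substitution matrix alphabet")
    return aligned_positive_columns(a, b) / max(len(a), len(b))
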