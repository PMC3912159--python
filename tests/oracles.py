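"""Independent reference implementations used only by the tests.

Each oracle re-derives a quantity along a different computational route
than the package: a memoized recursive alignment instead of the iterative
DP, exhaustive enumeration of loss placements instead of the tree walk,
and a character-walking intron mapper instead of arithmetic on exon
lengths.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

from mxevolve.dollo import leaf_names, node_name
from mxevolve.similarity import GAP_EXTEND, GAP_OPEN, _tables

_NEG = (-(10 ** 9), 0)


def similarity_positive_columns(a: str, b: str) -> int:
    """Positive-column count of the lexicographically optimal global affine
    alignment, via top-down recursion with memoization."""
    sub, pos = _tables()

    @lru_cache(maxsize=None)
    def M(i, j):
        if i == 0 and j == 0:
            return (0, 0)
        if i == 0 or j == 0:
            return _NEG
        s, p = max(M(i - 1, j - 1), X(i - 1, j - 1), Y(i - 1, j - 1))
        return (s + sub[(a[i - 1], b[j - 1])], p + pos[(a[i - 1], b[j - 1])])

    @lru_cache(maxsize=None)
    def X(i, j):
        if i == 0:
            return _NEG
        sm, pm = M(i - 1, j)
        sx, px = X(i - 1, j)
        return max((sm - GAP_OPEN - GAP_EXTEND, pm), (sx - GAP_EXTEND, px))

    @lru_cache(maxsize=None)
    def Y(i, j):
        if j == 0:
            return _NEG
        sm, pm = M(i, j - 1)
        sy, py = Y(i, j - 1)
        return max((sm - GAP_OPEN - GAP_EXTEND, pm), (sy - GAP_EXTEND, py))

    n, m = len(a), len(b)
    _, p = max(M(n, m), X(n, m), Y(n, m))
    M.cache_clear(), X.cache_clear(), Y.cache_clear()
    return p


def similarity_oracle(a: str, b: str) -> float:
    return similarity_positive_columns(a.upper(), b.upper()) / max(len(a), len(b))


def minimal_loss_placements(tree, gain_name: str,
                            states: dict[str, str]) -> tuple[int, list[set]]:
    """All minimum-cardinality loss-branch sets below ``gain_name`` that
    keep every present leaf connected and cut off every absent leaf.
    Exhaustive search over branch subsets of increasing size."""
    gain = None
    for node in tree.preorder_node_iter():
        if node_name(node) == gain_name:
            gain = node
            break
    assert gain is not None
    below = [node_name(n) for n in gain.preorder_iter() if n is not gain]

    # path (set of strictly-below node names) from gain to each leaf
    paths: dict[str, set[str]] = {}

    def walk(node, acc):
        if node.is_leaf():
            paths[node.taxon.label] = set(acc)
            return
        for ch in node.child_nodes():
            walk(ch, acc + [node_name(ch)])

    walk(gain, [])
    present = {l for l in leaf_names(gain) if states.get(l) == "P"}
    absent = {l for l in leaf_names(gain) if states.get(l) == "A"}

    def valid(cut: set[str]) -> bool:
        for l in present:
            if paths[l] & cut:
                return False
        for l in absent:
            if not (paths[l] & cut):
                return False
        return True

    for k in range(len(below) + 1):
        sets = [set(c) for c in combinations(below, k) if valid(set(c))]
        if sets:
            return k, sets
    raise AssertionError("no valid loss placement (states inconsistent)")


def walk_intron_columns(exon_nts: list[str], msa_row: str) -> list[tuple[int, int]]:
    """(column, phase) of each intron by walking coding nucleotides one at a
    time across the reference exons and gap-aware MSA columns."""
    residue_cols = [i for i, ch in enumerate(msa_row) if ch != "-"]
    out = []
    coding = 0
    for exon in exon_nts[:-1]:
        for _ in exon:
            coding += 1
        aa, phase = coding // 3, coding % 3
        out.append((residue_cols[aa], phase))
    return out
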