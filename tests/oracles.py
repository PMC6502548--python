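"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or by the
textbook formula, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

from citsift.sequences import AA_INDEX


def brute_force_forward_bits(hmm, seq: str) -> float:
    """Sum P(path, seq) over *all* state paths of a profile HMM by
    explicit recursion; log2-odds against the background model."""
    m = hmm.n_match_states
    t = hmm.transitions
    x = [AA_INDEX[c] for c in seq.upper()]
    total = 0.0

    def succ(state):
        typ, k = state
        out = []
        if typ == "M":
            if k < m:
                out += [(("M", k + 1), t["MM"][k], True), (("D", k + 1), t["MD"][k], False)]
            else:
                out.append((("E", 0), t["MM"][k], False))
            out.append((("I", k), t["MI"][k], True))
        elif typ == "I":
            nxt = ("M", k + 1) if k < m else ("E", 0)
            out += [(nxt, t["IM"][k], True), (("I", k), t["II"][k], True)]
            if k == m:
                out[0] = (("E", 0), t["IM"][k], False)
        else:
            if k < m:
                out += [(("M", k + 1), t["DM"][k], True), (("D", k + 1), t["DD"][k], False)]
            else:
                out.append((("E", 0), t["DM"][k], False))
        return out

    def emis(state, xi):
        typ, k = state
        return hmm.match_emissions[k - 1][xi] if typ == "M" else hmm.insert_emissions[xi]

    def rec(state, pos, p):
        nonlocal total
        if state == ("E", 0):
            if pos == len(x):
                total += p
            return
        for nxt, tp, emits in succ(state):
            if tp <= 0:
                continue
            if nxt == ("E", 0):
                rec(nxt, pos, p * tp)
            elif emits:
                if pos < len(x):
                    rec(nxt, pos + 1, p * tp * emis(nxt, x[pos]))
            else:
                rec(nxt, pos, p * tp)

    rec(("M", 0), 0, 1.0)
    p_null = float(np.prod([hmm.background[i] for i in x]))
    return math.log2(total / p_null)


def brute_force_sequence_probability(hmm, seq: str) -> float:
    """P(seq | model, exactly len(seq) residues emitted), by the same
    path enumeration."""
    bits = brute_force_forward_bits(hmm, seq)
    x = [AA_INDEX[c] for c in seq.upper()]
    p_null = float(np.prod([hmm.background[i] for i in x]))
    return 2.0**bits * p_null


def enumerate_global_alignments(a: str, b: str, matrix, gap_open: float, gap_extend: float):
    """Best ``(score, identical, -length)`` over *every* global
    alignment, by exhaustive recursion (first gap column costs
    open + extend, each further column extend)."""
    best = [None]

    def rec(i, j, score, ident, length, gapstate):
        if i == len(a) and j == len(b):
            key = (score, ident, -length)
            if best[0] is None or key > best[0]:
                best[0] = key
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]],
                ident + (a[i] == b[j]), length + 1, 0)
        if i < len(a):
            cost = gap_extend if gapstate == 1 else gap_open + gap_extend
            rec(i + 1, j, score - cost, ident, length + 1, 1)
        if j < len(b):
            cost = gap_extend if gapstate == 2 else gap_open + gap_extend
            rec(i, j + 1, score - cost, ident, length + 1, 2)

    rec(0, 0, 0.0, 0, 0, None)
    return best[0]


def bh_fdr_by_hand(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the definition: for the i-th smallest
    p-value, min over the tail of p_(j) * n / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        adjusted[idx] = running_min
    return adjusted
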