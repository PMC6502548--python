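"""Profile hidden Markov models built from seed alignments of
characterised citrate transporters, used to screen a proteome.

Architecture
------------
Classic global match/insert/delete profile:

* a begin state (treated as match state 0), match states ``M_1..M_m``
  from alignment columns whose gap fraction is below a threshold,
* insert states ``I_0..I_m`` (one per match interval, emitting with the
  background distribution),
* silent delete states ``D_1..D_m``, and an end state.

Seven transition types are modelled (``M->M, M->I, M->D, I->M, I->I,
D->M, D->D``); there are no ``I->D``/``D->I`` transitions and no local
alignment modes: a protein is aligned globally, with the terminal insert
states ``I_0``/``I_m`` absorbing unmatched flanks at background emission
cost (an inserted residue therefore costs only transition probability in
the log-odds score).

Scoring
-------
``forward_bits`` returns ``log2(P(seq|model) / P(seq|background))``
summed over all alignments by the forward recursion.  The recursion runs
in odds space (emissions divided by background frequencies) with
per-position rescaling, which avoids underflow on long proteins without
any transcendental calls in the inner loop.  The silent-delete chain
within one position is a linear recurrence solved blockwise so that long
all-delete runs cannot underflow the intermediate products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .sequences import AA_INDEX, ALPHABET, GAP_CHARS, encode as _encode_seq

_DSCAN_BLOCK = 32  # block width of the delete-chain scan


@dataclass
class ProfileHMM:
    """Profile HMM parameters (probability space).

    ``match_emissions[k-1]`` is the 20-vector of match state ``M_k``;
    ``transitions`` holds seven ``(m+1,)`` arrays indexed by the source
    column ``k`` (column 0 is the begin state; entries at the boundary
    that correspond to transitions into the end state reuse the ``*M``
    slots).  ``insert_emissions`` equals ``background``.
    """

    n_match_states: int
    match_emissions: np.ndarray  # (m, 20)
    insert_emissions: np.ndarray  # (20,)
    background: np.ndarray  # (20,)
    transitions: dict[str, np.ndarray]  # keys MM MI MD IM II DM DD, each (m+1,)

    def __post_init__(self) -> None:
        if self.n_match_states < 1:
            raise ValidationError("profile HMM needs at least one match state")

    def validate(self, tol: float = 1e-9) -> None:
        """Check that every emission/transition distribution sums to 1."""
        m = self.n_match_states
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=tol):
            raise ValidationError("match emissions do not normalise")
        for vec in (self.insert_emissions, self.background):
            if abs(vec.sum() - 1.0) > tol:
                raise ValidationError("background distribution does not normalise")
        t = self.transitions
        if not np.allclose(t["MM"] + t["MI"] + t["MD"], 1.0, atol=tol):
            raise ValidationError("match transitions do not normalise")
        if not np.allclose(t["IM"] + t["II"], 1.0, atol=tol):
            raise ValidationError("insert transitions do not normalise")
        # D_0 does not exist; its row is all zeros by construction.
        dsum = t["DM"] + t["DD"]
        if not (np.allclose(dsum[1:], 1.0, atol=tol) and abs(dsum[0]) <= tol):
            raise ValidationError("delete transitions do not normalise")


@dataclass(frozen=True)
class HmmHit:
    protein_id: str
    score: float  # log-odds bits
    rank: int


def _check_alignment(seqs: list[str]) -> int:
    if len(seqs) < 2:
        raise ValidationError("need at least two aligned sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValidationError("ragged alignment: sequences differ in aligned length")
    if length == 0:
        raise ValidationError("empty alignment")
    for s in seqs:
        bad = set(s.upper()) - set(ALPHABET) - GAP_CHARS
        if bad:
            raise ValidationError(f"illegal alignment characters {sorted(bad)}")
    return length


def _sequence_path(row, is_match, match_ordinal, m):
    """Backbone residues (per match column; -1 = delete) and per-segment
    insert residues for one aligned sequence.

    The seven-transition architecture has no I<->D transitions, so an
    insert residue cannot sit directly against a deleted match column.
    Such adjacencies are resolved by absorbing insert residues into the
    adjacent deleted columns (treating an insert next to a delete as a
    misaligned substitution); leftover deletions form pure runs and
    leftover inserts end up flanked by match states, both of which the
    architecture supports.  Emission order of the sequence is preserved
    because deleted columns emit nothing.
    """
    backbone = np.full(m, -1, dtype=int)
    seg: list[list[int]] = [[] for _ in range(m + 1)]
    for j, res in enumerate(row):
        if is_match[j]:
            if res >= 0:
                backbone[match_ordinal[j] - 1] = res
        elif res >= 0:
            seg[int(match_ordinal[j])].append(int(res))

    # maximal runs of deleted backbone columns, as ordinal ranges [a, b]
    k = 1
    while k <= m:
        if backbone[k - 1] >= 0:
            k += 1
            continue
        a = k
        while k <= m and backbone[k - 1] < 0:
            k += 1
        b = k - 1
        interior = [res for s in range(a, b) for res in seg[s]]
        for s in range(a, b):
            seg[s] = []
        need = b - a + 1
        fill = interior[:need]
        leftover = interior[need:]
        if len(fill) < need and seg[b]:
            take = min(need - len(fill), len(seg[b]))
            fill += seg[b][:take]
            seg[b] = seg[b][take:]
        if len(fill) < need and seg[a - 1]:
            take = min(need - len(fill), len(seg[a - 1]))
            fill = seg[a - 1][-take:] + fill
            seg[a - 1] = seg[a - 1][:-take]
        for offset, res in enumerate(fill):
            backbone[a - 1 + offset] = res
        if leftover:
            seg[b] = leftover + seg[b]
    return backbone, seg


def build_phmm(
    msa: Mapping[str, str] | Sequence[str],
    gap_threshold: float = 0.5,
    pseudocount: float = 1.0,
) -> ProfileHMM:
    """Estimate a profile HMM from an aligned set of sequences.

    Columns whose gap fraction is below ``gap_threshold`` become match
    states.  Emission and transition counts receive a Laplace
    ``pseudocount``; the background is the overall amino-acid frequency
    of the alignment (gaps excluded, lightly smoothed).
    """
    seqs = [s.upper() for s in (msa.values() if isinstance(msa, Mapping) else msa)]
    length = _check_alignment(seqs)
    n_seq = len(seqs)

    cols = np.array([[AA_INDEX.get(c, -1) for c in s] for s in seqs])  # -1 = gap
    gap_frac = (cols < 0).mean(axis=0)
    is_match = gap_frac < gap_threshold
    m = int(is_match.sum())
    if m == 0:
        raise ValidationError("no match columns at this gap threshold")

    # Background: MSA residue frequency mixed with 20% uniform.  The mix
    # keeps the log-odds of residues that are rare in a small seed
    # alignment bounded; a purely empirical background would give large
    # positive scores to residues the alignment never saw.
    bg_counts = np.bincount(cols[cols >= 0], minlength=20).astype(float)
    total = bg_counts.sum()
    freq = bg_counts / total if total > 0 else np.full(20, 1 / 20)
    bg = 0.8 * freq + 0.2 / 20

    emit = np.full((m, 20), pseudocount, dtype=float)
    # Transition counts indexed by source column k = 0..m.
    tcnt = {k: np.zeros(m + 1) for k in ("MM", "MI", "MD", "IM", "II", "DM", "DD")}

    match_ordinal = np.cumsum(is_match)  # ordinal of column j if it is a match col
    for s_idx in range(n_seq):
        backbone, seg = _sequence_path(cols[s_idx], is_match, match_ordinal, m)
        state, k = "M", 0  # begin state
        for kk in range(1, m + 1):
            for res in seg[kk - 1]:
                if state != "I" or k != kk - 1:
                    tcnt[state + "I"][kk - 1] += 1
                else:
                    tcnt["II"][kk - 1] += 1
                state, k = "I", kk - 1
            nxt = "M" if backbone[kk - 1] >= 0 else "D"
            tcnt[state + nxt][k] += 1
            state, k = nxt, kk
            if nxt == "M":
                emit[kk - 1, backbone[kk - 1]] += 1
        for res in seg[m]:
            if state != "I" or k != m:
                tcnt[state + "I"][m] += 1
            else:
                tcnt["II"][m] += 1
            state, k = "I", m
        tcnt[state + "M"][k] += 1  # transition into the end state

    emit /= emit.sum(axis=1, keepdims=True)

    t = {key: np.zeros(m + 1) for key in tcnt}
    for k in range(m + 1):
        last = k == m
        m_opts = ("MM", "MI") if last else ("MM", "MI", "MD")
        tot = sum(tcnt[o][k] + pseudocount for o in m_opts)
        for o in m_opts:
            t[o][k] = (tcnt[o][k] + pseudocount) / tot
        tot = tcnt["IM"][k] + tcnt["II"][k] + 2 * pseudocount
        t["IM"][k] = (tcnt["IM"][k] + pseudocount) / tot
        t["II"][k] = (tcnt["II"][k] + pseudocount) / tot
        if k >= 1:
            if last:
                t["DM"][k] = 1.0
            else:
                tot = tcnt["DM"][k] + tcnt["DD"][k] + 2 * pseudocount
                t["DM"][k] = (tcnt["DM"][k] + pseudocount) / tot
                t["DD"][k] = (tcnt["DD"][k] + pseudocount) / tot

    hmm = ProfileHMM(
        n_match_states=m,
        match_emissions=emit,
        insert_emissions=bg.copy(),
        background=bg,
        transitions=t,
    )
    hmm.validate()
    return hmm


def _delete_scan(a: np.ndarray, dd: np.ndarray) -> np.ndarray:
    """Solve ``d[k] = a[k] + dd[k] * d[k-1]`` (k >= 1, d[0] = 0), batched.

    ``a`` is (B, m+1); ``dd[k]`` multiplies ``d[k-1]``.  Solved in blocks
    with within-block cumulative products so long delete chains cannot
    underflow: within a block the product of at most ``_DSCAN_BLOCK``
    probabilities stays far from the float64 denormal range.
    """
    B, m1 = a.shape
    d = np.zeros_like(a)
    carry = np.zeros(B)
    dd64 = dd.astype(np.float64)
    for b in range(1, m1, _DSCAN_BLOCK):
        e = min(b + _DSCAN_BLOCK, m1)
        # float64 inside the block: the cumulative product of up to
        # _DSCAN_BLOCK transition probabilities must stay normalised.
        q = np.cumprod(dd64[b:e])
        s = np.cumsum(a[:, b:e].astype(np.float64) / q, axis=1)
        d[:, b:e] = q * (s + carry[:, None])
        carry = d[:, e - 1].astype(np.float64)
    return d


def _forward_batch(hmm: ProfileHMM, encoded: list[np.ndarray]) -> np.ndarray:
    """Forward log-odds (bits) for a batch of encoded sequences."""
    m = hmm.n_match_states
    t = hmm.transitions
    # float32 throughout: per-position rescaling keeps values near 1, so
    # single precision is ample and halves memory traffic on big scans.
    eodds = (hmm.match_emissions / hmm.background).T.astype(np.float32)  # (20, m)
    B = len(encoded)
    lengths = np.array([len(s) for s in encoded])
    lmax = int(lengths.max())
    # Residue index matrix padded with 0 (padded cells are never harvested).
    xs = np.zeros((B, lmax), dtype=np.intp)
    for i, s in enumerate(encoded):
        xs[i, : len(s)] = s

    f32 = np.float32
    mm, mi, md = t["MM"].astype(f32), t["MI"].astype(f32), t["MD"].astype(f32)
    im, ii = t["IM"].astype(f32), t["II"].astype(f32)
    dm, dd = t["DM"].astype(f32), t["DD"].astype(f32)
    dd_shift = np.concatenate(([0.0], dd[:-1])).astype(f32)  # t(D_{k-1} -> D_k)
    # dd_shift[1] multiplies d[0] = 0 (D_0 does not exist); keep the
    # cumulative products of the scan away from exact zero.
    dd_shift[1] = 1.0

    fM = np.zeros((B, m + 1), dtype=f32)
    fM[:, 0] = 1.0
    fI = np.zeros((B, m + 1), dtype=f32)
    a0 = np.zeros((B, m + 1), dtype=f32)
    a0[:, 1] = md[0]
    fD = _delete_scan(a0, dd_shift)
    log2acc = np.zeros(B)
    bits = np.full(B, np.nan)

    for pos in range(1, lmax + 1):
        E = eodds[xs[:, pos - 1]]  # (B, m)
        newM = np.zeros((B, m + 1), dtype=f32)
        newM[:, 1:] = E * (
            fM[:, :-1] * mm[:-1] + fI[:, :-1] * im[:-1] + fD[:, :-1] * dm[:-1]
        )
        newI = fM * mi + fI * ii
        # a[k] = newM[k-1] * t(M_{k-1} -> D_k)
        a = np.concatenate(
            (np.zeros((B, 1), dtype=f32), newM[:, :-1] * md[:-1]), axis=1
        )
        newD = _delete_scan(a, dd_shift)
        scale = np.maximum(
            newM.max(axis=1), np.maximum(newI.max(axis=1), newD.max(axis=1))
        )
        scale = np.where(scale > 0, scale, 1.0)
        fM = newM / scale[:, None]
        fI = newI / scale[:, None]
        fD = newD / scale[:, None]
        log2acc += np.log2(scale)
        done = lengths == pos
        if done.any():
            val = fM[done, m] * mm[m] + fI[done, m] * im[m] + fD[done, m] * dm[m]
            bits[done] = np.log2(val) + log2acc[done]
    return bits


def forward_bits(hmm: ProfileHMM, seq: str) -> float:
    """log2-odds of ``seq`` under the profile vs the background model,
    summed over all alignments (forward algorithm)."""
    return float(_forward_batch(hmm, [_encode_seq(seq)])[0])


def viterbi_bits(hmm: ProfileHMM, seq: str) -> float:
    """log2-odds of the single best alignment (Viterbi).  Always <=
    ``forward_bits`` on the same pair."""
    x = _encode_seq(seq)
    m = hmm.n_match_states
    t = hmm.transitions
    with np.errstate(divide="ignore"):
        lmm, lmi, lmd = np.log2(t["MM"]), np.log2(t["MI"]), np.log2(t["MD"])
        lim, lii = np.log2(t["IM"]), np.log2(t["II"])
        ldm, ldd = np.log2(t["DM"]), np.log2(t["DD"])
        le = np.log2(hmm.match_emissions / hmm.background)  # (m, 20)
    neg = -np.inf

    def dscan(vm: np.ndarray) -> np.ndarray:
        # vd[k] = max_{j<k} vm[j] + lmd[j] + sum_{l=j+1}^{k-1} ldd[l]
        cd = np.concatenate(([0.0], np.cumsum(ldd[1:])))  # cd[k] = sum ldd[1..k]
        base = vm[:-1] + lmd[:-1] - cd[:-1]
        run = np.maximum.accumulate(base)
        vd = np.full(m + 1, neg)
        vd[1:] = run + cd[:-1]
        return vd

    vM = np.full(m + 1, neg)
    vM[0] = 0.0
    vI = np.full(m + 1, neg)
    vD = dscan(vM)
    for pos in range(len(x)):
        e = le[:, x[pos]]
        newM = np.full(m + 1, neg)
        prev = np.maximum(
            vM[:-1] + lmm[:-1], np.maximum(vI[:-1] + lim[:-1], vD[:-1] + ldm[:-1])
        )
        newM[1:] = e + prev
        newI = np.maximum(vM + lmi, vI + lii)
        newD = dscan(newM)
        vM, vI, vD = newM, newI, newD
    return float(max(vM[m] + lmm[m], vI[m] + lim[m], vD[m] + ldm[m]))


def scan_proteome(
    hmm: ProfileHMM, proteome: Mapping[str, str], top_n: int
) -> list[HmmHit]:
    """Score every protein and return the ``top_n`` hits.

    Hits are sorted by descending bit score, ties broken by ascending
    protein id; ranks cover all scored proteins.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    if not proteome:
        raise ValidationError("empty proteome")
    ids = list(proteome)
    encoded = [_encode_seq(proteome[i]) for i in ids]
    # Batch proteins of similar length together so short sequences do
    # not pay for padding to the longest protein in the proteome.
    order = sorted(range(len(ids)), key=lambda i: len(encoded[i]))
    bits = np.empty(len(ids))
    for c in range(0, len(order), 128):
        chunk = order[c : c + 128]
        bits[chunk] = _forward_batch(hmm, [encoded[i] for i in chunk])
    order = sorted(range(len(ids)), key=lambda i: (-bits[i], ids[i]))
    hits = [
        HmmHit(protein_id=ids[i], score=float(bits[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]
    return hits[: min(top_n, len(hits))]


# ---------------------------------------------------------------------------
# plain-text model serialisation

_TKEYS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")


def save_phmm(hmm: ProfileHMM, path) -> None:
    """Write the model in a documented plain-text format: a header, the
    background vector, one emission line per match state and one
    transition line (7 values) per source column."""
    with open(path, "w") as fh:
        fh.write("citsift-phmm 1\n")
        fh.write(f"m {hmm.n_match_states}\n")
        fh.write(f"alphabet {ALPHABET}\n")
        fh.write("background " + " ".join(f"{v:.10e}" for v in hmm.background) + "\n")
        for row in hmm.match_emissions:
            fh.write("emit " + " ".join(f"{v:.10e}" for v in row) + "\n")
        for k in range(hmm.n_match_states + 1):
            vals = " ".join(f"{hmm.transitions[key][k]:.10e}" for key in _TKEYS)
            fh.write(f"trans {vals}\n")


def load_phmm(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("citsift-phmm"):
        raise ValidationError(f"{path}: not a citsift profile HMM file")
    m = int(lines[1].split()[1])
    bg = np.array([float(v) for v in lines[3].split()[1:]])
    emit = np.array(
        [[float(v) for v in lines[4 + i].split()[1:]] for i in range(m)]
    )
    trans_rows = np.array(
        [[float(v) for v in lines[4 + m + k].split()[1:]] for k in range(m + 1)]
    )
    transitions = {key: trans_rows[:, i].copy() for i, key in enumerate(_TKEYS)}
    hmm = ProfileHMM(
        n_match_states=m,
        match_emissions=emit,
        insert_emissions=bg.copy(),
        background=bg,
        transitions=transitions,
    )
    hmm.validate(tol=1e-6)
    return hmm
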