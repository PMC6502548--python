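"""Producer/non-producer homology asymmetry screen.

The screen compares each query protein against the proteomes of five
comparator species — two citrate producers (*A. kawachii*,
*Y. lipolytica*) and three non-producers (*A. flavus*, *A. terreus*,
*S. cerevisiae*) — and asks whether the best homolog is *strictly* more
identical in the producers than in the matched non-producers.

Alignment model
---------------
Best hits are found by optimal global alignment with affine gap costs
(Gotoh) under a BLOSUM62 substitution matrix; a gap of length ``g``
costs ``gap_open + g * gap_extend`` (the first gap column pays both).
Percent identity is ``100 * identical columns / alignment length`` with
gap columns included in the length.

Among co-optimal alignments the reported identity is well defined: the
DP optimises the triple ``(score, identical columns, -alignment
length)`` lexicographically, packed into a single 64-bit integer so the
whole recursion runs as exact integer numpy operations.  Scores are kept
in half-units internally so the default 0.5 gap-extension cost stays
integral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .sequences import ALPHABET, encode

#: Comparator species of the screen (filesystem-safe tokens).
PRODUCERS = ("A_kawachii", "Y_lipolytica")
ASPERGILLUS_NONPRODUCERS = ("A_flavus", "A_terreus")
YEAST_NONPRODUCER = "S_cerevisiae"
SPECIES = ("A_kawachii", "A_flavus", "A_terreus", "Y_lipolytica", "S_cerevisiae")

# Packing constants: value = score_halves * _KS + identical * _KI - length.
_KS = 1 << 40
_KI = 1 << 20
_NEG = -(1 << 62)


def _blosum62_half_units() -> np.ndarray:
    b = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, c in enumerate(ALPHABET):
            mat[i, j] = int(round(2 * b[a, c]))
    return mat


_BLOSUM62_2X = _blosum62_half_units()


def _matrix_half_units(matrix) -> np.ndarray:
    if matrix is None:
        return _BLOSUM62_2X
    mat = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, c in enumerate(ALPHABET):
            mat[i, j] = int(round(2 * matrix[a, c]))
    return mat


@dataclass(frozen=True)
class AlignmentStats:
    """Optimal global alignment summary for one sequence pair."""

    score: float  # affine-gap BLOSUM score
    identical: int  # identical columns of the reported optimum
    length: int  # alignment length, gap columns included

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identical / self.length


def _gotoh_batch(
    q: np.ndarray,
    db_mat: np.ndarray,
    db_lens: np.ndarray,
    gap_open: float,
    gap_extend: float,
    sub2: np.ndarray,
) -> list[AlignmentStats]:
    """Batched Gotoh DP of one query against padded db sequences.

    Maximises ``(score, identical, -length)`` lexicographically via the
    integer packing; returns one :class:`AlignmentStats` per db entry.
    """
    open2 = int(round(2 * gap_open))
    ext2 = int(round(2 * gap_extend))
    g_open = -(open2 + ext2) * _KS - 1  # first gap column: open + extend
    g_ext = -ext2 * _KS - 1

    n = len(q)
    D, lmax = db_mat.shape
    # Per-pair diagonal increment table: packed (substitution, identity, -1).
    enc = sub2 * _KS - 1
    enc[np.arange(20), np.arange(20)] += _KI

    j_idx = np.arange(lmax + 1, dtype=np.int64)
    M = np.full((D, lmax + 1), _NEG, dtype=np.int64)
    X = np.full((D, lmax + 1), _NEG, dtype=np.int64)
    Y = np.full((D, lmax + 1), _NEG, dtype=np.int64)
    M[:, 0] = 0
    Y[:, 1:] = g_open + (j_idx[1:] - 1) * g_ext

    for i in range(1, n + 1):
        diag = enc[q[i - 1]][db_mat]  # (D, lmax)
        best_prev = np.maximum(np.maximum(M, X), Y)
        newM = np.full_like(M, _NEG)
        newM[:, 1:] = best_prev[:, :-1] + diag
        newX = np.maximum(
            np.maximum(M + g_open, X + g_ext), Y + g_open
        )
        # Y scan within the row: a gap in b entered after column k and
        # extended to column j costs g_open + (j - k - 1) * g_ext.
        b = np.maximum(newM, newX) + g_open - (j_idx + 1) * g_ext
        run = np.maximum.accumulate(b, axis=1)
        newY = np.full_like(M, _NEG)
        newY[:, 1:] = run[:, :-1] + j_idx[1:] * g_ext
        M, X, Y = newM, newX, newY

    final = np.maximum(np.maximum(M, X), Y)
    out = []
    for d in range(D):
        v = int(final[d, db_lens[d]])
        s2, rem = divmod(v, _KS)
        if rem > _KS // 2:
            rem -= _KS
            s2 += 1
        ident = -((-rem) // _KI)
        length = ident * _KI - rem
        out.append(AlignmentStats(score=s2 / 2.0, identical=ident, length=length))
    return out


def align_global(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix=None,
) -> AlignmentStats:
    """Optimal global affine-gap alignment statistics for one pair."""
    qa = encode(a, "sequence a")
    qb = encode(b, "sequence b")
    sub2 = _matrix_half_units(matrix)
    return _gotoh_batch(
        qa, qb[None, :], np.array([len(qb)]), gap_open, gap_extend, sub2
    )[0]


def percent_identity(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix=None,
) -> float:
    """Percent identity of the optimal global alignment of ``a`` and
    ``b`` (best identity among score-co-optimal alignments)."""
    return align_global(a, b, gap_open, gap_extend, matrix).percent_identity


def best_hit(
    query: str,
    db: Mapping[str, str],
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix=None,
) -> tuple[str | None, float]:
    """Best database hit of ``query`` by alignment *score* (not
    identity); returns ``(hit_id, percent_identity_of_that_hit)``, or
    ``(None, 0.0)`` for an empty database.  Score ties break by
    ascending id."""
    if not db:
        return None, 0.0
    q = encode(query, "query")
    ids = list(db)
    enc_db = [encode(db[i], f"db sequence {i}") for i in ids]
    lens = np.array([len(e) for e in enc_db])
    mat = np.zeros((len(ids), int(lens.max())), dtype=np.intp)
    for r, e in enumerate(enc_db):
        mat[r, : len(e)] = e
    stats = _gotoh_batch(q, mat, lens, gap_open, gap_extend, _matrix_half_units(matrix))
    best = min(range(len(ids)), key=lambda i: (-stats[i].score, ids[i]))
    return ids[best], stats[best].percent_identity


@dataclass
class HomologProfile:
    """Best-hit percent identities of one query against the comparator
    species (0 when a species database yields no hit)."""

    query_id: str
    identity: dict[str, float]
    best_hit_id: dict[str, str | None]

    def __post_init__(self) -> None:
        for sp, val in self.identity.items():
            if not 0.0 <= val <= 100.0:
                raise ValidationError(f"identity[{sp}] = {val} outside [0, 100]")


def homolog_profile(
    query_id: str,
    query_seq: str,
    dbs: Mapping[str, Mapping[str, str]],
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> HomologProfile:
    """Best-hit identity of one query against every species database.

    The five comparator species must all be present; additional species
    (e.g. *A. nidulans*, *A. fumigatus*) are carried as extra columns and
    play no role in the asymmetry predicates.
    """
    missing = [sp for sp in SPECIES if sp not in dbs]
    if missing:
        raise ValidationError(f"missing homolog database(s): {missing}")
    identity: dict[str, float] = {}
    hits: dict[str, str | None] = {}
    for sp in dbs:
        hit, pid = best_hit(query_seq, dbs[sp], gap_open, gap_extend)
        identity[sp] = pid
        hits[sp] = hit
    return HomologProfile(query_id=query_id, identity=identity, best_hit_id=hits)


def producer_asymmetry(p: HomologProfile) -> tuple[bool, bool]:
    """The two homology criteria, both with *strict* inequality (ties
    fail):

    * ``aspergillus_ok`` — more identical to the *A. kawachii* homolog
      than to both the *A. flavus* and *A. terreus* homologs;
    * ``yeast_ok`` — more identical to the *Y. lipolytica* homolog than
      to the *S. cerevisiae* homolog.
    """
    missing = [sp for sp in SPECIES if sp not in p.identity]
    if missing:
        raise ValidationError(f"profile {p.query_id!r} missing species {missing}")
    ident = p.identity
    aspergillus_ok = all(
        ident["A_kawachii"] > ident[sp] for sp in ASPERGILLUS_NONPRODUCERS
    )
    yeast_ok = ident["Y_lipolytica"] > ident[YEAST_NONPRODUCER]
    return aspergillus_ok, yeast_ok
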