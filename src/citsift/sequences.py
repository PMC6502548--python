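"""Shared protein-sequence alphabet helpers."""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

#: The 20 canonical amino acids, alphabetical one-letter order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
GAP_CHARS = frozenset("-.")


def encode(seq: str, name: str = "sequence") -> np.ndarray:
    """Encode a protein as alphabet indices; unknown residues are an
    error (never silently skipped)."""
    if not seq:
        raise ValidationError(f"empty {name}")
    try:
        return np.array([AA_INDEX[c] for c in seq.upper()], dtype=np.intp)
    except KeyError:
        bad = sorted(set(seq.upper()) - set(ALPHABET))
        raise ValidationError(f"unknown residue(s) {bad} in {name}") from None


def validate_protein(seq: str, name: str = "sequence") -> str:
    """Return the upper-cased sequence, raising on illegal residues."""
    up = seq.upper()
    bad = set(up) - set(ALPHABET)
    if bad:
        raise ValidationError(f"illegal residue(s) {sorted(bad)} in {name}")
    return up
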