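"""Transmembrane-helix counts and localisation labels.

The cascade consumes *precomputed* predictions (a TSV of per-protein
helix counts, optionally with a localisation label, as produced by
external predictors).  A simple Kyte-Doolittle hydropathy counter is
provided as an optional stand-in for generating such tables from
sequence; it is a windowed heuristic, not a topology model.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

from .errors import ParseError
from .sequences import validate_protein

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Label accepted by the localisation filter.
PLASMA_MEMBRANE = "plasma membrane"


@dataclass(frozen=True)
class TopologyRecord:
    protein_id: str
    tm_helices: int
    localisation: str = "unknown"

    def __post_init__(self) -> None:
        if self.tm_helices < 0:
            raise ParseError(f"{self.protein_id}: negative helix count")


def has_tm(r: TopologyRecord) -> bool:
    """At least one predicted transmembrane helix."""
    return r.tm_helices >= 1


def parse_topology_table(path) -> dict[str, TopologyRecord]:
    """Read a TSV of ``protein_id  tm_helices  [localisation]``.

    A header line starting with ``protein_id`` is allowed and skipped.
    Missing localisation defaults to ``"unknown"``; duplicate ids and
    non-integer or negative helix counts are parse errors carrying the
    line number.
    """
    records: dict[str, TopologyRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "protein_id":
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            pid = fields[0]
            try:
                tm = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: helix count {fields[1]!r} is not an integer"
                ) from None
            if tm < 0:
                raise ParseError(f"{path}:{lineno}: negative helix count {tm}")
            if pid in records:
                raise ParseError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            loc = fields[2] if len(fields) > 2 and fields[2] else "unknown"
            records[pid] = TopologyRecord(pid, tm, loc)
    return records


def write_topology_table(records: dict[str, TopologyRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\ttm_helices\tlocalisation\n")
        for pid, rec in records.items():
            fh.write(f"{pid}\t{rec.tm_helices}\t{rec.localisation}\n")


def hydropathy_tm_count(seq: str, window: int = 19, threshold: float = 1.6) -> int:
    """Count hydrophobic stretches by greedy non-overlapping windows.

    Scans left to right; whenever the mean Kyte-Doolittle hydropathy of
    the next ``window`` residues exceeds ``threshold``, one helix is
    counted and the scan jumps past that window.  Sequences shorter than
    the window yield 0 with a warning.
    """
    seq = validate_protein(seq)
    n = len(seq)
    if n < window:
        warn(f"sequence of length {n} shorter than window {window}; count is 0")
        return 0
    kd = [KYTE_DOOLITTLE[c] for c in seq]
    # prefix sums -> O(1) window means
    pref = [0.0]
    for v in kd:
        pref.append(pref[-1] + v)
    count, i = 0, 0
    while i + window <= n:
        if (pref[i + window] - pref[i]) / window > threshold:
            count += 1
            i += window
        else:
            i += 1
    return count
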