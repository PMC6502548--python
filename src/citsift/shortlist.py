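"""Fusion of the three candidate tracks into the ranked shortlist.

Candidates arrive from three independent tracks — the profile-HMM
screen (``hmm``), the producer/non-producer homology screen
(``homology``) and the citrate-synthase neighbourhood (``proximity``) —
and pass through an ordered filter cascade with per-criterion drop-out
logging:

Minimal criteria (all tracks):
  1. mean avNtCov >= 1 in all five conditions;
  2. mean avNtCov >= 50 in the two key conditions (highest citrate
     production rate: NW186 -Fe_a; highest yield: NW186 +Fe_c);
  3. up-regulated in C1 (NW186 -Fe_a vs NW305 -Fe_a);
  4. up-regulated in C2 (NW186 +Fe_c vs NW186 +Fe_a).

Stringent criteria (homology track only):
  5. >= 1 predicted transmembrane helix;
  6. more identical to the A. kawachii homolog than to A. flavus and
     A. terreus (strict);
  7. more identical to the Y. lipolytica homolog than to S. cerevisiae
     (strict);
  8. up-regulated in C3 (NW305 -Fe_a vs NW305 ++Fe_a) — advisory by
     default (logged, non-blocking), because NW305 shifts to oxalate
     production under iron limitation.

Evaluation short-circuits at the first failing criterion purely for the
drop-out log; the overall verdict is the plain conjunction.  Survivors
are ranked by descending C1 log2 fold-change (the biologically most
relevant contrast for citrate export), ties by ascending protein id,
undefined fold-changes last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .conditions import CONDITIONS, CONTRASTS, KEY_CONDITIONS, RANKING_CONTRAST
from .errors import ParseError, ValidationError
from .expression import STRICT_FDR, STRICT_LOG2FC, UP_MODES, ContrastResult
from .homology import HomologProfile, producer_asymmetry
from .topology import TopologyRecord

TRACKS = ("hmm", "homology", "proximity")


@dataclass(frozen=True)
class PipelineConfig:
    """Cascade thresholds and track parameters."""

    cov_all: float = 1.0  # criterion 1 threshold (avNtCov, all conditions)
    cov_key: float = 50.0  # criterion 2 threshold (key conditions)
    up_mode: str = "lenient"  # "lenient" (log2FC > 0) or "strict"
    soft_c3: bool = True  # criterion 8 advisory (non-blocking)
    k: int = 10  # neighbourhood half-width of the proximity track
    top_n: int = 20  # HMM hits admitted to the hmm track
    pseudocount: float = 0.5  # CPM pseudocount of the contrasts

    def __post_init__(self) -> None:
        if self.up_mode not in UP_MODES:
            raise ValidationError(f"up_mode must be one of {UP_MODES}")

    def as_dict(self) -> dict:
        return {
            "cov_all": self.cov_all,
            "cov_key": self.cov_key,
            "up_mode": self.up_mode,
            "soft_c3": self.soft_c3,
            "k": self.k,
            "top_n": self.top_n,
            "pseudocount": self.pseudocount,
        }


@dataclass
class CandidateRecord:
    """One gene's full evidence row.

    ``cov`` maps condition -> (mean, sd) avNtCov; ``contrasts`` maps the
    three contrast names to (log2fc, fdr), either of which may be None
    for genes with no defined fold-change (zero coverage in parsed
    published data).
    """

    protein_id: str
    tracks: set[str] = field(default_factory=set)
    tm_helices: int = 0
    localisation: str = "unknown"
    cov: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    contrasts: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    homology: HomologProfile | None = None
    criteria_log: list[tuple[str, bool]] = field(default_factory=list)

    def log2fc(self, name: str) -> float | None:
        return self.contrasts.get(name, (None, None))[0]


def _up(rec: CandidateRecord, contrast_name: str, mode: str) -> bool:
    log2fc, fdr = rec.contrasts.get(contrast_name, (None, None))
    if log2fc is None:
        return False
    if mode == "lenient":
        return log2fc > 0
    return log2fc >= STRICT_LOG2FC and fdr is not None and fdr <= STRICT_FDR


def minimal_criteria(
    rec: CandidateRecord,
    mode: str = "lenient",
    cov_all: float = 1.0,
    cov_key: float = 50.0,
) -> tuple[bool, list[tuple[str, bool]]]:
    """Criteria 1-4, evaluated in order with short-circuit logging."""
    if mode not in UP_MODES:
        raise ValidationError(f"mode must be one of {UP_MODES}")
    missing = [c for c in CONDITIONS if c not in rec.cov]
    if missing:
        raise ValidationError(
            f"{rec.protein_id}: missing coverage for condition(s) {missing}"
        )
    log: list[tuple[str, bool]] = []

    def check(name: str, ok: bool) -> bool:
        log.append((name, ok))
        return ok

    ok = check(
        "min1_cov_all_conditions",
        all(
            rec.cov[c][0] is not None and rec.cov[c][0] >= cov_all
            for c in CONDITIONS
        ),
    )
    if ok:
        ok = check(
            "min2_cov_key_conditions",
            all(
                rec.cov[c][0] is not None and rec.cov[c][0] >= cov_key
                for c in KEY_CONDITIONS
            ),
        )
    if ok:
        ok = check("min3_up_C1", _up(rec, "C1", mode))
    if ok:
        ok = check("min4_up_C2", _up(rec, "C2", mode))
    return ok, log


def stringent_criteria(
    rec: CandidateRecord,
    mode: str = "lenient",
    soft_c3: bool = True,
) -> tuple[bool, list[tuple[str, bool]]]:
    """Criteria 5-8 of the homology track.

    Criterion 8 (up-regulation in C3) is advisory when ``soft_c3`` is
    true: its verdict is logged but does not block the candidate.
    """
    if "homology" in rec.tracks and rec.homology is None:
        raise ValidationError(
            f"{rec.protein_id}: on the homology track but has no homology profile"
        )
    if rec.homology is None:
        raise ValidationError(f"{rec.protein_id}: homology profile required")
    log: list[tuple[str, bool]] = []
    ok = rec.tm_helices >= 1
    log.append(("str5_tm_helix", ok))
    if ok:
        asp_ok, yeast_ok = producer_asymmetry(rec.homology)
        log.append(("str6_aspergillus_asymmetry", asp_ok))
        ok = asp_ok
        if ok:
            log.append(("str7_yeast_asymmetry", yeast_ok))
            ok = yeast_ok
    if ok:
        c3 = _up(rec, "C3", mode)
        log.append(("str8_up_C3_advisory" if soft_c3 else "str8_up_C3", c3))
        if not soft_c3:
            ok = c3
    return ok, log


@dataclass
class Shortlist:
    """Ranked survivors plus the full per-criterion drop-out log."""

    records: list[CandidateRecord]
    dropout_log: list[tuple[str, str, bool]]  # (gene, criterion, passed)
    provenance: dict = field(default_factory=dict)


def _sort_key(rec: CandidateRecord):
    fc = rec.log2fc(RANKING_CONTRAST)
    # Undefined fold-changes sort below all defined values.
    return (fc is None, -fc if fc is not None else 0.0, rec.protein_id)


def sort_records(records: Iterable[CandidateRecord]) -> list[CandidateRecord]:
    """Descending C1 log2FC, ties by ascending id, undefined last."""
    return sorted(records, key=_sort_key)


def build_shortlist(
    tracks: Mapping[str, Iterable[str]],
    contrasts: Mapping[str, ContrastResult],
    coverage: Mapping[str, pd.DataFrame],
    topology: Mapping[str, TopologyRecord],
    homology_profiles: Mapping[str, HomologProfile],
    config: PipelineConfig = PipelineConfig(),
    localisation: Mapping[str, str] | None = None,
    provenance: dict | None = None,
) -> Shortlist:
    """Evaluate every tracked candidate and rank the survivors.

    ``tracks`` maps track name -> candidate ids; ``contrasts`` must hold
    C1, C2 and C3; ``coverage`` maps each condition to the avNtCov
    summary of the whole matrix.  A candidate survives if it passes the
    minimal criteria via the hmm or proximity track, or the minimal plus
    stringent criteria via the homology track; multi-track candidates
    are deduplicated keeping the union of track labels.
    """
    unknown_tracks = set(tracks) - set(TRACKS)
    if unknown_tracks:
        raise ValidationError(f"unknown track(s) {sorted(unknown_tracks)}")
    for name in CONTRASTS:
        if name not in contrasts:
            raise ValidationError(f"missing contrast {name}")
    known_genes = set(contrasts["C1"].table.index)
    track_sets = {t: set(ids) for t, ids in tracks.items()}
    missing = sorted(set().union(*track_sets.values()) - known_genes) if track_sets else []
    if missing:
        raise ValidationError(
            f"tracked gene(s) absent from the expression matrix: {missing}"
        )

    records: dict[str, CandidateRecord] = {}
    for track in TRACKS:
        for gid in track_sets.get(track, ()):
            rec = records.setdefault(gid, CandidateRecord(protein_id=gid))
            rec.tracks.add(track)

    survivors: list[CandidateRecord] = []
    dropout: list[tuple[str, str, bool]] = []
    for gid in sorted(records):
        rec = records[gid]
        rec.cov = {
            cond: (float(df.loc[gid, "mean"]), float(df.loc[gid, "sd"]))
            for cond, df in coverage.items()
        }
        rec.contrasts = {
            name: (float(cr.table.loc[gid, "log2fc"]), float(cr.table.loc[gid, "fdr"]))
            for name, cr in contrasts.items()
        }
        top = topology.get(gid)
        if top is not None:
            rec.tm_helices = top.tm_helices
            rec.localisation = top.localisation
        if localisation and gid in localisation:
            rec.localisation = localisation[gid]
        rec.homology = homology_profiles.get(gid)

        min_ok, min_log = minimal_criteria(
            rec, config.up_mode, config.cov_all, config.cov_key
        )
        rec.criteria_log = list(min_log)
        passed = min_ok and bool(rec.tracks & {"hmm", "proximity"})
        if "homology" in rec.tracks and min_ok:
            str_ok, str_log = stringent_criteria(rec, config.up_mode, config.soft_c3)
            rec.criteria_log += str_log
            passed = passed or str_ok
        dropout += [(gid, crit, ok) for crit, ok in rec.criteria_log]
        if passed:
            survivors.append(rec)

    prov = {"config": config.as_dict()}
    if provenance:
        prov.update(provenance)
    return Shortlist(
        records=sort_records(survivors), dropout_log=dropout, provenance=prov
    )


# ---------------------------------------------------------------------------
# published shortlist fixture

#: (contrast name, reference-coverage column condition, test-coverage
#: column condition) of the three printed blocks, in file order.  Note
#: the printed fold-change of each block is oriented second-column vs
#: first-column; for C3 that is the *opposite* orientation of the
#: criterion-8 contrast (NW305 -Fe_a vs NW305 ++Fe_a), and the parser
#: stores the printed value verbatim.
_PUBLISHED_BLOCKS = (
    ("C1", "NW305 -Fe_a", "NW186 -Fe_a"),
    ("C2", "NW186 +Fe_a", "NW186 +Fe_c"),
    ("C3", "NW305 -Fe_a", "NW305 ++Fe_a"),
)


def _parse_number(cell: str, where: str) -> float | None:
    cell = cell.strip().replace("−", "-")
    if cell in ("#N/A", "NA", ""):
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"{where}: malformed number {cell!r}") from None


def _parse_mean_sd(cell: str, where: str) -> tuple[float | None, float | None]:
    parts = cell.split("±")
    if len(parts) != 2:
        raise ParseError(f"{where}: malformed 'mean ± sd' cell {cell!r}")
    mean_s, sd_s = (p.strip().replace("−", "-") for p in parts)
    if mean_s == "-" and sd_s == "-":
        return None, None
    try:
        return float(mean_s), float(sd_s)
    except ValueError:
        raise ParseError(f"{where}: malformed 'mean ± sd' cell {cell!r}") from None


def parse_published_shortlist(path=None) -> list[CandidateRecord]:
    """Parse the published 50-candidate shortlist table.

    Without ``path``, the transcription packaged with citsift is used.
    Columns: proteinId, tmhmm, then three blocks of (coverage ``mean ±
    sd`` for two conditions, log2FC, FDR).  ``#N/A`` fold-changes and
    ``− ± −`` coverages become ``None``.
    """
    if path is None:
        ref = resources.files("citsift").joinpath("data/published_shortlist.tsv")
        text = ref.read_text(encoding="utf-8")
        where_name = "published_shortlist.tsv"
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        where_name = str(path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    records = []
    for row_no, line in enumerate(lines[1:], start=2):
        where = f"{where_name}:{row_no}"
        fields = line.split("\t")
        if len(fields) != 14:
            raise ParseError(f"{where}: expected 14 columns, got {len(fields)}")
        pid = fields[0].strip()
        tm = int(fields[1])
        cov: dict[str, tuple[float | None, float | None]] = {}
        contrasts: dict[str, tuple[float | None, float | None]] = {}
        for b, (name, ref_cond, test_cond) in enumerate(_PUBLISHED_BLOCKS):
            base = 2 + 4 * b
            ref_cov = _parse_mean_sd(fields[base], f"{where} col {base + 1}")
            test_cov = _parse_mean_sd(fields[base + 1], f"{where} col {base + 2}")
            cov.setdefault(ref_cond, ref_cov)
            cov.setdefault(test_cond, test_cov)
            log2fc = _parse_number(fields[base + 2], f"{where} col {base + 3}")
            fdr = _parse_number(fields[base + 3], f"{where} col {base + 4}")
            contrasts[name] = (log2fc, fdr)
        records.append(
            CandidateRecord(
                protein_id=pid, tm_helices=tm, cov=cov, contrasts=contrasts
            )
        )
    return records


def write_shortlist_table(shortlist: Shortlist, path) -> None:
    """Write survivors in the published-table layout (``mean ± sd`` with
    two decimals, blocks C1/C2/C3)."""

    def cell(v: tuple[float | None, float | None]) -> str:
        if v[0] is None:
            return "- ± -"
        return f"{v[0]:.2f} ± {v[1]:.2f}"

    def num(v: float | None) -> str:
        return "#N/A" if v is None else f"{v:.2f}"

    with open(path, "w") as fh:
        header = ["proteinId", "tmhmm", "tracks"]
        for name, ref_cond, test_cond in _PUBLISHED_BLOCKS:
            header += [f"cov[{ref_cond}]", f"cov[{test_cond}]",
                       f"log2FC[{name}]", f"FDR[{name}]"]
        fh.write("\t".join(header) + "\n")
        for rec in shortlist.records:
            row = [rec.protein_id, str(rec.tm_helices), "+".join(sorted(rec.tracks))]
            for name, ref_cond, test_cond in _PUBLISHED_BLOCKS:
                fc, fdr = rec.contrasts.get(name, (None, None))
                row += [
                    cell(rec.cov.get(ref_cond, (None, None))),
                    cell(rec.cov.get(test_cond, (None, None))),
                    num(fc),
                    num(fdr),
                ]
            fh.write("\t".join(row) + "\n")


def write_dropout_log(shortlist: Shortlist, path) -> None:
    """One line per gene per evaluated criterion."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcriterion\tverdict\n")
        for gid, crit, ok in shortlist.dropout_log:
            fh.write(f"{gid}\t{crit}\t{'pass' if ok else 'fail'}\n")
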