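"""Readers and writers for the pipeline's plain-text formats.

All formats are deliberately simple text: FASTA (plain and aligned),
a GFF-like tab table for gene loci (1-based inclusive coordinates), a
counts TSV whose header encodes condition and replicate
(``NW186_minusFe_a_r1``), two-column label tables, a YAML-ish key-value
config, and a JSON run manifest with input hashes.  Every writer's
output round-trips through the matching reader.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser

from . import __version__
from .conditions import condition_for, token_for
from .errors import ParseError, ValidationError
from .expression import ContrastResult, ExpressionMatrix
from .proximity import GeneLocus
from .sequences import ALPHABET, GAP_CHARS


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, aligned: bool = False) -> dict[str, str]:
    """Order-preserving ``id -> sequence`` map.

    Headers are truncated at the first whitespace; sequences are
    upper-cased; duplicate ids and illegal residues raise.  With
    ``aligned=True``, gap characters are permitted.
    """
    allowed = set(ALPHABET) | (GAP_CHARS if aligned else set())
    out: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0] if header.split() else ""
            if not name:
                raise ParseError(f"{path}: record with empty header")
            if name in out:
                raise ParseError(f"{path}: duplicate id {name!r}")
            seq = seq.upper()
            bad = set(seq) - allowed
            if bad:
                raise ParseError(
                    f"{path}: illegal residue(s) {sorted(bad)} in record {name!r}"
                )
            out[name] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# counts

def sample_name(condition: str, replicate: int) -> str:
    """``"NW186 -Fe_a"``, 1 -> ``"NW186_minusFe_a_r1"``."""
    return f"{token_for(condition)}_r{replicate}"


def split_sample_name(name: str) -> tuple[str, int]:
    token, _, rep = name.rpartition("_r")
    try:
        return condition_for(token), int(rep)
    except (KeyError, ValueError):
        raise ValidationError(
            f"sample name {name!r} is not <condition_token>_r<replicate>"
        ) from None


def read_counts(path, read_length: int = 100) -> ExpressionMatrix:
    """Read a counts TSV (columns: gene_id, length, then samples)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "length"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("gene_id", "length")]
    conditions = [split_sample_name(c)[0] for c in sample_cols]
    counts = df[sample_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        raise ParseError(f"{path}: non-integer counts")
    return ExpressionMatrix(
        gene_ids=df["gene_id"].tolist(),
        counts=counts,
        sample_names=sample_cols,
        sample_conditions=conditions,
        gene_lengths=df["length"].to_numpy(),
        read_length=read_length,
    )


def write_counts(m: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(m.counts, columns=m.sample_names)
    df.insert(0, "length", m.gene_lengths.astype(int))
    df.insert(0, "gene_id", m.gene_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loci and label tables

_LOCI_COLUMNS = ("contig", "start", "end", "strand", "gene_id")


def read_loci(path) -> list[GeneLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str})
    missing = set(_LOCI_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        GeneLocus(
            gene_id=row.gene_id,
            contig=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
        )
        for row in df.itertuples()
    ]


def write_loci(loci, path) -> None:
    df = pd.DataFrame(
        [(l.contig, l.start, l.end, l.strand, l.gene_id) for l in loci],
        columns=_LOCI_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_label_table(path) -> dict[str, str]:
    """Two-column TSV ``id -> label`` (e.g. localisation); optional header."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] in ("protein_id", "gene_id", "id"):
                continue
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if fields[0] in out:
                raise ParseError(f"{path}:{lineno}: duplicate id {fields[0]!r}")
            out[fields[0]] = fields[1]
    return out


def write_label_table(labels: Mapping[str, str], path, header: str = "protein_id\tlabel") -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for key, val in labels.items():
            fh.write(f"{key}\t{val}\n")


def read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_id_list(ids, path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


# ---------------------------------------------------------------------------
# contrast table

def write_contrast_table(cr: ContrastResult, path) -> None:
    """TSV with coverages rendered as ``mean ± sd`` (2 decimals)."""
    t = cr.table
    with open(path, "w") as fh:
        test, ref = cr.contrast
        fh.write(
            "gene_id\tlog2fc\tpvalue\tfdr\t"
            f"cov[{token_for(test)}]\tcov[{token_for(ref)}]\n"
        )
        for gid, row in t.iterrows():
            fh.write(
                f"{gid}\t{row['log2fc']:.4f}\t{row['pvalue']:.4g}\t{row['fdr']:.4g}\t"
                f"{row['cov_test_mean']:.2f} ± {row['cov_test_sd']:.2f}\t"
                f"{row['cov_ref_mean']:.2f} ± {row['cov_ref_sd']:.2f}\n"
            )


# ---------------------------------------------------------------------------
# config and manifest

def load_config(path) -> dict:
    """Plain key-value configuration (YAML subset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a key-value mapping")
    return data


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    seed: int | None
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)  # stage -> path
    version: str = __version__

    def add_input(self, path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def add_output(self, stage: str, path) -> None:
        if not Path(path).exists():
            raise ValidationError(f"stage {stage!r} output missing: {path}")
        self.outputs[stage] = str(path)

    def write(self, path) -> None:
        for stage, out in self.outputs.items():
            if not Path(out).exists():
                raise ValidationError(f"stage {stage!r} output missing: {out}")
        with open(path, "w") as fh:
            json.dump(
                {
                    "tool": "citsift",
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
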