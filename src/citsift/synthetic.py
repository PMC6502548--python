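"""Synthetic five-condition study with a planted citrate exporter.

The generator emulates the study design the cascade was built for: two
strains under iron limitation plus a supplement comparison, five
conditions with two biological replicates each, and a proteome with
coordinates, topology predictions, localisation labels, comparator-
species homolog databases and a seed alignment of "characterised
transporters".  One (configurable) planted gene carries the full
exporter evidence signature:

* negative-binomial counts with a ``+planted_effect_log2fc`` shift in
  all three diagnostic contrasts and high coverage (~150x / ~350x) in
  the two key conditions, against background genes with no systematic
  contrast;
* a protein with ``tm_helix_count_planted`` hydrophobic stretches that
  the hydropathy counter detects exactly;
* homologs that are ``producer_identity_gap`` percentage points more
  identical in the citrate-producing comparator species than in the
  non-producers (background decoy homologs are symmetric);
* placement within 10 loci of the citrate-synthase anchor ``citA``;
* a seed alignment derived from the planted protein, so the profile-HMM
  track fires on it.

Everything is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .conditions import CONDITIONS, N_REPLICATES
from .errors import ValidationError
from .expression import ExpressionMatrix
from .homology import PRODUCERS, SPECIES
from .proximity import GeneLocus
from .sequences import ALPHABET
from .topology import PLASMA_MEMBRANE
from . import io as cio

#: Residues used for planted transmembrane helices (all strongly
#: hydrophobic on the Kyte-Doolittle scale) and for the hydrophilic
#: linkers between them.
HELIX_RESIDUES = "AILVFM"
LINKER_RESIDUES = "DEKRNQSTGP"
HELIX_LENGTH = 19  # matches the hydropathy counter's window

#: Target mean avNtCov of the planted gene in the two key conditions
#: (condition of highest citrate production rate / highest total yield).
PLANTED_COV_RATE = 150.0
PLANTED_COV_YIELD = 350.0

#: Best-hit percent identity of planted homologs in producer species.
PRODUCER_IDENTITY = 80.0

#: Background gene coverage: lognormal(median, sigma) per gene.
BACKGROUND_COV_MEDIAN = 30.0
BACKGROUND_COV_SIGMA = 1.0

#: Fraction of background proteins labelled plasma membrane.
PM_FRACTION = 0.08

ANCHOR_ID = "citA"


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the generator.

    The defaults are the study conditions all recovery tests run under;
    ``planted_effect_log2fc=0`` is the null calibration (the planted
    gene keeps its coverage but loses every contrast).
    """

    n_genes: int = 500
    seed: int = 0
    read_length: int = 100
    gene_length_range: tuple[int, int] = (450, 1500)
    libsize_range: tuple[int, int] = (400_000, 600_000)
    nb_dispersion: float = 0.05
    planted_effect_log2fc: float = 3.0
    n_planted: int = 1
    tm_helix_count_planted: int = 12
    producer_identity_gap: float = 15.0

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValidationError("n_genes must be >= 50")
        if self.n_planted < 0:
            raise ValidationError("n_planted must be >= 0")
        if self.n_planted > self.n_genes:
            raise ValidationError("n_planted exceeds n_genes")
        if self.planted_effect_log2fc < 0:
            raise ValidationError("planted_effect_log2fc must be >= 0")
        for name in ("gene_length_range", "libsize_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValidationError(f"{name} must be a non-empty positive range")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.tm_helix_count_planted < 1:
            raise ValidationError("tm_helix_count_planted must be >= 1")
        if not 0 <= self.producer_identity_gap < PRODUCER_IDENTITY:
            raise ValidationError("producer_identity_gap out of range")


@dataclass
class SyntheticDataset:
    """A complete fake study (see module docstring)."""

    expression: ExpressionMatrix
    proteome: dict[str, str]
    loci: list[GeneLocus]
    homolog_dbs: dict[str, dict[str, str]]
    tm_counts: dict[str, int]
    localisation: dict[str, str]
    seed_msa: dict[str, str]
    truth: set[str]
    config: SimConfig | None = None


def _planted_coverage_targets(effect: float) -> dict[str, float]:
    """Per-condition expected avNtCov of a planted gene: the effect is
    present in all three contrasts (C1, C2, C3) simultaneously."""
    f = 2.0 ** effect
    return {
        "NW186 -Fe_a": PLANTED_COV_RATE,
        "NW305 -Fe_a": PLANTED_COV_RATE / f,
        "NW305 ++Fe_a": PLANTED_COV_RATE / f**2,
        "NW186 +Fe_c": PLANTED_COV_YIELD,
        "NW186 +Fe_a": PLANTED_COV_YIELD / f,
    }


def _planted_protein(rng: np.random.Generator, n_helices: int) -> str:
    """Alternating hydrophilic linkers and 19-residue hydrophobic
    helices; built so the greedy hydropathy counter finds exactly
    ``n_helices`` stretches."""
    parts = []
    for i in range(n_helices + 1):
        linker_len = int(rng.integers(10, 15))
        parts.append("".join(rng.choice(list(LINKER_RESIDUES), linker_len)))
        if i < n_helices:
            parts.append("".join(rng.choice(list(HELIX_RESIDUES), HELIX_LENGTH)))
    return "".join(parts)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point-substitute each site with probability ``rate`` (no indels),
    always to a different residue."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [a for a in ALPHABET if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw: var = mu + dispersion * mu^2."""
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the full study deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_bg = config.n_genes - config.n_planted
    if n_bg < 1:
        raise ValidationError("need at least one background gene")

    bg_ids = [f"g{i:04d}" for i in range(n_bg)]
    planted_ids = [f"g_planted_{j}" for j in range(config.n_planted)]
    # citA replaces one background id (the anchor of the proximity track).
    anchor_pos = int(rng.integers(n_bg))
    bg_ids[anchor_pos] = ANCHOR_ID
    gene_ids = bg_ids + planted_ids

    # --- proteome and gene lengths -------------------------------------
    lo, hi = config.gene_length_range
    bg_lengths = rng.integers(lo, hi + 1, size=n_bg)
    proteome: dict[str, str] = {}
    aa = list(ALPHABET)
    for gid, glen in zip(bg_ids, bg_lengths):
        proteome[gid] = "".join(rng.choice(aa, max(30, int(glen) // 3)))
    archetype = _planted_protein(rng, config.tm_helix_count_planted)
    planted_seqs = (
        [archetype]
        + [_mutate(rng, archetype, 0.02) for _ in range(max(0, config.n_planted - 1))]
    )[: config.n_planted]
    for gid, seq in zip(planted_ids, planted_seqs):
        proteome[gid] = seq
    gene_lengths = np.concatenate(
        [bg_lengths, [3 * len(s) for s in planted_seqs]]
    ).astype(int)

    # --- counts ---------------------------------------------------------
    bg_cov = BACKGROUND_COV_MEDIAN * np.exp(
        rng.normal(0.0, BACKGROUND_COV_SIGMA, size=n_bg)
    )
    targets = _planted_coverage_targets(config.planted_effect_log2fc)
    cov = np.empty((config.n_genes, len(CONDITIONS)))
    for ci, cond in enumerate(CONDITIONS):
        cov[:n_bg, ci] = bg_cov
        cov[n_bg:, ci] = targets[cond]
    mu_raw = cov * gene_lengths[:, None] / config.read_length
    totals = mu_raw.sum(axis=0)

    sample_names, sample_conditions, count_cols = [], [], []
    for ci, cond in enumerate(CONDITIONS):
        for rep in range(1, N_REPLICATES + 1):
            libsize = int(rng.integers(*config.libsize_range))
            mu = mu_raw[:, ci] * (libsize / totals[ci])
            count_cols.append(_nb_counts(rng, mu, config.nb_dispersion))
            sample_names.append(cio.sample_name(cond, rep))
            sample_conditions.append(cond)
    expression = ExpressionMatrix(
        gene_ids=gene_ids,
        counts=np.column_stack(count_cols),
        sample_names=sample_names,
        sample_conditions=sample_conditions,
        gene_lengths=gene_lengths,
        read_length=config.read_length,
    )

    # --- loci: two contigs; planted gene 0 within 10 loci of citA -------
    order = list(gene_ids)
    rng.shuffle(order)
    special = [g for g in (ANCHOR_ID, planted_ids[0] if planted_ids else None) if g]
    order = [g for g in order if g not in special]
    half = len(order) // 2
    contig_genes = {"contig_1": order[:half], "contig_2": order[half:]}
    c1 = contig_genes["contig_1"]
    apos = int(rng.integers(len(c1) + 1))
    c1.insert(apos, ANCHOR_ID)
    if planted_ids:
        offset = int(rng.integers(1, 11)) * (1 if rng.random() < 0.5 else -1)
        ppos = min(max(apos + offset, 0), len(c1))
        c1.insert(ppos, planted_ids[0])
    length_of = dict(zip(gene_ids, gene_lengths))
    loci = []
    for contig, genes in contig_genes.items():
        pos = 1
        for gid in genes:
            start = pos + int(rng.integers(200, 1000))
            end = start + int(length_of[gid]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(GeneLocus(gid, contig, start, end, strand))
            pos = end

    # --- topology and localisation --------------------------------------
    tm_counts, localisation = {}, {}
    for gid in bg_ids:
        tm_counts[gid] = 0 if rng.random() < 0.55 else int(rng.integers(1, 15))
        localisation[gid] = PLASMA_MEMBRANE if rng.random() < PM_FRACTION else "other"
    localisation[ANCHOR_ID] = "other"
    for gid in planted_ids:
        tm_counts[gid] = config.tm_helix_count_planted
        localisation[gid] = PLASMA_MEMBRANE

    # --- homolog databases ----------------------------------------------
    pm_bg = [g for g in bg_ids if localisation[g] == PLASMA_MEMBRANE and g != ANCHOR_ID]
    n_decoys = min(6, len(pm_bg))
    decoy_src = [pm_bg[i] for i in sorted(rng.choice(len(pm_bg), n_decoys, replace=False))] if n_decoys else []
    homolog_dbs: dict[str, dict[str, str]] = {}
    for sp in SPECIES:
        ident = PRODUCER_IDENTITY if sp in PRODUCERS else (
            PRODUCER_IDENTITY - config.producer_identity_gap
        )
        db: dict[str, str] = {}
        for gid, seq in zip(planted_ids, planted_seqs):
            db[f"{sp}_hom_{gid}"] = _mutate(rng, seq, 1.0 - ident / 100.0)
        for gid in decoy_src:
            db[f"{sp}_dec_{gid}"] = _mutate(rng, proteome[gid], 0.30)
        for i in range(2):
            db[f"{sp}_rnd_{i}"] = "".join(rng.choice(aa, int(rng.integers(150, 400))))
        homolog_dbs[sp] = db

    # --- seed alignment ---------------------------------------------------
    seed_msa: dict[str, str] = {"seed_0": archetype}
    for i in range(1, 6):
        mut = list(_mutate(rng, archetype, 0.10))
        dele = rng.random(len(mut)) < 0.02
        for j in np.flatnonzero(dele):
            mut[j] = "-"
        seed_msa[f"seed_{i}"] = "".join(mut)

    return SyntheticDataset(
        expression=expression,
        proteome=proteome,
        loci=loci,
        homolog_dbs=homolog_dbs,
        tm_counts=tm_counts,
        localisation=localisation,
        seed_msa=seed_msa,
        truth=set(planted_ids),
        config=config,
    )


# ---------------------------------------------------------------------------
# on-disk layout

def write_dataset(ds: SyntheticDataset, directory) -> dict[str, str]:
    """Write every artefact as plain text; returns ``name -> path``.

    Files: counts.tsv, proteome.fasta, loci.gff3, homologs_<species>.fasta,
    tm_counts.tsv, localisation.tsv, seed_msa.afa, truth.txt.  The layout
    round-trips losslessly through :func:`read_dataset`.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(d / name)
        return d / name

    cio.write_counts(ds.expression, _p("counts.tsv"))
    cio.write_fasta(ds.proteome, _p("proteome.fasta"))
    cio.write_loci(ds.loci, _p("loci.gff3"))
    for sp, db in ds.homolog_dbs.items():
        cio.write_fasta(db, _p(f"homologs_{sp}.fasta"))
    cio.write_label_table(
        {g: str(ds.tm_counts[g]) for g in ds.expression.gene_ids},
        _p("tm_counts.tsv"),
        header="protein_id\ttm_helices",
    )
    cio.write_label_table(
        {g: ds.localisation[g] for g in ds.expression.gene_ids},
        _p("localisation.tsv"),
        header="protein_id\tlocalisation",
    )
    cio.write_fasta(ds.seed_msa, _p("seed_msa.afa"))
    cio.write_id_list(sorted(ds.truth), _p("truth.txt"))
    return paths


def read_dataset(directory) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset`."""
    d = Path(directory)
    homolog_dbs = {
        sp: cio.read_fasta(d / f"homologs_{sp}.fasta") for sp in SPECIES
    }
    return SyntheticDataset(
        expression=cio.read_counts(d / "counts.tsv"),
        proteome=cio.read_fasta(d / "proteome.fasta"),
        loci=cio.read_loci(d / "loci.gff3"),
        homolog_dbs=homolog_dbs,
        tm_counts={k: int(v) for k, v in cio.read_label_table(d / "tm_counts.tsv").items()},
        localisation=cio.read_label_table(d / "localisation.tsv"),
        seed_msa=cio.read_fasta(d / "seed_msa.afa", aligned=True),
        truth=set(cio.read_id_list(d / "truth.txt")),
    )


def dataset_equal(a: SyntheticDataset, b: SyntheticDataset) -> bool:
    """Field-wise equality of the data content (config excluded)."""
    ea, eb = a.expression, b.expression
    return (
        ea.gene_ids == eb.gene_ids
        and np.array_equal(ea.counts, eb.counts)
        and ea.sample_names == eb.sample_names
        and np.array_equal(ea.gene_lengths, eb.gene_lengths)
        and a.proteome == b.proteome
        and a.loci == b.loci
        and a.homolog_dbs == b.homolog_dbs
        and a.tm_counts == b.tm_counts
        and a.localisation == b.localisation
        and a.seed_msa == b.seed_msa
        and a.truth == b.truth
    )
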