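"""End-to-end orchestration of the three tracks and the cascade.

``run_pipeline`` takes a complete dataset (generated or read from disk)
and produces the ranked shortlist plus all intermediate evidence; the
CLI and the recovery experiments are thin wrappers around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .conditions import CONDITIONS, CONTRASTS
from .errors import ValidationError
from .expression import ContrastResult, av_nt_cov, contrast
from .homology import HomologProfile, homolog_profile
from .phmm import HmmHit, ProfileHMM, build_phmm, scan_proteome
from .proximity import neighbourhood
from .shortlist import (
    CandidateRecord,
    PipelineConfig,
    Shortlist,
    build_shortlist,
    minimal_criteria,
)
from .synthetic import ANCHOR_ID, SyntheticDataset
from .topology import PLASMA_MEMBRANE, TopologyRecord


@dataclass
class PipelineResult:
    shortlist: Shortlist
    tracks: dict[str, set[str]]
    contrasts: dict[str, ContrastResult]
    coverage: dict
    hmm: ProfileHMM | None = None
    hmm_hits: list[HmmHit] = field(default_factory=list)
    homology_profiles: dict[str, HomologProfile] = field(default_factory=dict)
    topology: dict[str, TopologyRecord] = field(default_factory=dict)


def expression_stage(ds: SyntheticDataset, config: PipelineConfig):
    """All three contrasts plus per-condition coverage summaries."""
    m = ds.expression
    contrasts = {
        name: contrast(m, test, ref, pseudocount=config.pseudocount)
        for name, (test, ref) in CONTRASTS.items()
    }
    coverage = {cond: av_nt_cov(m, cond) for cond in CONDITIONS}
    return contrasts, coverage

def hmm_track(ds: SyntheticDataset, config: PipelineConfig):
    """Build the profile from the seed alignment and scan the proteome."""
    hmm = build_phmm(ds.seed_msa)
    hits = scan_proteome(hmm, ds.proteome, top_n=config.top_n)
    return hmm, hits


def homology_track_queries(ds: SyntheticDataset) -> list[str]:
    """The homology track: every predicted plasma-membrane protein."""
    return [
        gid
        for gid in ds.expression.gene_ids
        if ds.localisation.get(gid) == PLASMA_MEMBRANE
    ]


def homology_track(
    ds: SyntheticDataset, queries: list[str] | None = None
) -> dict[str, HomologProfile]:
    """Profile plasma-membrane proteins against the five comparator-
    species databases."""
    if queries is None:
        queries = homology_track_queries(ds)
    return {
        gid: homolog_profile(gid, ds.proteome[gid], ds.homolog_dbs)
        for gid in queries
    }


def _passes_minimal(gid, contrasts, coverage, config: PipelineConfig) -> bool:
    """Minimal criteria 1-4 for one gene (same rule the cascade applies)."""
    rec = CandidateRecord(
        protein_id=gid,
        cov={
            cond: (float(df.loc[gid, "mean"]), float(df.loc[gid, "sd"]))
            for cond, df in coverage.items()
        },
        contrasts={
            name: (float(cr.table.loc[gid, "log2fc"]), float(cr.table.loc[gid, "fdr"]))
            for name, cr in contrasts.items()
        },
    )
    ok, _ = minimal_criteria(rec, config.up_mode, config.cov_all, config.cov_key)
    return ok


def run_pipeline(
    ds: SyntheticDataset,
    config: PipelineConfig = PipelineConfig(),
    anchor: str = ANCHOR_ID,
) -> PipelineResult:
    """Run the three tracks and the filter cascade on a dataset."""
    missing = [g for g in ds.expression.gene_ids if g not in ds.proteome]
    if missing:
        raise ValidationError(f"genes without protein sequence: {missing[:5]}...")

    contrasts, coverage = expression_stage(ds, config)
    hmm, hits = hmm_track(ds, config)
    pm_queries = homology_track_queries(ds)
    # Stringent (homology) criteria are only ever evaluated for
    # candidates that survive the minimal cascade, so the costly
    # alignment profiling is restricted to those.
    profiled = [
        gid
        for gid in pm_queries
        if _passes_minimal(gid, contrasts, coverage, config)
    ]
    profiles = homology_track(ds, profiled)
    tracks = {
        "hmm": {h.protein_id for h in hits},
        "homology": set(pm_queries),
        "proximity": neighbourhood(ds.loci, anchor, k=config.k),
    }
    topology = {
        gid: TopologyRecord(
            gid, ds.tm_counts.get(gid, 0), ds.localisation.get(gid, "unknown")
        )
        for gid in ds.expression.gene_ids
    }
    shortlist = build_shortlist(
        tracks=tracks,
        contrasts=contrasts,
        coverage=coverage,
        topology=topology,
        homology_profiles=profiles,
        config=config,
    )
    return PipelineResult(
        shortlist=shortlist,
        tracks=tracks,
        contrasts=contrasts,
        coverage=coverage,
        hmm=hmm,
        hmm_hits=hits,
        homology_profiles=profiles,
        topology=topology,
    )
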