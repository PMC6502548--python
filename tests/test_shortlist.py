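"""The filter cascade, ranking rules, and the published-table parser."""

import pytest

from citsift import (
    CandidateRecord,
    PipelineConfig,
    minimal_criteria,
    parse_published_shortlist,
    run_pipeline,
    sort_records,
    stringent_criteria,
)
from citsift.conditions import CONDITIONS
from citsift.errors import ParseError, ValidationError
from citsift.homology import SPECIES, HomologProfile
from citsift.shortlist import build_shortlist


def _cov(values):
    return {cond: (v, 0.1) for cond, v in zip(CONDITIONS, values)}


def _record(**kw):
    defaults = dict(
        protein_id="x",
        tracks={"hmm"},
        tm_helices=12,
        # order: NW305 -Fe_a, NW305 ++Fe_a, NW186 -Fe_a, NW186 +Fe_a, NW186 +Fe_c
        cov=_cov([14.61, 4.73, 139.89, 34.03, 350.11]),
        contrasts={"C1": (3.42, 0.0), "C2": (3.30, 0.0), "C3": (1.75, 0.0)},
    )
    defaults.update(kw)
    return CandidateRecord(**defaults)


def _profile(kaw=80, fla=60, ter=55, lip=50, cer=30):
    return HomologProfile(
        query_id="x",
        identity={"A_kawachii": kaw, "A_flavus": fla, "A_terreus": ter,
                  "Y_lipolytica": lip, "S_cerevisiae": cer},
        best_hit_id={sp: None for sp in SPECIES},
    )


class TestMinimalCriteria:
    def test_published_top_row_passes(self):
        ok, log = minimal_criteria(_record())
        assert ok and [v for _, v in log] == [True, True, True, True]

    def test_low_coverage_short_circuits(self):
        rec = _record(cov=_cov([0.5, 4.73, 139.89, 34.03, 350.11]))
        ok, log = minimal_criteria(rec)
        assert not ok
        assert log == [("min1_cov_all_conditions", False)]

    def test_key_coverage_boundary_is_inclusive(self):
        rec = _record(cov=_cov([14.61, 4.73, 50.0, 34.03, 50.0]))
        ok, log = minimal_criteria(rec)
        assert ok and ("min2_cov_key_conditions", True) in log

    def test_strict_mode_enforces_fdr(self):
        rec = _record(contrasts={"C1": (0.70, 0.50), "C2": (3.3, 0.0), "C3": (1.0, 0.0)})
        assert minimal_criteria(rec, mode="lenient")[0]
        ok, log = minimal_criteria(rec, mode="strict")
        assert not ok and log[-1] == ("min3_up_C1", False)

    def test_missing_condition_coverage_is_error(self):
        rec = _record()
        del rec.cov["NW186 +Fe_c"]
        with pytest.raises(ValidationError, match="NW186"):
            minimal_criteria(rec)


class TestStringentCriteria:
    def test_no_tm_helix_fails_first(self):
        rec = _record(tracks={"homology"}, tm_helices=0, homology=_profile())
        ok, log = stringent_criteria(rec)
        assert not ok and log == [("str5_tm_helix", False)]

    def test_asymmetry_and_advisory_c3(self):
        rec = _record(tracks={"homology"}, homology=_profile())
        ok, log = stringent_criteria(rec)
        assert ok
        assert [n for n, _ in log] == [
            "str5_tm_helix",
            "str6_aspergillus_asymmetry",
            "str7_yeast_asymmetry",
            "str8_up_C3_advisory",
        ]

    def test_c3_down_passes_when_advisory(self):
        # the published top candidate is C3-down yet was retained
        rec = _record(tracks={"homology"}, homology=_profile(),
                      contrasts={"C1": (3.42, 0.0), "C2": (3.3, 0.0), "C3": (-1.75, 0.0)})
        ok, log = stringent_criteria(rec, soft_c3=True)
        assert ok and log[-1] == ("str8_up_C3_advisory", False)

    def test_c3_down_blocks_when_hard(self):
        rec = _record(tracks={"homology"}, homology=_profile(),
                      contrasts={"C1": (3.42, 0.0), "C2": (3.3, 0.0), "C3": (-1.75, 0.0)})
        ok, _ = stringent_criteria(rec, soft_c3=False)
        assert not ok

    def test_missing_profile_is_error(self):
        rec = _record(tracks={"homology"}, homology=None)
        with pytest.raises(ValidationError, match="profile"):
            stringent_criteria(rec)


class TestSorting:
    def test_descending_with_ties_by_id(self):
        recs = [
            _record(protein_id="b", contrasts={"C1": (1.0, 0.0)}),
            _record(protein_id="a", contrasts={"C1": (1.0, 0.0)}),
            _record(protein_id="c", contrasts={"C1": (2.0, 0.0)}),
        ]
        assert [r.protein_id for r in sort_records(recs)] == ["c", "a", "b"]

    def test_undefined_sorts_last(self):
        recs = [
            _record(protein_id="nan", contrasts={"C1": (None, None)}),
            _record(protein_id="neg", contrasts={"C1": (-5.0, 0.9)}),
        ]
        assert [r.protein_id for r in sort_records(recs)] == ["neg", "nan"]


class TestBuildShortlist:
    def test_empty_tracks_give_empty_shortlist(self, small_result, small_dataset):
        sl = build_shortlist(
            tracks={},
            contrasts=small_result.contrasts,
            coverage=small_result.coverage,
            topology=small_result.topology,
            homology_profiles={},
        )
        assert sl.records == [] and sl.provenance["config"]["cov_key"] == 50.0

    def test_unknown_gene_in_track_is_error(self, small_result):
        with pytest.raises(ValidationError, match="ghost"):
            build_shortlist(
                tracks={"hmm": {"ghost"}},
                contrasts=small_result.contrasts,
                coverage=small_result.coverage,
                topology=small_result.topology,
                homology_profiles={},
            )

    def test_multi_track_candidates_deduplicated(self, small_result):
        sl = small_result.shortlist
        ids = [r.protein_id for r in sl.records]
        assert len(ids) == len(set(ids))
        planted = next(r for r in sl.records if r.protein_id == "g_planted_0")
        assert planted.tracks == {"hmm", "homology", "proximity"}

    def test_stringent_entries_only_for_homology_track(self, small_result):
        for rec in small_result.shortlist.records:
            has_stringent = any(n.startswith("str") for n, _ in rec.criteria_log)
            if "homology" not in rec.tracks:
                assert not has_stringent

    def test_monotone_under_threshold_tightening(self, small_dataset):
        base = run_pipeline(small_dataset, PipelineConfig())
        loose = {r.protein_id for r in base.shortlist.records}
        for tighter in (
            PipelineConfig(cov_key=80.0),
            PipelineConfig(cov_all=5.0),
            PipelineConfig(up_mode="strict"),
            PipelineConfig(soft_c3=False),
        ):
            tight = run_pipeline(small_dataset, tighter)
            assert {r.protein_id for r in tight.shortlist.records} <= loose


class TestPublishedTable:
    def test_has_fifty_records(self):
        assert len(parse_published_shortlist()) == 50

    def test_first_row_values(self):
        rec = parse_published_shortlist()[0]
        assert rec.protein_id == "1165828"
        assert rec.tm_helices == 12
        assert rec.contrasts["C1"] == (3.42, 0.0)
        assert rec.cov["NW305 -Fe_a"] == (14.61, 0.99)
        assert rec.cov["NW186 -Fe_a"] == (139.89, 22.45)

    def test_undefined_rows_parse_to_none(self):
        rec = next(r for r in parse_published_shortlist() if r.protein_id == "37369")
        assert rec.contrasts["C1"] == (None, None)
        assert rec.cov["NW186 -Fe_a"] == (None, None)

    def test_resorting_preserves_file_order(self):
        # The printed table is already sorted by descending C1 log2FC;
        # within equal fold-changes our ascending-id tie-break may
        # permute rows, so compare as (value, id-set) groups.
        recs = parse_published_shortlist()
        resorted = sort_records(recs)
        defined = [r for r in recs if r.log2fc("C1") is not None]
        assert [r.log2fc("C1") for r in resorted[: len(defined)]] == [
            r.log2fc("C1") for r in defined
        ]

        def groups(rows):
            out = {}
            for r in rows:
                if r.log2fc("C1") is not None:
                    out.setdefault(r.log2fc("C1"), set()).add(r.protein_id)
            return out

        assert groups(resorted) == groups(defined)
        # undefined fold-changes stay at the bottom, as printed
        assert [r.protein_id for r in resorted[len(defined):]] == ["1178960", "37369"]

    def test_rank_one_is_the_validated_exporter(self):
        top = sort_records(parse_published_shortlist())[0]
        assert top.protein_id == "1165828" and top.tm_helices == 12

    def test_malformed_cell_reports_position(self, tmp_path):
        bad = tmp_path / "t.tsv"
        header = "\t".join(["h"] * 14)
        row = "\t".join(["g1", "2"] + ["1.0 ± 0.1", "1.0 ± 0.1", "oops", "0.0"] * 3)
        bad.write_text(header + "\n" + row + "\n")
        with pytest.raises(ParseError, match="col 5"):
            parse_published_shortlist(bad)
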