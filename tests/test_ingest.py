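"""Parsing, deduplication, keyword filtering, SOC mapping, descriptive table."""

import pandas as pd
import pytest

from conftest import make_report, make_set
from faersig.ingest import (deduplicate, descriptive_summary,
                            filter_primary_suspect, map_meddra,
                            parse_faers_tables, reports_from_frames, share)
from faersig.synthetic import write_dataset


def frames(demo_rows, drug_rows, reac_rows, ther_rows=None):
    demo = pd.DataFrame(demo_rows, columns=["primaryid", "caseid", "event_dt", "sex",
                                            "age", "age_cod", "occp_cod", "occr_country"])
    drug = pd.DataFrame(drug_rows, columns=["primaryid", "drug_seq", "role_cod",
                                            "drugname", "prodname"])
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "pt"])
    out = {"DEMO": demo, "DRUG": drug, "REAC": reac}
    if ther_rows is not None:
        out["THER"] = pd.DataFrame(ther_rows, columns=["primaryid", "dsg_drug_seq", "start_dt"])
    return out


class TestParse:
    def test_round_trip_with_generator(self, small_dataset, tmp_path):
        tables, manifest = small_dataset
        paths = write_dataset(tables, manifest, tmp_path)
        rs = parse_faers_tables({k: paths[k] for k in ("DEMO", "DRUG", "REAC", "THER")})
        assert len(rs) == len(tables["DEMO"])
        # PT sets match the manifest for single-version cases
        by_pid = {r.primaryid: r for r in rs}
        for caseid, pts, last in zip(manifest.caseids, manifest.pts,
                                     [manifest.latest_primaryid[c] for c in manifest.caseids]):
            assert by_pid[last].pts == set(pts)

    def test_duplicate_pt_rows_collapse(self):
        fr = frames(
            [("1", "1", "", "F", "", "", "CN", "US")],
            [("1", "1", "PS", "LECANEMAB", "LEQEMBI")],
            [("1", "Headache"), ("1", "Headache"), ("1", "Chills")],
        )
        rs = reports_from_frames(fr)
        assert rs.reports[0].pts == {"Headache", "Chills"}

    def test_orphan_rows_dropped(self):
        fr = frames(
            [("1", "1", "", "F", "", "", "CN", "US")],
            [("1", "1", "PS", "X", "X"), ("99", "1", "PS", "Y", "Y")],
            [("1", "Headache"), ("99", "Nausea")],
        )
        rs = reports_from_frames(fr)
        assert len(rs) == 1
        assert rs.reports[0].pts == {"Headache"}

    def test_missing_mandatory_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_faers_tables({"DEMO": tmp_path / "DEMO.txt"})

    def test_age_units_normalized(self):
        fr = frames(
            [("1", "1", "", "F", "18", "MON", "CN", "US"),
             ("2", "2", "", "M", "75", "YR", "CN", "US"),
             ("3", "3", "", "M", "75", "???", "CN", "US")],
            [], [],
        )
        rs = reports_from_frames(fr)
        ages = {r.primaryid: r.age_years for r in rs}
        assert ages["1"] == pytest.approx(1.5)
        assert ages["2"] == 75.0
        assert ages["3"] is None  # unknown unit -> missing

    def test_ther_start_joined_to_ps_sequence(self):
        fr = frames(
            [("1", "1", "20230210", "F", "", "", "CN", "US")],
            [("1", "1", "C", "OTHER", "OTHER"), ("1", "2", "PS", "LECANEMAB", "LEQEMBI")],
            [("1", "Headache")],
            [("1", "1", "20200101"), ("1", "2", "20230108"), ("1", "2", "20230115")],
        )
        r = reports_from_frames(fr).reports[0]
        assert r.start_dt == "20230108"  # earliest full date of the PS sequence


class TestDeduplicate:
    def test_latest_version_retained(self):
        rs = make_set([make_report("1001", caseid="100", pts={"A"}),
                       make_report("1002", caseid="100", pts={"A"})], dedup=False)
        out = deduplicate(rs)
        assert [r.primaryid for r in out] == ["1002"]
        assert out.dedup_applied

    def test_identity_without_shared_caseids(self):
        rs = make_set([make_report(i) for i in range(5)], dedup=False)
        assert deduplicate(rs).primaryids() == rs.primaryids()

    def test_exact_duplicate_rows_collapse(self):
        r = make_report("7", pts={"A"})
        out = deduplicate(make_set([r, make_report("7", pts={"A"})], dedup=False))
        assert len(out) == 1

    def test_idempotent(self):
        rs = make_set([make_report("1001", caseid="100"), make_report("1002", caseid="100"),
                       make_report("2001", caseid="200")], dedup=False)
        once = deduplicate(rs)
        twice = deduplicate(once)
        assert once.primaryids() == twice.primaryids()

    def test_matches_generator_manifest(self, small_dataset):
        tables, manifest = small_dataset
        rs = deduplicate(reports_from_frames(tables))
        assert rs.primaryids() == manifest.latest_primaryids


def entry(name, prod, role, seq=1):
    return (name, prod, role, seq)


class TestFilter:
    def test_product_name_keyword(self):
        rs = make_set([make_report("1", drug_entries=[entry("UNKNOWN", "LEQEMBI", "PS")])])
        out = filter_primary_suspect(rs)
        assert len(out) == 1 and out.reports[0].target_drug == "lecanemab"

    def test_suffixed_generic_keyword(self):
        rs = make_set([make_report("1", drug_entries=[entry("ADUCANUMAB-AVWA", "", "PS")])])
        out = filter_primary_suspect(rs)
        assert out.reports[0].target_drug == "aducanumab"

    def test_non_ps_role_excluded(self):
        rs = make_set([make_report("1", drug_entries=[entry("LECANEMAB", "LEQEMBI", "C")]),
                       make_report("2", drug_entries=[entry("LECANEMAB", "LEQEMBI", "SS")])])
        assert len(filter_primary_suspect(rs)) == 0

    def test_case_insensitive_substring(self):
        rs = make_set([make_report("1", drug_entries=[entry("Lecanemab 100mg/ml", "", "PS")])])
        assert len(filter_primary_suspect(rs)) == 1

    def test_empty_keywords_error(self):
        with pytest.raises(ValueError):
            filter_primary_suspect(make_set([]), {})

    def test_filter_is_subset_and_commutes_with_dedup(self, small_dataset):
        tables, _ = small_dataset
        rs = reports_from_frames(tables)
        a = filter_primary_suspect(deduplicate(rs))
        b = deduplicate(filter_primary_suspect(rs))
        assert a.primaryids() == b.primaryids()
        assert a.primaryids() <= rs.primaryids()


class TestMapMeddra:
    DICT = {"Headache": "Nervous system disorders",
            "Chills": "General disorders and administration site conditions",
            "Dizziness": "Nervous system disorders"}

    def test_union_of_socs(self):
        rs = make_set([make_report("1", pts={"Headache", "Chills"})])
        out = map_meddra(rs, self.DICT)
        assert len(out.reports[0].socs) == 2

    def test_shared_soc_counts_once(self):
        rs = make_set([make_report("1", pts={"Headache", "Dizziness"})])
        out = map_meddra(rs, self.DICT)
        assert out.reports[0].socs == {"Nervous system disorders"}

    def test_unmapped_pt_kept_for_pt_level_only(self):
        rs = make_set([make_report("1", pts={"Headache", "Mystery term"}),
                       make_report("2", pts={"Chills"}),
                       make_report("3", pts={"Mystery term"})])
        out = map_meddra(rs, self.DICT)
        assert out.unmapped_pts == {"Mystery term"}
        r3 = next(r for r in out if r.primaryid == "3")
        assert r3.pts == {"Mystery term"} and r3.socs == set()

    def test_empty_dictionary_error(self):
        with pytest.raises(ValueError):
            map_meddra(make_set([]), {})


class TestDescriptive:
    def test_printed_share_logic(self):
        # percentage = count / column-total * 100 rounded to 2 decimals
        assert share(892, 1409) == 63.31
        assert share(517, 1409) == 36.69
        assert share(747, 1409) == 53.02
        assert share(568, 1409) == 40.31

    def test_single_sex_is_100_percent(self):
        rs = make_set([make_report(i, sex="F", drug="lecanemab") for i in range(4)])
        df = descriptive_summary(rs)
        sex = df[df.block == "sex"].set_index("category")
        assert sex.loc["F", "overall_pct"] == 100.00
        assert sex.loc["M", "overall_pct"] == 0.00

    def test_blocks_sum_to_100(self, small_dataset):
        tables, _ = small_dataset
        rs = filter_primary_suspect(deduplicate(reports_from_frames(tables)))
        df = descriptive_summary(rs)
        for block in ("sex", "age", "reporter", "country"):
            for col in ("lecanemab_pct", "aducanumab_pct", "overall_pct"):
                total = df.loc[df.block == block, col].sum()
                assert total == pytest.approx(100.0, abs=0.05)

    def test_empty_set_warns_and_returns_empty(self):
        assert descriptive_summary(make_set([])).empty
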