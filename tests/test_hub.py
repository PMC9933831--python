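import json
from pathlib import Path

import pytest

from pepscout.exceptions import ProteinNotFoundError
from pepscout.hub import (
    SearchConfig,
    export_report,
    filter_by_organism,
    load_config,
    load_report,
    merge_reports,
    search,
)
from pepscout.retrieval import DatasetRecord, FixtureRetriever, Organism

HUMAN = Organism(name="Homo sapiens", taxon_id=9606)
MOUSE = Organism(name="Mus musculus", taxon_id=10090)


def ds(acc, organisms=(), **kw):
    return DatasetRecord(accession=acc, organisms=set(organisms), sources={"db"}, **kw)


class TestOrganismFilter:
    def test_taxon_id_match(self):
        retained, removed = filter_by_organism([ds("D1", [HUMAN])], 9606)
        assert [d.accession for d in retained] == ["D1"] and removed == 0

    def test_off_organism_removed(self):
        retained, removed = filter_by_organism([ds("D1", [MOUSE])], 9606)
        assert retained == [] and removed == 1

    def test_name_match_case_insensitive_multi_organism(self):
        retained, _ = filter_by_organism([ds("D1", [HUMAN, MOUSE])], "homo sapiens")
        assert [d.accession for d in retained] == ["D1"]

    def test_numeric_string_target_matches_taxon(self):
        retained, _ = filter_by_organism([ds("D1", [HUMAN])], "9606")
        assert len(retained) == 1

    def test_unannotated_dropped_by_default_kept_on_request(self):
        data = [ds("D1", [HUMAN]), ds("D2")]
        retained, removed = filter_by_organism(data, 9606)
        assert [d.accession for d in retained] == ["D1"] and removed == 1
        retained, removed = filter_by_organism(data, 9606, keep_unannotated=True)
        assert len(retained) == 2 and removed == 0

    def test_conservation_and_idempotence(self):
        data = [ds("D1", [HUMAN]), ds("D2", [MOUSE]), ds("D3"), ds("D4", [HUMAN, MOUSE])]
        retained, removed = filter_by_organism(data, 9606)
        assert len(retained) + removed == len(data)
        again, removed2 = filter_by_organism(retained, 9606)
        assert again == retained and removed2 == 0

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            filter_by_organism([], "")


class TestMergeReports:
    def test_same_dataset_from_two_sources(self):
        a = DatasetRecord(accession="PXD001985", title="first", organisms={HUMAN},
                          sources={"pride"}, full_metadata={"pride": {"title": "first"}})
        b = DatasetRecord(accession="PXD001985", title="second", organisms={MOUSE},
                          sources={"iprox"}, full_metadata={"iprox": {"title": "second"}})
        merged = merge_reports([[a], [b]])
        assert len(merged) == 1
        rec = merged[0]
        assert rec.sources == {"pride", "iprox"}
        assert rec.title == "first"  # first-configured source wins
        assert rec.organisms == {HUMAN, MOUSE}
        assert set(rec.full_metadata) == {"pride", "iprox"}  # loser payload kept

    def test_empty_scalar_never_beats_nonempty(self):
        a = DatasetRecord(accession="D1", title="", sources={"pride"})
        b = DatasetRecord(accession="D1", title="real title", sources={"iprox"})
        assert merge_reports([[a], [b]])[0].title == "real title"

    def test_disjoint_sorted(self):
        merged = merge_reports([[ds("D2")], [ds("D1")]])
        assert [r.accession for r in merged] == ["D1", "D2"]

    def test_empty(self):
        assert merge_reports([]) == []

    def test_associative_given_fixed_source_order(self):
        a, b, c = [ds(f"D{i}", [HUMAN]) for i in range(3)]
        b2 = DatasetRecord(accession="D0", title="alt", sources={"other"})
        left = merge_reports([merge_reports([[a], [b, b2]]), [c]])
        right = merge_reports([[a], merge_reports([[b, b2], [c]])])
        assert left == right


@pytest.fixture
def demo_report(demo_world):
    paths, key = demo_world
    config = SearchConfig(
        target_accession=key["target_accession"],
        proteome_path=paths.fasta,
        retrievers=FixtureRetriever.all_for_manifest(paths.manifest),
    )
    return search(config)


class TestExportDialect:
    def test_tsv_shape_and_sanitization(self, demo_report, tmp_path):
        demo_report.rows[0].record.summary = "line one\nline\ttwo"
        _, tsv = export_report(demo_report, tmp_path)
        lines = tsv.read_text().splitlines()
        assert len(lines) == 1 + len(demo_report.rows)
        assert all(line.count("\t") == 7 for line in lines)  # 8 columns everywhere
        assert "line one line two" in lines[1 + 0].split("\t")[6] or any(
            "line one line two" in ln for ln in lines
        )

    def test_json_reload_reexport_is_byte_identical(self, demo_report, tmp_path):
        json_path, tsv_path = export_report(demo_report, tmp_path / "a")
        reloaded = load_report(json_path)
        json2, tsv2 = export_report(reloaded, tmp_path / "b")
        assert tsv2.read_bytes() == tsv_path.read_bytes()
        assert json2.read_bytes() == json_path.read_bytes()

    def test_unusable_output_path_writes_nothing(self, demo_report, tmp_path):
        target = tmp_path / "blocked"
        target.write_text("a file where the output directory should go")
        with pytest.raises(OSError):
            export_report(demo_report, target)
        assert target.read_text().startswith("a file")  # untouched, no partial output

    def test_dataframe_matches_tsv(self, demo_report):
        df = demo_report.to_dataframe()
        assert list(df.columns)[0] == "accession"
        assert len(df) == len(demo_report.rows)


class TestEndToEnd:
    def test_answer_key_reproduced(self, demo_world):
        paths, key = demo_world
        report = search(SearchConfig(
            target_accession=key["target_accession"],
            proteome_path=paths.fasta,
            retrievers=FixtureRetriever.all_for_manifest(paths.manifest),
        ))
        assert report.n_unique_peptides == key["n_unique_peptides"]
        assert sorted(report.dataset_accessions) == sorted(key["retained"])
        assert report.filtered_out == key["filtered_out"]
        for row in report.rows:
            expected = key["retained"][row.record.accession]
            assert row.evidence.matched_by == expected["matched_by"]
            assert sorted(row.evidence.matched_peptides) == expected["matched_peptides"]
            assert row.evidence.usi_count == expected["usi_count"]

    def test_taxon_falls_back_to_proteome_header(self, demo_world):
        paths, key = demo_world
        report = search(SearchConfig(
            target_accession=key["target_accession"],
            proteome_path=paths.fasta,
            retrievers=FixtureRetriever.all_for_manifest(paths.manifest),
        ))
        assert report.target_taxon == key["target_taxon"]

    def test_absent_accession_no_output_files(self, demo_world, tmp_path):
        paths, _ = demo_world
        out = tmp_path / "out"
        with pytest.raises(ProteinNotFoundError):
            search(SearchConfig(
                target_accession="NOSUCH",
                proteome_path=paths.fasta,
                retrievers=FixtureRetriever.all_for_manifest(paths.manifest),
                output_dir=out,
            ))
        assert not out.exists()

    def test_foreign_taxon_retains_nothing(self, demo_world):
        paths, key = demo_world
        report = search(SearchConfig(
            target_accession=key["target_accession"],
            proteome_path=paths.fasta,
            retrievers=FixtureRetriever.all_for_manifest(paths.manifest),
            target_taxon=559292,  # yeast: absent from every fixture dataset
        ))
        assert report.rows == []
        assert report.filtered_out == key["mapped_total"]

    def test_two_runs_identical_modulo_timestamp(self, demo_world, tmp_path):
        paths, key = demo_world
        def run(out):
            return search(SearchConfig(
                target_accession=key["target_accession"],
                proteome_path=paths.fasta,
                retrievers=FixtureRetriever.all_for_manifest(paths.manifest),
                output_dir=out,
            ))
        run(tmp_path / "r1")
        run(tmp_path / "r2")
        a = json.loads((tmp_path / "r1" / "report.json").read_text())
        b = json.loads((tmp_path / "r2" / "report.json").read_text())
        a.pop("timestamp"), b.pop("timestamp")
        assert a == b
        assert (tmp_path / "r1" / "report.tsv").read_bytes() == (
            tmp_path / "r2" / "report.tsv").read_bytes()


def test_load_config_builds_retrievers(demo_world, tmp_path):
    paths, key = demo_world
    cfg_path = tmp_path / "cfg.json"
    cfg_path.write_text(json.dumps({
        "accession": key["target_accession"],
        "proteome": str(paths.fasta),
        "retrievers": [
            {"type": "fixture", "manifest": str(paths.manifest), "repository": "mockdb1"},
            {"type": "fixture", "manifest": str(paths.manifest), "repository": "mockdb2"},
        ],
        "digestion": {"max_missed_cleavages": 1},
    }))
    config = load_config(cfg_path, output_dir=str(tmp_path / "out"))
    assert [r.name for r in config.retrievers] == ["mockdb1", "mockdb2"]
    report = search(config)
    assert sorted(report.dataset_accessions) == sorted(key["retained"])
    assert (tmp_path / "out" / "report.tsv").exists()
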