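import logging

import numpy as np
import pandas as pd
import pytest

from mimeta import (
    DatasetRecord,
    ExpressionStudy,
    ProbeMap,
    ValidationError,
    collapse_probes,
    ensure_log2,
    filter_manifest,
    read_expression_study,
)
from mimeta.study_io import read_manifest, read_probe_map, read_series_matrix

from conftest import write_study_tsvs


class TestEnsureLog2:
    def test_log_scale_matrix_unchanged(self):
        values = pd.DataFrame([[1.2, 14.2], [3.3, 8.0]])
        assert ensure_log2(values) is values

    def test_raw_scale_transformed(self):
        values = pd.DataFrame([[1023.0, 1023.0], [1023.0, 1023.0]])
        out = ensure_log2(values)
        assert np.allclose(out.to_numpy(), 10.0)

    def test_negative_values_in_raw_matrix_rejected(self):
        values = pd.DataFrame([[60.0, -1.0]])
        with pytest.raises(ValidationError):
            ensure_log2(values)

    def test_idempotent(self):
        values = pd.DataFrame([[0.0, 40000.0], [250.0, 1.0]])
        once = ensure_log2(values)
        assert ensure_log2(once) is once


class TestCollapseProbes:
    def test_median_of_two_probes(self):
        values = pd.DataFrame(
            [[1.0, 3.0], [3.0, 5.0]], index=["p1", "p2"], columns=["a", "b"]
        )
        out = collapse_probes(values, ProbeMap({"p1": "G", "p2": "G"}))
        assert list(out.index) == ["G"]
        assert out.loc["G"].tolist() == [2.0, 4.0]

    def test_one_probe_per_gene_is_rename(self):
        values = pd.DataFrame([[1.0], [2.0]], index=["p1", "p2"], columns=["a"])
        out = collapse_probes(values, ProbeMap({"p1": "G1", "p2": "G2"}))
        assert sorted(out.index) == ["G1", "G2"]
        assert out.loc["G1", "a"] == 1.0

    def test_odd_probe_count_median(self):
        values = pd.DataFrame(
            [[1.0], [2.0], [9.0]], index=["p1", "p2", "p3"], columns=["a"]
        )
        out = collapse_probes(values, ProbeMap({f"p{i}": "G" for i in (1, 2, 3)}))
        assert out.loc["G", "a"] == 2.0

    def test_unmapped_probe_dropped(self):
        values = pd.DataFrame([[1.0], [2.0]], index=["p1", "px"], columns=["a"])
        out = collapse_probes(values, ProbeMap({"p1": "G1"}))
        assert list(out.index) == ["G1"]

    def test_empty_intersection_rejected(self):
        values = pd.DataFrame([[1.0]], index=["p1"], columns=["a"])
        with pytest.raises(ValidationError):
            collapse_probes(values, ProbeMap({"other": "G"}))

    def test_row_count_equals_distinct_mapped_genes(self):
        rng = np.random.default_rng(0)
        probes = [f"p{i}" for i in range(20)]
        genes = [f"G{i % 7}" for i in range(20)]
        values = pd.DataFrame(
            rng.normal(size=(20, 3)), index=probes, columns=["a", "b", "c"]
        )
        out = collapse_probes(values, ProbeMap(dict(zip(probes, genes))))
        assert len(out) == 7

    def test_empty_gene_symbol_rejected(self):
        with pytest.raises(ValidationError):
            ProbeMap({"p1": ""})


class TestReadExpressionStudy:
    def test_round_trip(self, tmp_path):
        values = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [2.0, 3.0], "s3": [3.0, 4.0], "s4": [4.0, 5.0]},
            index=["G1", "G2"],
        )
        groups = {"s1": "case", "s2": "case", "s3": "control", "s4": "control"}
        mpath, ppath = write_study_tsvs(tmp_path, values, groups)
        study = read_expression_study(mpath, ppath)
        assert study.genes == ["G1", "G2"]
        assert len(study.case_samples) == 2
        assert len(study.control_samples) == 2

    def test_unlabeled_samples_dropped_with_warning(self, tmp_path, caplog):
        values = pd.DataFrame(
            {"s1": [1.0], "s2": [2.0], "s3": [3.0], "s4": [4.0]}, index=["G1"]
        )
        groups = {"s1": "case", "s2": "case", "s3": "control"}
        mpath, ppath = write_study_tsvs(tmp_path, values, groups)
        with caplog.at_level(logging.WARNING):
            study = read_expression_study(mpath, ppath)
        assert len(study.groups) == 3
        assert "s4" not in study.values.columns
        assert any("dropping" in r.message for r in caplog.records)

    def test_probe_collapsing_applied(self, tmp_path):
        values = pd.DataFrame(
            {"s1": [1.0, 3.0], "s2": [3.0, 5.0], "s3": [2.0, 2.0], "s4": [2.0, 2.0]},
            index=["p1", "p2"],
        )
        groups = {"s1": "case", "s2": "case", "s3": "control", "s4": "control"}
        mpath, ppath = write_study_tsvs(tmp_path, values, groups)
        study = read_expression_study(
            mpath, ppath, probe_map=ProbeMap({"p1": "G", "p2": "G"})
        )
        assert study.values.loc["G", "s1"] == 2.0
        assert study.values.loc["G", "s2"] == 4.0

    def test_single_group_rejected(self, tmp_path):
        values = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["G1"])
        groups = {"s1": "case", "s2": "case"}
        mpath, ppath = write_study_tsvs(tmp_path, values, groups)
        with pytest.raises(ValidationError):
            read_expression_study(mpath, ppath)

    def test_duplicate_phenotype_sample_rejected(self, tmp_path):
        values = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["G1"])
        mpath = tmp_path / "m.tsv"
        values.rename_axis("id").to_csv(mpath, sep="\t")
        ppath = tmp_path / "p.tsv"
        ppath.write_text(
            "sample_id\tgroup\ns1\tcase\ns1\tcase\ns2\tcontrol\n"
        )
        with pytest.raises(ValidationError):
            read_expression_study(mpath, ppath)

    def test_series_matrix_metadata_lines_skipped(self, tmp_path):
        path = tmp_path / "series.tsv"
        path.write_text(
            '!Series_title\t"demo"\nid\ts1\ts2\nG1\t1.0\t2.0\n'
        )
        df = read_series_matrix(path)
        assert df.loc["G1", "s2"] == 2.0


def record(accession="A", is_array=True, downloadable=True,
           organism="Homo sapiens", design=True):
    return DatasetRecord(
        accession=accession,
        is_array=is_array,
        downloadable=downloadable,
        organism=organism,
        design_case_vs_healthy=design,
    )


class TestFilterManifest:
    def test_only_fully_qualifying_records_survive_in_order(self):
        records = [
            record("A"),
            record("B", is_array=False),
            record("C", downloadable=False),
            record("D", organism="Mus musculus"),
            record("E"),
        ]
        out = filter_manifest(records)
        assert [r.accession for r in out] == ["A", "E"]

    @pytest.mark.parametrize("organism", ["human", "HUMAN", "Homo sapiens", "homo sapiens"])
    def test_organism_spellings_accepted(self, organism):
        assert filter_manifest([record(organism=organism)])

    def test_non_human_excluded(self):
        assert filter_manifest([record(organism="Mus musculus")]) == []

    def test_non_case_control_design_excluded(self):
        assert filter_manifest([record(design=False)]) == []

    def test_empty_manifest(self):
        assert filter_manifest([]) == []

    def test_subset_and_idempotent(self):
        records = [
            record("A"),
            record("B", is_array=False),
            record("C", organism="rat"),
            record("D", design=False),
            record("E", downloadable=False),
            record("F"),
        ]
        once = filter_manifest(records)
        assert set(r.accession for r in once) <= set(r.accession for r in records)
        assert filter_manifest(once) == once

    def test_duplicate_accession_rejected(self):
        with pytest.raises(ValidationError):
            filter_manifest([record("A"), record("A")])


def test_manifest_and_probe_map_readers(tmp_path):
    mpath = tmp_path / "manifest.csv"
    mpath.write_text(
        "accession,is_array,downloadable,organism,design_case_vs_healthy\n"
        "GSE1,true,true,Homo sapiens,true\n"
        "GSE2,false,true,Homo sapiens,true\n"
    )
    records = read_manifest(mpath)
    assert [r.accession for r in records] == ["GSE1", "GSE2"]
    assert records[0].is_array and not records[1].is_array

    ppath = tmp_path / "map.tsv"
    ppath.write_text("probe_id\tgene_symbol\np1\tG1\np2\tG1\n")
    pm = read_probe_map(ppath)
    assert pm.entries == {"p1": "G1", "p2": "G1"}
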