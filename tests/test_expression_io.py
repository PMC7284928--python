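"""Series-matrix/TSV ingestion, probe mapping, log2 normalisation, selection."""

import numpy as np
import pandas as pd
import pytest

from megapath import (
    GroupRule,
    SelectionCriteria,
    ensure_log2,
    map_probes,
    read_matrix_tsv,
    read_series_matrix,
    validate_selection,
)
from megapath.expression_io import SeriesMatrixError, write_matrix_tsv

from conftest import make_study

RULE = GroupRule(case="myocardial infarction", control="healthy control")


class TestReadSeriesMatrix:
    def test_fixture_parses_with_3_3_groups(self, tiny_series_matrix):
        study = read_series_matrix(tiny_series_matrix, RULE)
        assert study.study_id == "GSETEST"
        assert (study.n_case, study.n_control) == (3, 3)
        assert study.matrix.shape == (2, 6)
        assert study.covariates.country == "Italy"
        assert study.covariates.study_age == 3.0
        assert study.matrix.loc["GENE1", "B1"] == 7.0

    def test_no_case_match_is_error(self, tiny_series_matrix):
        with pytest.raises(ValueError, match="no cases"):
            read_series_matrix(
                tiny_series_matrix, GroupRule(case="stroke", control="healthy")
            )

    def test_unterminated_table_block(self, tmp_path, tiny_series_matrix):
        text = tiny_series_matrix.read_text().replace("!series_matrix_table_end\n", "")
        p = tmp_path / "broken.txt"
        p.write_text(text)
        with pytest.raises(SeriesMatrixError, match="never closed"):
            read_series_matrix(p, RULE)

    def test_missing_table_block(self, tmp_path):
        p = tmp_path / "meta_only.txt"
        p.write_text('!Series_geo_accession\t"X"\n')
        with pytest.raises(SeriesMatrixError, match="no series_matrix table"):
            read_series_matrix(p, RULE)

    def test_synthetic_bundle_mirrors_published_design(self, tmp_path):
        """The 8-study synthetic bundle reproduces the published group sizes."""
        from megapath.synthetic import (
            DEFAULT_GROUP_RULE,
            SimulationConfig,
            generate_studies,
            write_series_matrix,
        )

        expected = [(4, 34), (4, 34), (48, 49), (21, 31),
                    (7, 10), (7, 17), (14, 84), (50, 49)]
        sizes = []
        for study in generate_studies(SimulationConfig(seed=0, n_genes=12)):
            p = tmp_path / f"{study.study_id}.txt"
            write_series_matrix(study, p)
            back = read_series_matrix(p, DEFAULT_GROUP_RULE)
            sizes.append((back.n_control, back.n_case))
            assert back.covariates.country == study.covariates.country
        assert sizes == expected


class TestPlainTsvRoundTrip:
    def test_roundtrip_identity(self, tmp_path):
        study = make_study("RT", case=[[7.0, 7.5], [9.0, 9.2]],
                           ctrl=[[5.0, 5.5], [9.1, 8.9]])
        mp_, gp = tmp_path / "m.tsv", tmp_path / "g.tsv"
        write_matrix_tsv(study, mp_, gp)
        back = read_matrix_tsv(mp_, gp)
        assert back.study_id == study.study_id
        pd.testing.assert_frame_equal(back.matrix, study.matrix)
        pd.testing.assert_series_equal(back.groups, study.groups)
        assert back.covariates == study.covariates


class TestMapProbes:
    def test_mean_aggregation(self):
        study = make_study("S", case=[[1, 2], [3, 4]], ctrl=[[0, 0], [0, 0]],
                           genes=["p1", "p2"])
        out = map_probes(study, {"p1": "GENEX", "p2": "GENEX"}, aggregation="mean")
        assert list(out.matrix.index) == ["GENEX"]
        np.testing.assert_allclose(out.matrix.loc["GENEX"].to_numpy(),
                                   [0.0, 0.0, 2.0, 3.0])

    def test_unmapped_probe_dropped(self):
        study = make_study("S", case=[[1], [2]], ctrl=[[1], [2]], genes=["p1", "p2"])
        out = map_probes(study, {"p1": "GENEX"})
        assert list(out.matrix.index) == ["GENEX"]

    def test_max_mean_matches_brute_force(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(8, 2, size=(5, 6))
        study = make_study("S", case=vals[:, :3], ctrl=vals[:, 3:],
                           genes=[f"p{i}" for i in range(5)])
        out = map_probes(study, {f"p{i}": "G" for i in range(5)},
                         aggregation="max_mean")
        best = max(range(5), key=lambda i: vals[i].mean())  # brute force
        np.testing.assert_allclose(
            out.matrix.loc["G"].to_numpy(),
            study.matrix.iloc[best].to_numpy(),
        )

    def test_never_increases_rows_preserves_columns(self):
        study = make_study("S", case=[[1], [2], [3]], ctrl=[[1], [2], [3]],
                           genes=["p1", "p2", "p3"])
        out = map_probes(study, {"p1": "A", "p2": "A", "p3": "B"})
        assert out.matrix.shape[0] <= study.matrix.shape[0]
        assert list(out.matrix.columns) == list(study.matrix.columns)
        pd.testing.assert_series_equal(out.groups, study.groups)

    def test_empty_platform_map_is_error(self):
        study = make_study("S", case=[[1]], ctrl=[[1]])
        with pytest.raises(ValueError, match="empty platform map"):
            map_probes(study, {})


class TestEnsureLog2:
    def test_log_scale_passes_through(self):
        study = make_study("S", case=[[14.2, 10.0]], ctrl=[[8.0, 9.0]])
        out = ensure_log2(study)
        pd.testing.assert_frame_equal(out.matrix, study.matrix)

    def test_linear_scale_transformed(self):
        study = make_study("S", case=[[1023.0, 1023.0]], ctrl=[[0.0, 0.0]])
        out = ensure_log2(study)
        np.testing.assert_allclose(out.matrix.to_numpy(), [[0.0, 0.0, 10.0, 10.0]])

    def test_negative_on_linear_scale_is_error(self):
        study = make_study("S", case=[[60.0, -2.0]], ctrl=[[5.0, 5.0]])
        with pytest.raises(ValueError, match="negative"):
            ensure_log2(study)

    def test_idempotent(self):
        study = make_study("S", case=[[200.0, 4000.0]], ctrl=[[100.0, 900.0]])
        once = ensure_log2(study)
        twice = ensure_log2(once)
        pd.testing.assert_frame_equal(twice.matrix, once.matrix)


class TestValidateSelection:
    def test_published_size_passes(self):
        study = make_study("S", case=np.zeros((1, 34)) + 8, ctrl=np.zeros((1, 4)) + 8)
        ok, reasons = validate_selection(study)
        assert ok and not reasons

    def test_ten_is_not_bigger_than_ten(self):
        study = make_study("S", case=np.zeros((1, 5)) + 8, ctrl=np.zeros((1, 5)) + 8)
        ok, reasons = validate_selection(study)
        assert not ok
        assert any("sample size" in r for r in reasons)

    def test_metadata_criterion_failure_reported(self):
        study = make_study("S", case=np.zeros((1, 30)) + 8, ctrl=np.zeros((1, 30)) + 8)
        ok, reasons = validate_selection(
            study, SelectionCriteria(require_metadata={"organism=Homo sapiens": False})
        )
        assert not ok and any("organism" in r for r in reasons)
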