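import numpy as np
import pandas as pd
import pytest

from megapath import ExpressionStudy, GeneEffect, StudyCovariates
from megapath.synthetic import SimulationConfig


def make_study(
    study_id: str = "S1",
    case: np.ndarray | list | None = None,
    ctrl: np.ndarray | list | None = None,
    genes: list[str] | None = None,
    covariates: StudyCovariates | None = None,
) -> ExpressionStudy:
    """Small helper: build a study from explicit case/control value blocks."""
    case = np.atleast_2d(np.asarray(case, dtype=float))
    ctrl = np.atleast_2d(np.asarray(ctrl, dtype=float))
    genes = genes or [f"G{i+1}" for i in range(case.shape[0])]
    samples = [f"{study_id}_C{i}" for i in range(ctrl.shape[1])] + [
        f"{study_id}_M{i}" for i in range(case.shape[1])
    ]
    matrix = pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=samples)
    matrix.index.name = "gene"
    groups = pd.Series(
        ["control"] * ctrl.shape[1] + ["case"] * case.shape[1],
        index=samples, name="group",
    )
    return ExpressionStudy(study_id, matrix, groups,
                           covariates or StudyCovariates("Italy", 3.0))


def effect(gene="G", study="S", lfc=0.0, var=1.0, n_case=10, n_control=10) -> GeneEffect:
    return GeneEffect(gene, study, lfc, var, n_case, n_control)


@pytest.fixture
def tiny_series_matrix(tmp_path):
    """A 3-case/3-control series-matrix file with two genes."""
    text = "\n".join([
        '!Series_geo_accession\t"GSETEST"',
        '!Series_country\t"Italy"',
        '!Series_study_age\t"3"',
        '!Sample_geo_accession\t"A1"\t"A2"\t"A3"\t"B1"\t"B2"\t"B3"',
        '!Sample_characteristics_ch1\t"disease state: healthy control"'
        '\t"disease state: healthy control"\t"disease state: healthy control"'
        '\t"disease state: myocardial infarction"'
        '\t"disease state: myocardial infarction"'
        '\t"disease state: myocardial infarction"',
        "!series_matrix_table_begin",
        'ID_REF\t"A1"\t"A2"\t"A3"\t"B1"\t"B2"\t"B3"',
        "GENE1\t5.0\t5.5\t6.0\t7.0\t7.5\t8.0",
        "GENE2\t9.0\t9.1\t8.9\t9.0\t9.2\t8.8",
        "!series_matrix_table_end",
        "",
    ])
    p = tmp_path / "GSETEST_series_matrix.txt"
    p.write_text(text, encoding="utf-8")
    return p


@pytest.fixture
def fast_sim_config():
    """A small, quick simulation config (defaults otherwise untouched)."""
    return SimulationConfig(seed=11, n_genes=30)
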