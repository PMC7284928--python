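"""Fixed/random-effects pooling, heterogeneity and model selection.

Independent oracles: the inverse-variance pooled estimate is re-derived by
numerically minimising the weighted sum of squares; Q and the DerSimonian–
Laird τ² are re-derived step by step from their definitions with plain
Python floats; and one instance is cross-checked against R's metafor.
"""

import math
import subprocess
import sys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from megapath import (
    fixed_effects,
    heterogeneity,
    mega_analyze,
    pool_gene,
    random_effects,
)
from conftest import effect


def eff_list(ys, vs):
    return [effect(gene="G", study=f"S{i}", lfc=y, var=v)
            for i, (y, v) in enumerate(zip(ys, vs))]


small_instances = st.integers(1, 3).flatmap(
    lambda k: st.tuples(
        st.lists(st.floats(-5, 5), min_size=k, max_size=k),
        st.lists(st.floats(0.01, 4.0), min_size=k, max_size=k),
    )
)


class TestFixedEffects:
    def test_single_study_identity(self):
        pooled, se = fixed_effects(eff_list([0.4], [0.01]))
        assert (pooled, se) == (pytest.approx(0.4), pytest.approx(0.1))

    def test_equal_variances_give_arithmetic_mean(self):
        pooled, _ = fixed_effects(eff_list([0.2, 0.6], [0.1, 0.1]))
        assert pooled == pytest.approx(0.4)

    def test_hand_inverse_variance_example(self):
        pooled, _ = fixed_effects(eff_list([0.5, 0.1], [0.04, 0.01]))
        assert pooled == pytest.approx(0.18)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            fixed_effects([])

    @settings(derandomize=True, max_examples=60)
    @given(small_instances)
    def test_agrees_with_wls_minimiser_oracle(self, inst):
        ys, vs = inst
        pooled, se = fixed_effects(eff_list(ys, vs))
        # oracle: argmin_mu sum (y-mu)^2 / v, solved numerically
        opt = minimize_scalar(
            lambda mu: sum((y - mu) ** 2 / v for y, v in zip(ys, vs)),
            bounds=(min(ys) - 1, max(ys) + 1), method="bounded",
            options={"xatol": 1e-10},
        )
        assert pooled == pytest.approx(opt.x, abs=1e-6)
        assert se == pytest.approx(math.sqrt(1.0 / sum(1.0 / v for v in vs)))

    @settings(derandomize=True, max_examples=60)
    @given(small_instances)
    def test_pooled_within_observed_range(self, inst):
        ys, vs = inst
        pooled, _ = fixed_effects(eff_list(ys, vs))
        assert min(ys) - 1e-9 <= pooled <= max(ys) + 1e-9


class TestHeterogeneity:
    def test_identical_effects_have_zero_q(self):
        effs = eff_list([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
        pooled, _ = fixed_effects(effs)
        q, df, i_sq, p_q = heterogeneity(effs, pooled)
        assert q == pytest.approx(0.0)
        assert i_sq == 0.0
        assert df == 2

    def test_q_equal_to_df_gives_zero_isq(self):
        # w = 2 each; deviations ±0.5 from pooled 0 give Q = 1 = df exactly
        effs = eff_list([-0.5, 0.5], [0.5, 0.5])
        q, df, i_sq, _ = heterogeneity(effs, 0.0)
        assert q == pytest.approx(1.0)
        assert i_sq == 0.0

    def test_hand_derived_instance(self):
        effs = eff_list([0.0, 1.0], [0.25, 0.25])
        pooled, _ = fixed_effects(effs)
        q, df, i_sq, p_q = heterogeneity(effs, pooled)
        assert pooled == pytest.approx(0.5)
        assert q == pytest.approx(2.0)
        assert (df, i_sq) == (1, pytest.approx(50.0))

    def test_fewer_than_two_studies_is_error(self):
        with pytest.raises(ValueError):
            heterogeneity(eff_list([0.1], [0.1]), 0.1)

    @settings(derandomize=True, max_examples=60)
    @given(small_instances)
    def test_q_matches_definition_oracle(self, inst):
        ys, vs = inst
        if len(ys) < 2:
            return
        effs = eff_list(ys, vs)
        pooled, _ = fixed_effects(effs)
        q, df, i_sq, _ = heterogeneity(effs, pooled)
        q_oracle = sum((y - pooled) ** 2 / v for y, v in zip(ys, vs))
        assert q == pytest.approx(q_oracle, rel=1e-9, abs=1e-9)
        assert i_sq == (0.0 if q <= df else pytest.approx(100 * (q - df) / q))


class TestRandomEffects:
    def test_hand_derived_dl_instance(self):
        effs = eff_list([0.0, 1.0], [0.25, 0.25])
        pooled, se, tau_sq = random_effects(effs)
        # w = 4 each: tau² = (2-1)/(8 - 32/8) = 0.25
        assert tau_sq == pytest.approx(0.25)
        assert pooled == pytest.approx(0.5)
        assert se == pytest.approx(math.sqrt(1.0 / (2 * (1 / 0.5))))

    def test_reduces_to_fixed_when_q_below_df(self):
        effs = eff_list([0.3, 0.31], [0.5, 0.5])
        pooled_f, se_f = fixed_effects(effs)
        pooled_r, se_r, tau_sq = random_effects(effs)
        assert tau_sq == 0.0
        assert pooled_r == pytest.approx(pooled_f)
        assert se_r == pytest.approx(se_f)

    def test_tau_vanishes_for_homogeneous_studies(self):
        rng = np.random.default_rng(6)
        k = 50
        v = 0.01
        ys = rng.normal(0.3, math.sqrt(v), k)
        _, _, tau_sq = random_effects(eff_list(ys, [v] * k))
        assert tau_sq < 0.01  # consistent with tau² = 0 at k = 50

    @settings(derandomize=True, max_examples=60)
    @given(small_instances)
    def test_dl_matches_step_by_step_oracle_and_se_ordering(self, inst):
        ys, vs = inst
        if len(ys) < 2:
            return
        effs = eff_list(ys, vs)
        pooled, se, tau_sq = random_effects(effs)
        # independent step-by-step DL with plain floats
        w = [1.0 / v for v in vs]
        mu_f = sum(wi * yi for wi, yi in zip(w, ys)) / sum(w)
        q = sum(wi * (yi - mu_f) ** 2 for wi, yi in zip(w, ys))
        c = sum(w) - sum(wi * wi for wi in w) / sum(w)
        tau_oracle = max(0.0, (q - (len(ys) - 1)) / c)
        assert tau_sq == pytest.approx(tau_oracle, rel=1e-9, abs=1e-12)
        ws = [1.0 / (v + tau_oracle) for v in vs]
        assert pooled == pytest.approx(
            sum(wi * yi for wi, yi in zip(ws, ys)) / sum(ws), rel=1e-9, abs=1e-9
        )
        _, se_f = fixed_effects(effs)
        assert se >= se_f - 1e-12


class TestMegaAnalyze:
    def test_model_flags_follow_q_rule(self):
        by_gene = {
            "HOMOG": eff_list([0.5, 0.5, 0.5], [0.1, 0.1, 0.1]),
            "HETERO": eff_list([-1.0, 1.0, 2.0], [0.01, 0.01, 0.01]),
        }
        res = mega_analyze(by_gene)
        assert res["HOMOG"].model == "fixed"
        assert res["HOMOG"].tau_sq == 0.0
        assert res["HETERO"].model == "random"
        assert res["HETERO"].q_stat > res["HETERO"].df

    def test_significance_threshold_rule_keeps_mild_heterogeneity_fixed(self):
        # Q slightly above df but far from significant
        effs = eff_list([0.0, 0.6, 1.0], [0.1, 0.1, 0.1])
        default = pool_gene(effs)
        thresholded = pool_gene(effs, het_p_threshold=0.05)
        assert default.q_stat > default.df
        assert default.model == "random"
        assert thresholded.model == "fixed"

    def test_null_gene_has_p_one(self):
        res = pool_gene(eff_list([0.0, 0.0, 0.0], [1e-6, 1e-6, 1e-6]))
        assert res.pooled_lfc == 0.0
        assert res.p_value == 1.0

    def test_min_k_filter_omits_sparse_genes(self):
        by_gene = {"A": eff_list([0.1, 0.2, 0.3], [0.1] * 3),
                   "B": eff_list([0.1], [0.1])}
        res = mega_analyze(by_gene, min_k=2)
        assert set(res) == {"A"}

    def test_min_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            mega_analyze({}, min_k=1)


class TestAgainstMetafor:
    """Cross-check one instance against R's metafor (FE and DL fits)."""

    def test_fe_and_dl_match_metafor(self, tmp_path):
        ys = [0.42, -0.31, 0.95, 0.10]
        vs = [0.04, 0.09, 0.25, 0.02]
        script = tmp_path / "meta_check.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"y <- c({', '.join(map(str, ys))})\n"
            f"v <- c({', '.join(map(str, vs))})\n"
            "fe <- rma(yi = y, vi = v, method = 'FE')\n"
            "dl <- rma(yi = y, vi = v, method = 'DL')\n"
            "cat(coef(fe), fe$se, fe$QE, fe$QEp, dl$tau2, coef(dl), dl$se,\n"
            "    sep = '\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        )
        ref = [float(x) for x in out.stdout.strip().splitlines()]
        effs = eff_list(ys, vs)
        pooled_f, se_f = fixed_effects(effs)
        q, df, _, p_q = heterogeneity(effs, pooled_f)
        pooled_r, se_r, tau_sq = random_effects(effs)
        ours = [pooled_f, se_f, q, p_q, tau_sq, pooled_r, se_r]
        np.testing.assert_allclose(ours, ref, rtol=1e-6)
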