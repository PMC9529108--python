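"""Mantel-Haenszel / DerSimonian-Laird pooling and heterogeneity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.meta_analysis import combine_effects

from vdrmeta.association import study_effect
from vdrmeta.genetic_models import (
    ContrastTable,
    GeneticModel,
    dataset_contrasts,
)
from vdrmeta.pooling import (
    FIXED_MH,
    RANDOM_DL,
    pool_auto,
    pool_fixed_mh,
    pool_random_dl,
    q_i2,
    select_model,
)


def table(a, b, c, d):
    return ContrastTable(a, b, c, d, unit="persons", model=GeneticModel.HOMOZYGOTE)


SMALL_SETS = [
    [(12, 5, 8, 9), (30, 22, 25, 28)],
    [(3, 9, 4, 11), (14, 6, 10, 8), (20, 20, 18, 25)],
    [(40, 35, 28, 44), (9, 3, 7, 5), (16, 21, 19, 14), (11, 13, 12, 10)],
]


class TestHeterogeneity:
    def test_identical_effects_no_dispersion(self):
        e = study_effect(table(12, 8, 9, 11))
        het = q_i2([e, e])
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0

    def test_single_study_degenerate(self):
        het = q_i2([study_effect(table(5, 6, 7, 8))])
        assert (het.q, het.df, het.p_het, het.i2) == (0.0, 0, 1.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            q_i2([])

    def test_asian_homozygote_triplet_i2(self, rs2228570):
        """Ma + He + Pan homozygote contrasts: published I2 = 21%."""
        asian = rs2228570.subset(["Ma-2020", "He-2015", "Pan-2009"])
        tables = dataset_contrasts(asian, GeneticModel.HOMOZYGOTE)
        het = q_i2([study_effect(t) for t in tables])
        assert het.i2 == pytest.approx(21.0, abs=3.0)


class TestMantelHaenszel:
    def test_single_study_identity(self):
        t = table(12, 5, 8, 9)
        r = pool_fixed_mh([t])
        assert r.pooled_or == pytest.approx(study_effect(t).or_, rel=1e-12)

    @pytest.mark.parametrize("k", [2, 5, 11])
    def test_replication_invariance(self, k):
        t = table(12, 5, 8, 9)
        r = pool_fixed_mh([t] * k)
        assert r.pooled_or == pytest.approx(study_effect(t).or_, rel=1e-12)

    @pytest.mark.parametrize("cells_list", SMALL_SETS)
    def test_brute_force_mh_formula(self, cells_list):
        """MH point estimate checked against independent direct summation."""
        r = pool_fixed_mh([table(*c) for c in cells_list])
        num = sum(a * d / (a + b + c + d) for a, b, c, d in cells_list)
        den = sum(b * c / (a + b + c + d) for a, b, c, d in cells_list)
        assert r.pooled_or == pytest.approx(num / den, rel=1e-12)

    @pytest.mark.parametrize("cells_list", SMALL_SETS)
    def test_against_statsmodels_stratified_table(self, cells_list):
        """Cross-check OR and RBG standard error with statsmodels."""
        sm_tables = [np.array([[a, b], [c, d]]) for a, b, c, d in cells_list]
        st_ = StratifiedTable(sm_tables)
        r = pool_fixed_mh([table(*c) for c in cells_list])
        assert r.pooled_or == pytest.approx(float(st_.oddsratio_pooled), rel=1e-10)
        lo, hi = st_.oddsratio_pooled_confint()
        assert r.ci_low == pytest.approx(float(lo), rel=1e-6)
        assert r.ci_high == pytest.approx(float(hi), rel=1e-6)

    def test_all_excluded_rejected(self):
        t = ContrastTable(0, 5, 0, 7, unit="persons",
                          model=GeneticModel.HOMOZYGOTE, excluded=True)
        with pytest.raises(ValueError, match="excluded"):
            pool_fixed_mh([t])


class TestDerSimonianLaird:
    def test_collapse_to_inverse_variance_when_q_le_df(self):
        t = table(12, 8, 9, 11)
        effects = [study_effect(t), study_effect(t)]
        r = pool_random_dl(effects)
        assert r.tau2 == 0.0
        w = np.array([1 / e.se**2 for e in effects])
        y = np.array([e.log_or for e in effects])
        assert r.log_or == pytest.approx(float(np.sum(w * y) / np.sum(w)), abs=1e-14)

    # heterogeneous sets (Q > df) so tau2 > 0: statsmodels does not
    # truncate a negative moment estimate at zero, so only there do the
    # two routes estimate the same quantity
    HET_SETS = [
        [(60, 20, 20, 60), (15, 45, 50, 18), (30, 30, 28, 33)],
        [(80, 20, 30, 70), (10, 50, 45, 15), (25, 25, 60, 10), (12, 40, 33, 20)],
    ]

    @pytest.mark.parametrize("cells_list", HET_SETS)
    def test_against_statsmodels_combine_effects(self, cells_list):
        effects = [study_effect(table(*c)) for c in cells_list]
        res = combine_effects(
            np.array([e.log_or for e in effects]),
            np.array([e.se**2 for e in effects]),
            method_re="chi2",
        )
        frame = res.summary_frame()
        r = pool_random_dl(effects)
        assert r.tau2 > 0
        assert r.log_or == pytest.approx(
            float(frame.loc["random effect", "eff"]), abs=1e-10
        )
        assert r.tau2 == pytest.approx(float(res.tau2), abs=1e-10)

    def test_accepts_tables_and_counts_persons(self):
        r = pool_random_dl([table(12, 5, 8, 9), table(30, 22, 25, 28)])
        assert r.n_cases == 12 + 5 + 30 + 22
        assert r.n_controls == 8 + 9 + 25 + 28


class TestSelectModel:
    @pytest.mark.parametrize(
        "p_het, i2, expected",
        [
            (0.5, 13.0, FIXED_MH),
            (0.05, 30.0, RANDOM_DL),
            (0.5, 50.0, RANDOM_DL),   # boundary: I2 = 50 is "high"
            (0.10, 0.0, RANDOM_DL),   # boundary: p_het = 0.10 is "high"
        ],
    )
    def test_gate(self, p_het, i2, expected):
        assert select_model(p_het, i2) == expected

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            select_model(-0.1, 10)
        with pytest.raises(ValueError):
            select_model(0.5, 101)


class TestPoolAuto:
    def test_single_study(self):
        t = table(12, 5, 8, 9)
        r = pool_auto([t])
        assert r.pooling == FIXED_MH
        assert r.pooled_or == pytest.approx(study_effect(t).or_, rel=1e-12)

    @pytest.mark.parametrize(
        "snp, model, pooling, expected_or",
        [
            ("rs1544410", "allelic", FIXED_MH, 1.15),
            ("rs7975232", "allelic", FIXED_MH, 0.93),
            ("rs2228570", "allelic", RANDOM_DL, 1.27),
            ("rs731236", "allelic", RANDOM_DL, 1.19),
        ],
    )
    def test_fixture_overall_allelic(
        self, fixture_datasets, snp, model, pooling, expected_or
    ):
        tables = dataset_contrasts(fixture_datasets[snp], GeneticModel(model))
        r = pool_auto([t for t in tables if not t.excluded])
        assert r.pooling == pooling
        assert r.pooled_or == pytest.approx(expected_or, abs=0.02)


effect_sets = st.lists(
    st.tuples(st.integers(1, 60), st.integers(1, 60),
              st.integers(1, 60), st.integers(1, 60)),
    min_size=1, max_size=6,
)


@given(effect_sets)
def test_pooled_log_or_is_convex_combination(cells_list):
    tables = [table(*c) for c in cells_list]
    logs = [study_effect(t).log_or for t in tables]
    for pool in (pool_fixed_mh, pool_random_dl):
        r = pool(tables)
        assert min(logs) - 1e-9 <= r.log_or <= max(logs) + 1e-9


@given(effect_sets)
def test_reciprocity_under_exposure_flip(cells_list):
    tables = [table(*c) for c in cells_list]
    flipped = [t.flipped() for t in tables]
    for pool in (pool_fixed_mh, pool_random_dl):
        a, b = pool(tables), pool(flipped)
        assert a.log_or == pytest.approx(-b.log_or, abs=1e-9)
        assert a.ci_low == pytest.approx(1 / b.ci_high, rel=1e-7)
        assert a.ci_high == pytest.approx(1 / b.ci_low, rel=1e-7)


def test_rs1544410_fixture_ci_and_i2(rs1544410):
    """Published: allelic MH 1.15 [1.09, 1.22], I2 = 13%."""
    r = pool_auto(dataset_contrasts(rs1544410, GeneticModel.ALLELIC))
    assert (round(r.ci_low, 2), round(r.ci_high, 2)) == (1.09, 1.22)
    assert round(r.i2) == 13
    assert math.isclose(r.pooled_or, 1.15, abs_tol=0.005)
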