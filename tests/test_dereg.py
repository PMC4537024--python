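import itertools

import numpy as np
import pandas as pd
import pytest

from tamdereg.dereg import (
    bh_fdr,
    build_table1,
    call_refractory,
    call_up_in_tam_vitro,
    call_up_in_tam_vivo,
    load_table1,
    summarize_table1,
    venn_summaries,
    welchless_ttest,
)
from tamdereg.types import (
    CellType,
    ExpressionStudy,
    GeneClassificationReport,
    Medium,
    SampleMeta,
    Treatment,
)
from .conftest import make_study


def bh_oracle(pvalues):
    """Literal step-up definition: q_i = min over j with p_(j) >= p_(i) of
    m * p_(j) / j, clipped at 1."""
    p = list(pvalues)
    m = len(p)
    ranked = sorted(p)
    out = []
    for pi in p:
        q = min(
            m * pj / (k + 1) for k, pj in enumerate(ranked) if pj >= pi
        )
        out.append(min(q, 1.0))
    return out


class TestTTest:
    def test_identical_groups_p_one(self):
        assert welchless_ttest([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_degenerate_zero_variance_conventions(self):
        assert welchless_ttest([0, 0, 0, 0], [5, 5, 5, 5]) == 0.0
        assert welchless_ttest([2, 2], [2, 2]) == 1.0

    def test_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        # closed form: pooled t with n1+n2-2 df
        from scipy import stats

        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        assert welchless_ttest(x, y) == pytest.approx(p, rel=1e-12)

    def test_power_grows_with_sample_size(self):
        x = [0.0, 0.5, 1.0, 0.2]
        y = [1.0, 1.5, 2.0, 1.2]
        assert welchless_ttest(x * 2, y * 2) < welchless_ttest(x, y)


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.005, 0.04, 0.05]), [0.015, 0.05, 0.05])

    def test_equal_ps_unchanged_and_singleton(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
        np.testing.assert_allclose(bh_fdr([0.07]), [0.07])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_step_up_oracle_exhaustive_short_lists(self):
        grid = np.round(np.arange(0.0, 1.01, 0.01), 2)
        for p1 in grid[::5]:
            np.testing.assert_allclose(bh_fdr([p1]), bh_oracle([p1]), atol=1e-12)
        for p1, p2 in itertools.product(grid[::10], repeat=2):
            np.testing.assert_allclose(bh_fdr([p1, p2]), bh_oracle([p1, p2]), atol=1e-12)

    def test_matches_step_up_oracle_random_lists(self):
        rng = np.random.default_rng(8)
        grid = np.round(np.arange(0.0, 1.01, 0.01), 2)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            p = list(rng.choice(grid, size=n))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_monotone_along_sorted_pvalues(self):
        rng = np.random.default_rng(9)
        p = np.sort(rng.uniform(size=30))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()


def _vivo_study(tam_rows, mdm_rows):
    """Genes x (10 ex vivo TAM + 5 MDM DMSO) FPKM study."""
    tam_rows = np.atleast_2d(tam_rows)
    mdm_rows = np.atleast_2d(mdm_rows)
    data, samples = {}, []
    for i in range(tam_rows.shape[1]):
        sid = f"T{i}"
        data[sid] = tam_rows[:, i]
        samples.append(SampleMeta(sid, CellType.TAM, f"P{i}", Treatment.ASCITES, Medium.ASCITES, f"P{i}"))
    for i in range(mdm_rows.shape[1]):
        sid = f"M{i}"
        data[sid] = mdm_rows[:, i]
        samples.append(SampleMeta(sid, CellType.MDM, f"D{i}", Treatment.DMSO, Medium.R10, f"D{i}"))
    return make_study(data, samples=samples)


class TestVivoCall:
    def test_strong_difference_flagged(self):
        tam = np.tile([4.0, 1.5], (10, 1)).T
        mdm = np.tile([1.0, 1.0], (5, 1)).T
        # break exact ties so the t-test has variance
        rng = np.random.default_rng(0)
        tam = tam * (1 + 0.01 * rng.standard_normal(tam.shape))
        mdm = mdm * (1 + 0.01 * rng.standard_normal(mdm.shape))
        study = _vivo_study(tam, mdm)
        out = call_up_in_tam_vivo(study, {"G0", "G1"})
        # G0: log2(4.1/1.1) ~ 1.9 >= 1 and highly significant
        assert bool(out.loc["G0", "up_in_tam_vivo"])
        # G1: log2(1.6/1.1) ~ 0.55 < 1
        assert not bool(out.loc["G1", "up_in_tam_vivo"])
        assert out.loc["G1", "logfc_vivo"] == pytest.approx(np.log2(1.6 / 1.1), abs=0.05)

    def test_restricted_to_target_genes(self):
        study = _vivo_study(np.full((2, 10), 4.0), np.full((2, 5), 1.0))
        out = call_up_in_tam_vivo(study, {"G0"})
        assert list(out.index) == ["G0"]

    def test_empty_target_set_is_error(self):
        study = _vivo_study(np.full((1, 10), 4.0), np.full((1, 5), 1.0))
        with pytest.raises(ValueError):
            call_up_in_tam_vivo(study, set())

    def test_synthetic_recovery_of_planted_tam_up_set(self, default_sim):
        design, study, truth, _, _ = default_sim
        targets = set(truth.index[truth["is_direct_target"]])
        out = call_up_in_tam_vivo(study, targets)
        planted = set(truth.index[truth["is_tam_up"]])
        called = set(out.index[out["up_in_tam_vivo"]])
        assert len(called & planted) >= len(planted) - 2
        assert len(called - planted) <= 2


class TestVitroCall:
    def _study(self, tam, mdms):
        data = {"T_DMSO": np.atleast_1d(tam)}
        samples = [
            SampleMeta("T_DMSO", CellType.TAM, "P1", Treatment.DMSO, Medium.ASCITES, "P1")
        ]
        for i, col in enumerate(np.atleast_2d(mdms).T):
            sid = f"M{i}"
            data[sid] = col
            samples.append(SampleMeta(sid, CellType.MDM, f"D{i}", Treatment.DMSO, Medium.R10, f"D{i}"))
        return make_study(data, samples=samples)

    def test_both_conditions_must_hold_against_every_mdm(self):
        study = self._study([2.0], [[1.0, 1.2]])
        assert bool(call_up_in_tam_vitro(study, {"G0"}).loc["G0"])

    def test_margin_failure_blocks(self):
        study = self._study([1.4], [[1.0, 1.0]])
        assert not bool(call_up_in_tam_vitro(study, {"G0"}).loc["G0"])

    def test_equal_expression_not_flagged(self):
        study = self._study([1.0], [[1.0, 1.0]])
        assert not bool(call_up_in_tam_vitro(study, {"G0"}).loc["G0"])


class TestRefractory:
    def test_half_induction_rule(self):
        assert call_refractory(mdm_fc=10, tam_fc=4, tam_logfc=2.0)  # 40% < 50%
        assert not call_refractory(mdm_fc=10, tam_fc=6, tam_logfc=np.log2(6))

    def test_logfc_threshold_rule(self):
        # strong MDM induction but TAM logFC below 1 is refractory even at
        # >50% relative induction
        assert call_refractory(mdm_fc=1.8, tam_fc=1.7, tam_logfc=np.log2(1.7))

    def test_pdk4_like_gene(self):
        # 99-fold in MDMs, <10-fold in TAMs: refractory
        assert call_refractory(mdm_fc=99.0, tam_fc=9.5, tam_logfc=np.log2(9.5))

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            call_refractory(mdm_fc=0, tam_fc=1, tam_logfc=0)


class TestTable1:
    def test_packaged_table_counts(self):
        counts = summarize_table1(load_table1())
        assert counts["n_upregulated"] == 54
        assert counts["n_refractory"] == 32

    def test_build_rows_are_ligand_regulated_and_up_in_vivo(self):
        table = pd.DataFrame(
            {
                "agonist_up_mdm": [True, True, False, True],
                "ligand_regulated": [True, True, True, True],
                "inverse_down_mdm": [False, False, True, False],
                "agonist_vs_inverse_up_mdm": [False, False, False, False],
                "up_in_tam_vivo": [True, False, True, True],
                "peak_associated_tam": [True, False, False, False],
                "peak_associated_mdm": [False, False, False, True],
                "refractory_in_tam": [True, False, False, False],
            },
            index=["G1", "G2", "G3", "G4"],
        )
        report = GeneClassificationReport(table=table)
        t1, counts = build_table1(report, pd.DataFrame())
        assert set(t1.index) == {"G1", "G3", "G4"}
        assert counts == {"n_upregulated": 3, "n_refractory": 1, "n_peak": 2}
        # independent set computation
        expected = report.gene_set("ligand_regulated") & report.gene_set("up_in_tam_vivo")
        assert set(t1.index) == expected

    def test_empty_report_empty_table(self):
        report = GeneClassificationReport(table=pd.DataFrame(index=pd.Index([])))
        t1, counts = build_table1(report, pd.DataFrame())
        assert len(t1) == 0 and counts["n_upregulated"] == 0


class TestVennSummaries:
    def test_intersection_counts(self):
        table = pd.DataFrame(
            {
                "agonist_up_mdm": [True] * 4,
                "ligand_regulated": [True] * 4,
                "up_in_tam_vivo": [True, True, True, False],
                "up_in_tam_vitro": [False, True, True, True],
                "refractory_in_tam": [True, True, False, False],
            },
            index=["a", "b", "c", "d"],
        )
        out = venn_summaries(GeneClassificationReport(table=table))
        assert out["up_in_tam_vivo"] == 3
        assert out["up_in_tam_vitro"] == 3
        assert out["up_in_tam_vivo&up_in_tam_vitro"] == 2
        assert out["up_in_tam_vivo&refractory_in_tam"] == 2
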