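"""The correlation engine: per-pair OLS, BH FDR, cis/trans annotation, and
the Model/Results interface."""
import numpy as np
import pytest
from scipy import stats

from screqtl import (
    CovariateMatrix, GeneModel, PairSkipped, ReqtlRecord, ScReqtlModel,
    SnvLocus, ValidationError, annotate_cis_trans, bh_fdr, fit_snv_gene,
    run_reqtl,
)
from screqtl.ge_prep import NormalizedExpression
from screqtl.vaf import VafMatrix


def make_vaf_matrix(vaf_rows, cells=None):
    vaf = np.asarray(vaf_rows, dtype=float)
    mask = np.isfinite(vaf)
    loci = [SnvLocus("chr1", 100 + i, "A", "G") for i in range(vaf.shape[0])]
    cells = cells or [f"C{j}" for j in range(vaf.shape[1])]
    return VafMatrix(loci, cells, vaf, np.where(mask, 10, 0), mask, 10)


def make_norm(scaled, cells=None):
    scaled = np.asarray(scaled, dtype=float)
    cells = cells or [f"C{j}" for j in range(scaled.shape[1])]
    return NormalizedExpression(
        [f"G{i}" for i in range(scaled.shape[0])], cells, scaled, scaled
    )


class TestFitSnvGene:
    def test_perfect_linear_fit(self, rng):
        vaf = rng.random(20)
        beta, t, p, n = fit_snv_gene(vaf, 2.0 * vaf, None)
        assert beta == pytest.approx(2.0, abs=1e-10)
        assert n == 20
        assert p < 1e-12

    def test_constant_vaf_skipped(self):
        with pytest.raises(PairSkipped, match="degenerate"):
            fit_snv_gene(np.full(10, 0.5), np.arange(10.0), None)

    def test_exhausted_degrees_of_freedom_skipped(self, rng):
        vaf = rng.random(4)
        covars = rng.normal(size=(4, 3))  # p = 5 > n = 4
        with pytest.raises(PairSkipped, match="covariates"):
            fit_snv_gene(vaf, rng.normal(size=4), covars)

    def test_masked_cells_excluded(self, rng):
        vaf = np.concatenate([rng.random(15), [np.nan] * 5])
        expr = np.concatenate([3.0 * vaf[:15], rng.normal(size=5)])
        beta, _, _, n = fit_snv_gene(vaf, expr, None)
        assert n == 15
        assert beta == pytest.approx(3.0, abs=1e-10)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            n, k = 30, 3
            vaf = rng.random(n)
            covars = rng.normal(size=(n, k))
            expr = rng.normal(size=n)
            beta, t, p, _ = fit_snv_gene(vaf, expr, covars)
            x = sm.add_constant(np.column_stack([vaf, covars]))
            fit = sm.OLS(expr, x).fit()
            assert beta == pytest.approx(fit.params[1], abs=1e-9)
            assert t == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_reproduces_pearson_correlation_t(self, rng):
        """With no covariates the OLS t equals r*sqrt((n-2)/(1-r^2))."""
        n = 40
        vaf = rng.random(n)
        expr = 0.5 * vaf + rng.normal(size=n)
        _, t, _, _ = fit_snv_gene(vaf, expr, None)
        r = np.corrcoef(vaf, expr)[0, 1]
        expected = r * np.sqrt((n - 2) / (1 - r**2))
        assert t == pytest.approx(expected, abs=1e-10)

    def test_all_zero_covariate_column_is_harmless(self, rng):
        n = 25
        vaf = rng.random(n)
        covars = rng.normal(size=(n, 2))
        expr = rng.normal(size=n)
        beta_ref, _, _, _ = fit_snv_gene(vaf, expr, covars)
        padded = np.column_stack([covars, np.zeros(n)])
        beta_pad, _, _, _ = fit_snv_gene(vaf, expr, padded)
        assert beta_pad == pytest.approx(beta_ref, abs=1e-10)

    def test_null_p_values_are_uniform(self, rng):
        p_values = []
        for _ in range(1000):
            vaf = rng.random(25)
            expr = rng.normal(size=25)
            _, _, p, _ = fit_snv_gene(vaf, expr, None)
            p_values.append(p)
        ks = stats.kstest(p_values, "uniform")
        assert ks.pvalue > 0.01


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_is_identity(self):
        assert bh_fdr([0.04]) == [0.04]

    def test_order_preserving_with_input(self):
        q = bh_fdr([0.5, 0.001, 0.04])
        assert q[1] < q[2] < q[0]

    def test_q_at_least_p_and_monotone(self, rng):
        for _ in range(20):
            p = rng.random(size=int(rng.integers(1, 50)))
            q = np.array(bh_fdr(p))
            assert np.all(q >= p - 1e-15)
            assert np.all(q <= 1.0)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        q = bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_ties_get_equal_q(self):
        q = bh_fdr([0.02, 0.02, 0.5])
        assert q[0] == q[1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValidationError):
            bh_fdr([-0.1])

    def test_empty_input(self):
        assert bh_fdr([]) == []


class TestCisTransAnnotation:
    GENES = [
        GeneModel("AKR1C1", "AKR1C1", "chr10", 4969097, 4987351, "+"),
        GeneModel("AKR1C2", "AKR1C2", "chr10", 5005000, 5040000, "-"),
    ]

    @staticmethod
    def _record(chrom, pos, gene):
        return ReqtlRecord(SnvLocus(chrom, pos, "G", "A"), gene,
                           beta=1.0, t_stat=2.0, p_value=0.01, q_value=0.02)

    def test_harboring_gene_is_cis_neighbor_is_trans(self):
        records = [self._record("chr10", 4977767, "AKR1C1"),
                   self._record("chr10", 4977767, "AKR1C2")]
        annotated = annotate_cis_trans(records, self.GENES)
        assert [r.cls for r in annotated] == ["cis", "trans"]

    def test_closed_interval_boundaries(self):
        start = annotate_cis_trans([self._record("chr10", 4969097, "AKR1C1")],
                                   self.GENES)
        end = annotate_cis_trans([self._record("chr10", 4987351, "AKR1C1")],
                                 self.GENES)
        outside = annotate_cis_trans([self._record("chr10", 4987352, "AKR1C1")],
                                     self.GENES)
        assert start[0].cls == "cis" and end[0].cls == "cis"
        assert outside[0].cls == "trans"

    def test_gene_without_model_flagged_not_dropped(self):
        annotated = annotate_cis_trans([self._record("chr10", 1, "UNKNOWN")],
                                       self.GENES)
        assert len(annotated) == 1 and annotated[0].cls == "unannotated"

    def test_matches_brute_force_interval_checks(self, rng):
        genes = []
        for i in range(20):
            start = int(rng.integers(1, 10000))
            genes.append(GeneModel(f"g{i}", f"g{i}", f"chr{rng.integers(1, 4)}",
                                   start, start + int(rng.integers(10, 2000))))
        records = [
            self._record(f"chr{rng.integers(1, 4)}", int(rng.integers(1, 12000)),
                         f"g{rng.integers(0, 20)}")
            for _ in range(50)
        ]
        annotated = annotate_cis_trans(records, genes)
        by_id = {g.gene_id: g for g in genes}
        for r in annotated:
            g = by_id[r.gene_id]
            expected = ("cis" if (g.chrom == r.locus.chrom
                                  and g.start <= r.locus.pos <= g.end)
                        else "trans")
            assert r.cls == expected


class TestRunReqtl:
    def test_pair_enumeration(self, rng):
        m = make_vaf_matrix(rng.random((2, 30)))
        norm = make_norm(rng.normal(size=(3, 30)))
        records, skipped = run_reqtl(m, norm, None, min_cells=10)
        assert len(records) == 6 and not skipped
        assert {(r.locus.label, r.gene_id) for r in records} == {
            (l.label, g) for l in m.loci for g in norm.genes
        }

    def test_constant_vaf_locus_pairs_carry_reasons(self, rng):
        vaf = np.vstack([np.full(30, 0.5), rng.random(30)])
        m = make_vaf_matrix(vaf)
        norm = make_norm(rng.normal(size=(3, 30)))
        records, skipped = run_reqtl(m, norm, None, min_cells=10)
        assert len(records) == 3
        assert len(skipped) == 3
        assert all(s.reason == "degenerate regressor" for s in skipped)
        assert {s.locus for s in skipped} == {m.loci[0]}

    def test_q_values_assigned_within_group(self, rng):
        m = make_vaf_matrix(rng.random((2, 40)))
        norm = make_norm(rng.normal(size=(5, 40)))
        records, _ = run_reqtl(m, norm, None, min_cells=10)
        from screqtl import bh_fdr as bh
        expected = bh([r.p_value for r in records])
        assert [r.q_value for r in records] == pytest.approx(expected)

    def test_invariant_to_cell_ordering(self, rng):
        n = 30
        vaf = rng.random((2, n))
        scaled = rng.normal(size=(4, n))
        cov = rng.normal(size=(n, 2))
        perm = rng.permutation(n)
        cells = [f"C{j}" for j in range(n)]
        cells_p = [cells[j] for j in perm]
        rec_a, _ = run_reqtl(make_vaf_matrix(vaf, cells), make_norm(scaled, cells),
                             CovariateMatrix(cells, cov), min_cells=10)
        rec_b, _ = run_reqtl(make_vaf_matrix(vaf[:, perm], cells_p),
                             make_norm(scaled[:, perm], cells_p),
                             CovariateMatrix(cells_p, cov[perm]), min_cells=10)
        key = lambda r: (r.locus.label, r.gene_id)
        for a, b in zip(sorted(rec_a, key=key), sorted(rec_b, key=key)):
            assert a.beta == pytest.approx(b.beta, abs=1e-10)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-10)

    def test_empty_locus_set_returns_empty(self, rng):
        m = make_vaf_matrix(np.empty((0, 10)))
        norm = make_norm(rng.normal(size=(3, 10)))
        records, skipped = run_reqtl(m, norm, None)
        assert records == [] and skipped == []

    def test_mismatched_cells_rejected(self, rng):
        m = make_vaf_matrix(rng.random((1, 10)))
        norm = make_norm(rng.normal(size=(2, 10)), cells=[f"X{j}" for j in range(10)])
        with pytest.raises(ValidationError):
            run_reqtl(m, norm, None)


class TestModelResults:
    def _fitted(self, rng):
        n = 50
        vaf = rng.random((3, n))
        expr = rng.normal(size=(4, n))
        expr[0] += 2.0 * vaf[0]  # one strong pair
        m = make_vaf_matrix(vaf)
        norm = make_norm(expr)
        genes = [GeneModel(g, g, "chr1", 90 + i, 110 + i)
                 for i, g in enumerate(norm.genes)]
        return ScReqtlModel(m, norm, None, gene_models=genes,
                            group=("S1", "adipose"), min_cells=10).fit()

    def test_records_annotated_and_sorted_frame(self, rng):
        res = self._fitted(rng)
        assert all(r.cls in {"cis", "trans"} for r in res.records)
        q = res.frame["q"].to_numpy()
        assert np.all(np.diff(q) >= 0)

    def test_significant_subset(self, rng):
        res = self._fitted(rng)
        sig = res.significant(0.05)
        assert all(r.q_value <= 0.05 for r in sig)
        assert any(r.gene_id == "G0" and r.locus.label.endswith("100_A>G")
                   for r in sig)

    def test_summary_reports_counts(self, rng):
        res = self._fitted(rng)
        text = res.summary()
        assert "pairs fitted:               12" in text
        assert "('S1', 'adipose')" in text
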