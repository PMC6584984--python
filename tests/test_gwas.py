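import numpy as np
import pytest

from helpers import snp_blup
from ssgwas.analysis import emmax_reference_scan, run_association
from ssgwas.containers import RelationshipMatrix
from ssgwas.exceptions import NumericalError
from ssgwas.genomic import MarkerFrequencies
from ssgwas.gwas import (
    FLAG_NO_INFO,
    BacksolveScale,
    backsolve_snp_effects,
    bonferroni_threshold,
    emmax_scan,
    inflation_factor,
    snp_prediction_error_variance,
    snp_pvalues,
    to_fixed_regression,
    variance_explained,
)
from ssgwas.simulate import SimConfig, make_dataset
from ssgwas.ssgblup_core import PevBlock, VarianceComponents
from ssgwas.studies import base_frequency_panel


def _full_run(ds, vc, **kw):
    """Unblended full-rank setup: base-frequency centering on the
    MAF-filtered panel of a fully genotyped dataset."""
    panel, freqs = base_frequency_panel(ds)
    kw.setdefault("alpha", 0.0)
    kw.setdefault("blend", (0.0, 1.0))
    kw.setdefault("frequencies", freqs)
    kw.setdefault("qc", False)
    return run_association(ds.pedigree, panel, ds.phenotypes, vc, **kw)


class TestBacksolve:
    def test_zero_breeding_values_give_zero_effects(self, rng):
        Z = rng.normal(size=(5, 9))
        G = RelationshipMatrix(Z @ Z.T / 4.0 + np.eye(5) * 0.01,
                               tuple("abcde"), "G_blended")
        s = BacksolveScale(alpha=0.0, b=1.0, sum2pq=4.0)
        a = backsolve_snp_effects(Z, G, np.zeros(5), s)
        np.testing.assert_array_equal(a, 0.0)

    def test_single_marker_single_animal_closed_form(self):
        z, u, s2pq = 0.8, 0.31, 0.5
        Z = np.array([[z]])
        G = RelationshipMatrix([[z * z / s2pq]], ("a",), "G_raw")
        a = backsolve_snp_effects(Z, G, np.array([u]), BacksolveScale(0.0, 1.0, s2pq))
        assert a[0] == pytest.approx(u / z, rel=1e-12)

    def test_matches_snp_blup_solutions(self, full_geno_dataset, vc):
        run = _full_run(full_geno_dataset, vc)
        m = run.model
        a_oracle, _ = snp_blup(
            m.y, m.X, m.W[:, run.geno_index], run.Z,
            vc.sigma_u2, vc.sigma_e2, run.frequencies.sum2pq,
            S=m.extra_random, sigma_pe2=vc.sigma_pe2,
        )
        a_hat = run.result.table["a_hat"].to_numpy()
        np.testing.assert_allclose(a_hat, a_oracle, atol=1e-8)


class TestSnpVariance:
    def _setup(self, rng, n=6, m=12):
        Z = rng.normal(size=(n, m))
        f = MarkerFrequencies(rng.uniform(0.2, 0.8, m))
        G = RelationshipMatrix(Z @ Z.T / f.sum2pq, tuple(str(i) for i in range(n)), "G_raw")
        return Z, f, G

    def test_no_information_gives_zero_variance(self, rng, vc):
        Z, f, G = self._setup(rng)
        s = BacksolveScale(0.0, 1.0, f.sum2pq)
        var_a, clamped = snp_prediction_error_variance(
            Z, G, PevBlock(G.values * vc.sigma_u2), vc, s
        )
        np.testing.assert_allclose(var_a, 0.0, atol=1e-12)
        pv = snp_pvalues(np.zeros(Z.shape[1]), var_a)
        assert (pv["flag"] == FLAG_NO_INFO).all()

    def test_perfect_knowledge_limit(self, rng, vc):
        Z, f, G = self._setup(rng)
        s = BacksolveScale(0.0, 1.0, f.sum2pq)
        var_a, _ = snp_prediction_error_variance(
            Z, G, PevBlock(np.zeros(G.values.shape)), vc, s
        )
        Gi = np.linalg.inv(G.values)
        expect = s.scale**2 * vc.sigma_u2 * np.einsum("ij,jk,ik->i", Z.T, Gi, Z.T)
        np.testing.assert_allclose(var_a, expect, atol=1e-10)

    def test_inconsistent_inputs_raise(self, rng, vc):
        Z, f, G = self._setup(rng)
        s = BacksolveScale(0.0, 1.0, f.sum2pq)
        too_big = PevBlock(G.values * vc.sigma_u2 * 2.0)  # PEV beyond the prior
        with pytest.raises(NumericalError, match="negative"):
            snp_prediction_error_variance(Z, G, too_big, vc, s)

    def test_matches_snp_blup_variances(self, full_geno_dataset, vc):
        run = _full_run(full_geno_dataset, vc)
        m = run.model
        _, var_oracle = snp_blup(
            m.y, m.X, m.W[:, run.geno_index], run.Z,
            vc.sigma_u2, vc.sigma_e2, run.frequencies.sum2pq,
            S=m.extra_random, sigma_pe2=vc.sigma_pe2,
        )
        sd = run.result.table["sd_a"].to_numpy()
        np.testing.assert_allclose(sd**2, var_oracle, atol=1e-8)


class TestPvalues:
    def test_zero_effect_p_one(self):
        pv = snp_pvalues(np.array([0.0]), np.array([1.0]))
        assert pv["pvalue"][0] == 1.0

    def test_normal_quantile_identity(self):
        pv = snp_pvalues(np.array([1.959964]), np.array([1.0]))
        assert pv["pvalue"][0] == pytest.approx(0.05, abs=1e-6)

    def test_tail_matches_arbitrary_precision(self):
        import sympy

        z = 6.0
        pv = snp_pvalues(np.array([z]), np.array([1.0]))
        exact = 2 * (sympy.Rational(1, 2) * sympy.erfc(sympy.Float(z) / sympy.sqrt(2)))
        exact_neglog10 = float(-sympy.log(exact, 10))
        assert pv["neglog10p"][0] == pytest.approx(exact_neglog10, rel=1e-10)

    def test_no_underflow_for_large_z(self):
        pv = snp_pvalues(np.array([37.0]), np.array([1.0]))
        assert np.isfinite(pv["neglog10p"][0]) and pv["neglog10p"][0] > 250

    def test_bh_adjustment_passes_nan_and_keeps_order(self):
        from ssgwas.gwas import bh_adjust

        p = np.array([0.001, np.nan, 0.04, 0.5])
        out = bh_adjust(p)
        assert np.isnan(out[1])
        assert out[0] <= out[2] <= out[3]
        ok = np.isfinite(p)
        assert (out[ok] >= p[ok]).all()


class TestVarianceExplained:
    @pytest.mark.parametrize(
        "p,a,expected",
        [(0.28, -0.041, 0.000678), (0.46, 0.043, 0.000919), (0.5, 0.0, 0.0)],
    )
    def test_worked_values(self, p, a, expected):
        raw, pct = variance_explained(np.array([p]), np.array([a]), sigma_u2=1.0)
        assert raw[0] == pytest.approx(expected, rel=5e-3)
        assert pct[0] == pytest.approx(expected * 100, rel=5e-3)


class TestFixedRegression:
    def test_fixed_point_when_var_equals_prior(self):
        b, vb = to_fixed_regression(np.array([0.2]), np.array([0.7]), sigma_a2=0.7)
        assert b[0] == pytest.approx(0.2)
        assert vb[0] == pytest.approx(0.7)

    def test_z_statistic_preserved(self, rng):
        a = rng.normal(size=20)
        va = rng.uniform(0.1, 2.0, 20)
        b, vb = to_fixed_regression(a, va, sigma_a2=0.48)
        np.testing.assert_allclose(b / np.sqrt(vb), a / np.sqrt(va), atol=1e-12)

    def test_matches_emmax_fixed_estimates(self, full_geno_dataset, vc):
        run = _full_run(full_geno_dataset, vc)
        scan = emmax_reference_scan(run, vc)
        tab = run.result.table
        b, vb = to_fixed_regression(
            tab["a_hat"].to_numpy(), tab["sd_a"].to_numpy() ** 2,
            run.scale.scale * vc.sigma_u2,
        )
        np.testing.assert_allclose(b, scan["b_hat"].to_numpy(), rtol=1e-6, atol=1e-6)
        np.testing.assert_allclose(vb, scan["var_b"].to_numpy(), rtol=1e-6)


class TestBonferroni:
    def test_reported_genomewide_threshold(self):
        assert round(bonferroni_threshold(0.05, 38122), 1) == 5.9

    def test_small_cases(self):
        assert bonferroni_threshold(0.05, 1) == pytest.approx(1.30103, abs=1e-5)
        assert bonferroni_threshold(1.0, 10) == pytest.approx(1.0)


class TestInflationFactor:
    def test_uniform_pvalues_lambda_near_one(self):
        rng = np.random.default_rng(99)
        lam, _ = inflation_factor(rng.uniform(size=10_000))
        assert 0.95 < lam < 1.05

    def test_constant_half_gives_exactly_one(self):
        lam, _ = inflation_factor(np.full(100, 0.5))
        assert lam == pytest.approx(1.0)

    def test_enrichment_inflates(self):
        rng = np.random.default_rng(7)
        lam, _ = inflation_factor(rng.uniform(size=1000) ** 3)
        assert lam > 1.0


class TestEmmaxScan:
    def test_constant_marker_flagged_nan(self, vc):
        ds = make_dataset(SimConfig(n_founders=20, n_generations=1, n_markers=90,
                                    seed=5, genotyping_rule="all"))
        run = _full_run(ds, vc)
        Z = run.Z.copy()
        Z[:, 0] = 0.0
        scan = emmax_scan(_geno_model(run), Z, run.G, vc)
        assert np.isnan(scan["pvalue"][0])

    def test_null_type_one_error_rate(self, vc):
        """200 fully genotyped animals, 500 null markers: empirical rate at
        0.05 within a (correlation-widened) Monte-Carlo band."""
        ds = make_dataset(SimConfig(n_founders=50, n_generations=3, n_markers=500,
                                    seed=31, genotyping_rule="all"))
        run = _full_run(ds, vc)
        scan = emmax_scan(_geno_model(run), run.Z, run.G, vc)
        p = scan["pvalue"].to_numpy()
        rate = np.mean(p[np.isfinite(p)] < 0.05)
        assert 0.02 < rate < 0.09

    def test_equivalence_with_backsolved_pvalues(self, full_geno_dataset, vc):
        run = _full_run(full_geno_dataset, vc)
        scan = emmax_reference_scan(run, vc)
        dp = np.abs(run.result.table["pvalue"].to_numpy() - scan["pvalue"].to_numpy())
        assert np.nanmax(dp) < 1e-8


def _geno_model(run):
    """Record-to-genotyped-animal model for direct emmax_scan calls."""
    import scipy.sparse as sp
    from ssgwas.ssgblup_core import ModelSpec

    W = sp.csr_matrix(run.model.W)[:, run.geno_index]
    return ModelSpec(
        y=run.model.y, X=run.model.X, W=W,
        animal_ids=run.genotypes.animal_ids,
        extra_random=run.model.extra_random,
    )


class TestInvariances:
    def test_scale_invariance_of_statistics(self, vc):
        ds = make_dataset(SimConfig(n_founders=30, n_generations=2, n_markers=80,
                                    seed=13, qtl=((7, 0.3),)))
        run1 = run_association(ds.pedigree, ds.genotypes, ds.phenotypes, vc)
        c = 3.7
        ph = ds.phenotypes.copy()
        ph["y"] = ph["y"].astype(float) * c
        vc2 = VarianceComponents(
            vc.sigma_u2 * c**2, vc.sigma_e2 * c**2, vc.sigma_pe2 * c**2
        )
        run2 = run_association(ds.pedigree, ds.genotypes, ph, vc2)
        np.testing.assert_allclose(
            run1.result.table["z"].to_numpy(),
            run2.result.table["z"].to_numpy(),
            atol=1e-10,
        )
        np.testing.assert_allclose(
            run1.result.table["pvalue"].to_numpy(),
            run2.result.table["pvalue"].to_numpy(),
            atol=1e-10,
        )

    def test_constraint_choice_does_not_move_pvalues(self, vc):
        ds = make_dataset(SimConfig(n_founders=30, n_generations=2, n_markers=80,
                                    seed=17))
        runs = [
            run_association(ds.pedigree, ds.genotypes, ds.phenotypes, vc, coding=c)
            for c in ("treatment", "sum")
        ]
        np.testing.assert_allclose(
            runs[0].result.table["pvalue"].to_numpy(),
            runs[1].result.table["pvalue"].to_numpy(),
            atol=1e-10,
        )

    def test_null_calibration_pooled(self, vc):
        """Pooled over 5 no-QTL replicates at reduced scale: type-I error
        near 0.05 and pooled genomic-control λ in [0.9, 1.1]."""
        pvals = []
        for seed in range(41, 46):
            ds = make_dataset(SimConfig(n_founders=80, n_generations=2,
                                        n_markers=400, seed=seed))
            run = run_association(ds.pedigree, ds.genotypes, ds.phenotypes, vc)
            p = run.result.table["pvalue"].to_numpy()
            pvals.append(p[np.isfinite(p)])
        p = np.concatenate(pvals)
        rate = np.mean(p < 0.05)
        assert 0.03 < rate < 0.07
        lam, _ = inflation_factor(p)
        assert 0.9 < lam < 1.1
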