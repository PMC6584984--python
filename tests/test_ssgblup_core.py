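import numpy as np
import pytest
import scipy.sparse as sp

from helpers import gls_blup, snp_blup
from ssgwas.analysis import build_model_spec, run_association
from ssgwas.containers import RelationshipMatrix
from ssgwas.exceptions import InputError
from ssgwas.genomic import MarkerFrequencies
from ssgwas.pedigree import Pedigree, build_A, build_A_inverse, extract_A22
from ssgwas.ssgblup_core import (
    ModelSpec,
    VarianceComponents,
    assemble_mme,
    build_H_inverse,
    build_fixed_design,
    incidence_matrix,
    pev_genotyped,
    solve_mme,
)


def _model_from_dataset(ds, vc, ped=None):
    return build_model_spec(ds.phenotypes, ped or ds.pedigree, pe_col="dam")


class TestBuildHInverse:
    def test_no_genotyped_animals_returns_A_inverse(self):
        p = Pedigree(("s", "d", "o"), (None, None, "s"), (None, None, "d"))
        Ainv = build_A_inverse(p)
        empty = RelationshipMatrix(np.zeros((0, 0)), (), "A22")
        H = build_H_inverse(Ainv, empty, RelationshipMatrix(np.zeros((0, 0)), (), "G_blended"),
                            np.array([], dtype=int))
        np.testing.assert_allclose(H.toarray(), Ainv.toarray())

    def test_G_equal_A22_cancels(self, small_dataset):
        ped = small_dataset.pedigree
        ids = small_dataset.genotyped_ids
        A22 = extract_A22(ped, ids)
        G = RelationshipMatrix(A22.values.copy(), ids, "G_blended")
        Ainv = build_A_inverse(ped)
        gi = np.array([ped.order_index[a] for a in ids])
        H = build_H_inverse(Ainv, A22, G, gi)
        np.testing.assert_allclose(H.toarray(), Ainv.toarray(), atol=1e-8)

    def test_matches_partitioned_projection(self, small_dataset, vc):
        """inv(H⁻¹) equals the explicit pedigree-projection of G onto
        ungenotyped relatives."""
        run = run_association(
            small_dataset.pedigree, small_dataset.genotypes,
            small_dataset.phenotypes, vc,
        )
        ped = small_dataset.pedigree
        A = build_A(ped).values
        gi = run.geno_index
        mask = np.zeros(ped.n, bool)
        mask[gi] = True
        i1 = np.flatnonzero(~mask)
        A12 = A[np.ix_(i1, gi)]
        P = A12 @ np.linalg.inv(run.A22.values)
        G = run.G.values
        H = np.zeros((ped.n, ped.n))
        H[np.ix_(i1, i1)] = A[np.ix_(i1, i1)] - P @ A12.T + P @ G @ P.T
        H[np.ix_(i1, gi)] = P @ G
        H[np.ix_(gi, i1)] = (P @ G).T
        H[np.ix_(gi, gi)] = G
        Ainv = build_A_inverse(ped)
        Hinv = build_H_inverse(Ainv, run.A22, run.G, gi)
        np.testing.assert_allclose(np.linalg.inv(Hinv.toarray()), H, atol=1e-6)


class TestAssembleAndSolve:
    def test_dimension_counting(self):
        p = Pedigree(("a", "b", "c"), (None,) * 3, (None,) * 3)
        W, _ = incidence_matrix(["a", "b", "c"], level_order=p.ids)
        model = ModelSpec(
            y=np.array([1.0, 2.0, 3.0]), X=np.ones((3, 1)), W=W, animal_ids=p.ids
        )
        sys = assemble_mme(model, build_A_inverse(p), VarianceComponents(1.0, 1.0))
        assert sys.n == 4
        assert sys.block_index["fixed"] == slice(0, 1)
        assert sys.block_index["animal"] == slice(1, 4)

    def test_solver_residual_contract(self, small_dataset, vc):
        run = run_association(
            small_dataset.pedigree, small_dataset.genotypes,
            small_dataset.phenotypes, vc,
        )
        sol = np.concatenate(
            [run.solutions.beta_hat, run.solutions.u_hat, run.solutions.extra_hat]
        )
        r = run.mme.lhs @ sol - run.mme.rhs
        assert np.abs(r).max() < 1e-8 * np.abs(run.mme.rhs).max()

    def test_extreme_shrinkage_zeroes_breeding_values(self):
        p = Pedigree(("a", "b", "c"), (None,) * 3, (None,) * 3)
        W, _ = incidence_matrix(["a", "b", "c"], level_order=p.ids)
        model = ModelSpec(
            y=np.array([1.0, 3.0, 5.0]), X=np.ones((3, 1)), W=W, animal_ids=p.ids
        )
        vc = VarianceComponents(sigma_u2=1e-8, sigma_e2=1.0)  # lambda_u = 1e8
        sol = solve_mme(assemble_mme(model, build_A_inverse(p), vc))
        assert np.abs(sol.u_hat).max() < 1e-6
        assert sol.beta_hat[0] == pytest.approx(3.0, abs=1e-6)

    def test_rank_deficient_fixed_effects_rejected(self):
        p = Pedigree(("a", "b"), (None, None), (None, None))
        W, _ = incidence_matrix(["a", "b"], level_order=p.ids)
        X = np.ones((2, 2))  # duplicated intercept
        model = ModelSpec(y=np.array([1.0, 2.0]), X=X, W=W, animal_ids=p.ids)
        with pytest.raises(InputError, match="rank deficient"):
            assemble_mme(model, build_A_inverse(p), VarianceComponents(1.0, 1.0))

    def test_matches_variance_form_blup(self, small_dataset, vc):
        """MME solutions equal GLS/BLUP computed from the full phenotypic
        covariance V = WHW'σu² + SS'σpe² + Iσe² (independent oracle)."""
        run = run_association(
            small_dataset.pedigree, small_dataset.genotypes,
            small_dataset.phenotypes, vc,
        )
        ped = small_dataset.pedigree
        Ainv = build_A_inverse(ped)
        Hinv = build_H_inverse(Ainv, run.A22, run.G, run.geno_index)
        H = np.linalg.inv(Hinv.toarray())
        m = run.model
        beta, u, extra = gls_blup(
            m.y, m.X, m.W, H, vc.sigma_u2, vc.sigma_e2, m.extra_random, vc.sigma_pe2
        )
        np.testing.assert_allclose(run.solutions.beta_hat, beta, atol=1e-7)
        np.testing.assert_allclose(run.solutions.u_hat, u, atol=1e-7)
        np.testing.assert_allclose(run.solutions.extra_hat, extra, atol=1e-7)

    def test_pedigree_blup_when_H_is_A(self, small_dataset, vc):
        """With no genomic information (H⁻¹ = A⁻¹) the system reproduces
        plain pedigree BLUP."""
        ped = small_dataset.pedigree
        model = _model_from_dataset(small_dataset, vc)
        Ainv = build_A_inverse(ped)
        sol = solve_mme(assemble_mme(model, Ainv, vc))
        A = build_A(ped).values
        beta, u, _ = gls_blup(
            model.y, model.X, model.W, A, vc.sigma_u2, vc.sigma_e2,
            model.extra_random, vc.sigma_pe2,
        )
        np.testing.assert_allclose(sol.beta_hat, beta, atol=1e-7)
        np.testing.assert_allclose(sol.u_hat, u, atol=1e-7)


class TestPev:
    def test_animal_without_data_keeps_prior_variance(self):
        # record on one founder; the other founder is unrelated and unobserved
        p = Pedigree(("obs", "idle"), (None, None), (None, None))
        W, _ = incidence_matrix(["obs"], level_order=p.ids)
        model = ModelSpec(
            y=np.array([2.0]), X=np.zeros((1, 0)), W=W, animal_ids=p.ids
        )
        vc = VarianceComponents(sigma_u2=0.5, sigma_e2=1.0)
        sys = assemble_mme(model, build_A_inverse(p), vc,
                           geno_index=np.array([1]))
        pev = pev_genotyped(solve_and_return(sys))
        assert pev.values[0, 0] == pytest.approx(vc.sigma_u2, abs=1e-12)

    def test_diagonal_shrinks_with_more_records(self):
        p = Pedigree(("a",), (None,), (None,))
        vc = VarianceComponents(sigma_u2=1.0, sigma_e2=1.0)
        prev = np.inf
        for n_rec in (1, 2, 5, 10):
            W, _ = incidence_matrix(["a"] * n_rec, level_order=p.ids)
            model = ModelSpec(
                y=np.ones(n_rec), X=np.zeros((n_rec, 0)), W=W, animal_ids=p.ids
            )
            sys = assemble_mme(model, build_A_inverse(p), vc, geno_index=np.array([0]))
            val = pev_genotyped(sys).values[0, 0]
            assert val < prev
            prev = val

    def test_matches_full_dense_inverse(self, small_dataset, vc):
        run = run_association(
            small_dataset.pedigree, small_dataset.genotypes,
            small_dataset.phenotypes, vc,
        )
        Cfull = np.linalg.inv(run.mme.lhs)
        gi = run.mme.geno_index
        np.testing.assert_allclose(
            run.pev.values, Cfull[np.ix_(gi, gi)], atol=1e-8
        )

    def test_reliabilities_in_unit_interval(self, small_dataset, vc):
        run = run_association(
            small_dataset.pedigree, small_dataset.genotypes,
            small_dataset.phenotypes, vc,
        )
        h_diag = np.diag(run.G.values)  # genotyped block of H is G
        rel = 1.0 - np.diag(run.pev.values) / (vc.sigma_u2 * h_diag)
        assert np.all(rel >= 0.0) and np.all(rel <= 1.0)


def solve_and_return(sys):
    solve_mme(sys)
    return sys


class TestSnpBlupEquivalence:
    def test_gblup_breeding_values_equal_snp_blup_projection(self, full_geno_dataset, vc):
        """With every animal genotyped and G = ZZ'/2Σpq at base frequencies,
        û from the animal-level system equals Z·â from the marker-level MME."""
        ds = full_geno_dataset
        freqs = MarkerFrequencies(ds.base_freq)
        run = run_association(
            ds.pedigree, ds.genotypes, ds.phenotypes, vc,
            alpha=0.0, blend=(0.0, 1.0), frequencies=freqs, qc=False,
        )
        m = run.model
        a_hat, _ = snp_blup(
            m.y, m.X, m.W[:, run.geno_index], run.Z,
            vc.sigma_u2, vc.sigma_e2, freqs.sum2pq,
            S=m.extra_random, sigma_pe2=vc.sigma_pe2,
        )
        np.testing.assert_allclose(run.solutions.u2_hat, run.Z @ a_hat, atol=1e-8)


class TestFixedDesign:
    def test_treatment_and_sum_codings_are_full_rank(self):
        import pandas as pd

        df = pd.DataFrame({"cg": ["a", "b", "c", "a"], "x": [1.0, 2.0, 3.0, 4.0]})
        for coding in ("treatment", "sum"):
            X, names = build_fixed_design(df, ("cg",), ("x",), coding=coding)
            assert X.shape == (4, 4)
            assert np.linalg.matrix_rank(X) == 4
        assert names[0] == "intercept" and names[-1] == "x"
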