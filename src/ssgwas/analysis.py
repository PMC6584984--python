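"""In-memory driver: one call from (pedigree, genotypes, phenotypes) to
per-marker statistics, exposing every intermediate for auditing.

This is the library-level counterpart of the file-based pipeline; tests,
simulations and the single-marker cross-check all go through it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genomic, gwas
from . import pedigree as ped_mod
from . import ssgblup_core as core
from .containers import RelationshipMatrix
from .exceptions import InputError
from .genomic import BlendParams, GenotypeMatrix, MarkerFrequencies
from .gwas import BacksolveScale, GwasResult
from .pedigree import Pedigree


@dataclass
class AssociationRun:
    """Result bundle: the marker table plus every intermediate object."""

    result: GwasResult
    report: dict
    # intermediates, in genotyped-animal order
    genotypes: GenotypeMatrix
    frequencies: MarkerFrequencies
    Z: np.ndarray
    G: RelationshipMatrix
    A22: RelationshipMatrix
    blend: BlendParams
    scale: BacksolveScale
    model: core.ModelSpec
    mme: core.MMESystem
    solutions: core.Solutions
    pev: core.PevBlock
    geno_index: np.ndarray


def run_association(
    ped: Pedigree,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    vc: core.VarianceComponents,
    *,
    trait: str = "y",
    animal_col: str = "animal",
    fixed_categorical: tuple[str, ...] = ("cg",),
    covariates: tuple[str, ...] = (),
    pe_col: str | None = "dam",
    coding: str = "treatment",
    alpha: float = 0.05,
    blend: str | tuple[float, float] = "fit",
    frequencies: MarkerFrequencies | None = None,
    qc: bool = True,
    maf_min: float = 0.01,
    callrate_min: float = 0.9,
) -> AssociationRun:
    """Run the single-step association analysis on in-memory objects.

    ``blend`` is ``"fit"`` (match A22 means), a fixed ``(a, b)`` pair, or is
    ignored entirely when ``alpha == 0`` and ``(a, b) == (0, 1)`` — the
    unblended case, which requires a full-rank genomic matrix (e.g. when
    ``frequencies`` are known base frequencies rather than observed ones).
    """
    if not ped.is_sorted:
        ped = ped_mod.sort_pedigree(ped)
    report: dict = {}
    if qc:
        genotypes, qc_rep = genomic.qc_filter(
            genotypes, maf_min=maf_min, callrate_min=callrate_min
        )
        report["n_markers_dropped"] = int(len(qc_rep))
    A = ped_mod.build_A(ped)
    A22 = ped_mod.extract_A22(ped, genotypes.animal_ids, A=A)
    F = ped_mod.inbreeding_coefficients(ped)
    A_inv = ped_mod.build_A_inverse(ped, F)
    geno_index = np.array([ped.order_index[a] for a in genotypes.animal_ids])

    freqs = frequencies if frequencies is not None else genomic.allele_frequencies(genotypes)
    Z = genomic.center_genotypes(genotypes, freqs)
    G_raw = genomic.build_G_raw(Z, freqs, ids=genotypes.animal_ids)
    if blend == "fit":
        a_fit, b_fit = genomic.fit_blending(G_raw, A22)
    else:
        a_fit, b_fit = blend
    params = BlendParams(alpha=alpha, a=a_fit, b=b_fit)
    G = genomic.blend_G(G_raw, A22, params)
    H_inv = core.build_H_inverse(A_inv, A22, G, geno_index)

    model = build_model_spec(
        phenotypes,
        ped,
        trait=trait,
        animal_col=animal_col,
        fixed_categorical=fixed_categorical,
        covariates=covariates,
        pe_col=pe_col,
        coding=coding,
    )
    mme = core.assemble_mme(model, H_inv, vc, geno_index=geno_index)
    sol = core.solve_mme(mme)
    C = core.pev_genotyped(mme)

    scale = BacksolveScale(alpha=alpha, b=b_fit, sum2pq=freqs.sum2pq)
    a_hat = gwas.backsolve_snp_effects(Z, G, sol.u2_hat, scale)
    var_a, n_clamped = gwas.snp_prediction_error_variance(Z, G, C, vc, scale)
    pv = gwas.snp_pvalues(a_hat, var_a)
    raw_share, pct_share = gwas.variance_explained(freqs.p, a_hat, vc.sigma_u2)
    b_hat, var_b = gwas.to_fixed_regression(a_hat, var_a, scale.scale * vc.sigma_u2)
    lam, qq = gwas.inflation_factor(pv["pvalue"].to_numpy())
    thr = gwas.bonferroni_threshold(0.05, genotypes.n_markers)

    table = pd.DataFrame(
        {
            "marker_id": list(genotypes.marker_ids),
            "chrom": genotypes.chrom if genotypes.chrom is not None else np.nan,
            "pos": genotypes.pos if genotypes.pos is not None else np.nan,
            "freq": freqs.p,
            "a_hat": a_hat,
            "sd_a": np.sqrt(var_a),
            "z": pv["z"].to_numpy(),
            "pvalue": pv["pvalue"].to_numpy(),
            "pvalue_bh": gwas.bh_adjust(pv["pvalue"].to_numpy()),
            "neglog10p": pv["neglog10p"].to_numpy(),
            "var_explained_raw": raw_share,
            "var_explained_pct": pct_share,
            "b_hat": b_hat,
            "sd_b": np.sqrt(var_b),
            "flag": pv["flag"].to_numpy(),
        }
    )
    off = ~np.eye(G.n, dtype=bool)
    report.update(
        {
            "n_markers_tested": genotypes.n_markers,
            "n_records": int(model.y.size),
            "n_animals": ped.n,
            "n_genotyped": genotypes.n_animals,
            "n_equations": mme.n,
            "n_var_clamped": n_clamped,
            "n_flagged": int((pv["flag"] != gwas.FLAG_OK).sum()),
            "lambda_gc": lam,
            "bonferroni_neglog10": thr,
            "blending": {
                "alpha": alpha,
                "a": a_fit,
                "b": b_fit,
                "mean_diag_G": float(np.mean(np.diag(G.values))),
                "mean_diag_A22": float(np.mean(np.diag(A22.values))),
                "mean_offdiag_G": float(np.mean(G.values[off])) if G.n > 1 else None,
                "mean_offdiag_A22": float(np.mean(A22.values[off])) if G.n > 1 else None,
            },
        }
    )
    result = GwasResult(
        table=table, lambda_gc=lam, bonferroni_neglog10=thr, qq=qq,
        blend=report["blending"],
    )
    return AssociationRun(
        result=result,
        report=report,
        genotypes=genotypes,
        frequencies=freqs,
        Z=Z,
        G=G,
        A22=A22,
        blend=params,
        scale=scale,
        model=model,
        mme=mme,
        solutions=sol,
        pev=C,
        geno_index=geno_index,
    )


def build_model_spec(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    *,
    trait: str = "y",
    animal_col: str = "animal",
    fixed_categorical: tuple[str, ...] = ("cg",),
    covariates: tuple[str, ...] = (),
    pe_col: str | None = None,
    coding: str = "treatment",
) -> core.ModelSpec:
    """Phenotype table → design matrices with animals in pedigree order."""
    for col in (trait, animal_col):
        if col not in phenotypes.columns:
            raise InputError(f"phenotype table lacks column {col!r}")
    y = pd.to_numeric(phenotypes[trait], errors="raise").to_numpy(dtype=float)
    X, names = core.build_fixed_design(
        phenotypes,
        categorical=tuple(fixed_categorical),
        covariates=tuple(covariates),
        coding=coding,
    )
    W, _ = core.incidence_matrix(phenotypes[animal_col], level_order=ped.ids)
    S = None
    if pe_col:
        if pe_col not in phenotypes.columns:
            raise InputError(f"permanent-environment column {pe_col!r} missing")
        S, _ = core.incidence_matrix(phenotypes[pe_col])
    return core.ModelSpec(
        y=y, X=X, W=W, animal_ids=ped.ids, extra_random=S, fixed_names=names
    )


def emmax_reference_scan(run: AssociationRun, vc: core.VarianceComponents) -> pd.DataFrame:
    """Single-marker mixed-model scan matched to an association run.

    Valid only when every record belongs to a genotyped animal; the
    polygenic covariance is the run's G (the genotyped block of H).
    """
    import scipy.sparse as sp

    geno_ids = run.genotypes.animal_ids
    lookup = {a: k for k, a in enumerate(geno_ids)}
    # re-map records onto genotyped animals
    rec_animal = np.asarray(sp.csr_matrix(run.model.W).argmax(axis=1)).ravel()
    all_ids = run.model.animal_ids
    try:
        cols = np.array([lookup[all_ids[i]] for i in rec_animal])
    except KeyError as e:
        raise InputError(
            f"record animal {e.args[0]!r} is not genotyped; the single-marker "
            "scan applies only when all phenotyped animals are genotyped"
        ) from None
    n = run.model.y.size
    W = sp.csr_matrix((np.ones(n), (np.arange(n), cols)), shape=(n, len(geno_ids)))
    model = core.ModelSpec(
        y=run.model.y,
        X=run.model.X,
        W=W,
        animal_ids=geno_ids,
        extra_random=run.model.extra_random,
    )
    return gwas.emmax_scan(model, run.Z, run.G, vc)
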