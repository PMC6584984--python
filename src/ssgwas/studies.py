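"""Reference simulation studies bundled with the package.

Three desk-scale designs exercise the method's defining properties:

* exact equivalence between back-solved p-values and the single-marker
  mixed-model scan on fully genotyped data;
* type-I error / genomic-control calibration under a no-QTL null with
  partial, sires-first genotyping (the regime the method exists for);
* power to rank a planted QTL first on its chromosome.

Each study is a pure function of a base seed and returns plain dicts of
numbers, so it can be re-run verbatim from tests or scripts.
"""
from __future__ import annotations

import numpy as np

from .analysis import emmax_reference_scan, run_association
from .genomic import GenotypeMatrix, MarkerFrequencies
from .gwas import inflation_factor
from .simulate import SimConfig, make_dataset
from .ssgblup_core import VarianceComponents

#: the study variance components: phenotypic variance 1, heritability 0.48,
#: maternal permanent-environment share 0.10
STUDY_VC = dict(sigma_u2=0.48, sigma_e2=0.42, sigma_pe2=0.10)


def _vc() -> VarianceComponents:
    return VarianceComponents(**STUDY_VC)


def base_frequency_panel(ds, maf_min: float = 0.05):
    """MAF-filtered genotype panel paired with its *base* (founder)
    frequencies, so the genomic matrix is full rank without blending.

    Markers rare in the genotyped sample carry essentially no information
    (their effect variance cancels at rounding level), exactly what a
    standard MAF filter removes.
    """
    g = ds.genotypes
    obs = np.nanmean(g.values, axis=0) / 2.0
    keep = np.minimum(obs, 1.0 - obs) >= maf_min
    sub = GenotypeMatrix(
        g.values[:, keep],
        g.animal_ids,
        tuple(np.asarray(g.marker_ids)[keep]),
        chrom=None if g.chrom is None else np.asarray(g.chrom)[keep],
        pos=None if g.pos is None else np.asarray(g.pos)[keep],
    )
    return sub, MarkerFrequencies(ds.base_freq[keep])


def emmax_equivalence_study(
    seed: int,
    n_founders: int = 76,
    n_generations: int = 3,
    n_markers: int = 800,
) -> dict:
    """Fully genotyped population, unblended full-rank G built at base
    frequencies; returns the largest |Δp| between the back-solved scan and
    the per-marker GLS scan."""
    cfg = SimConfig(
        seed=seed,
        n_founders=n_founders,
        n_generations=n_generations,
        offspring_per_mating=2,
        n_markers=n_markers,
        genotyping_rule="all",
    )
    ds = make_dataset(cfg)
    vc = _vc()
    panel, freqs = base_frequency_panel(ds)
    run = run_association(
        ds.pedigree,
        panel,
        ds.phenotypes,
        vc,
        alpha=0.0,
        blend=(0.0, 1.0),
        frequencies=freqs,
        qc=False,
    )
    scan = emmax_reference_scan(run, vc)
    p1 = run.result.table["pvalue"].to_numpy()
    p2 = scan["pvalue"].to_numpy()
    ok = np.isfinite(p1) & np.isfinite(p2)
    return {
        "max_abs_dp": float(np.max(np.abs(p1[ok] - p2[ok]))),
        "n_markers": int(ok.sum()),
        "n_animals": ds.pedigree.n,
    }


def null_calibration_study(base_seed: int, n_replicates: int = 25) -> dict:
    """No-QTL replicates at the default design (1000 pedigreed animals, 300
    genotyped sires-first, 1000 markers): empirical type-I error at nominal
    0.05 pooled over replicates, and per-replicate genomic-control λ."""
    hits = 0
    total = 0
    lambdas: list[float] = []
    vc = _vc()
    for r in range(n_replicates):
        ds = make_dataset(SimConfig(seed=base_seed + r))
        run = run_association(ds.pedigree, ds.genotypes, ds.phenotypes, vc)
        p = run.result.table["pvalue"].to_numpy()
        p = p[np.isfinite(p)]
        hits += int((p < 0.05).sum())
        total += p.size
        lambdas.append(inflation_factor(p)[0])
    return {
        "type1_rate": hits / total,
        "n_tests": total,
        "lambdas": lambdas,
        "lambda_mean": float(np.mean(lambdas)),
        "lambda_min": float(np.min(lambdas)),
        "lambda_max": float(np.max(lambdas)),
    }


def qtl_effect_for_share(p: float, share: float, sigma_u2: float) -> float:
    """Allele-substitution effect giving 2pq·a² = share·σ_u²."""
    return float(np.sqrt(share * sigma_u2 / (2.0 * p * (1.0 - p))))


def power_study(
    base_seed: int,
    n_replicates: int = 50,
    qtl_share: float = 0.05,
    qtl_index: int = 500,
) -> dict:
    """Planted-QTL replicates (~500 fully genotyped animals, 1000 markers on
    29 autosomes): how often the QTL marker has the smallest p-value on its
    chromosome. The effect is sized to ``qtl_share`` of the additive genetic
    variance at the replicate's realized base frequency."""
    vc = _vc()
    design = dict(
        n_founders=126,
        n_generations=3,
        offspring_per_mating=2,
        n_markers=1000,
        genotyping_rule="all",
    )
    wins = 0
    valid = 0
    for r in range(n_replicates):
        seed = base_seed + r
        # same seed, no QTL: identical pedigree/genotypes, exposes base_freq
        probe = make_dataset(SimConfig(seed=seed, **design))
        p_qtl = float(probe.base_freq[qtl_index])
        eff = qtl_effect_for_share(p_qtl, qtl_share, vc.sigma_u2)
        ds = make_dataset(SimConfig(seed=seed, qtl=((qtl_index, eff),), **design))
        run = run_association(ds.pedigree, ds.genotypes, ds.phenotypes, vc)
        tab = run.result.table
        qtl_id = ds.genotypes_full.marker_ids[qtl_index]
        row = tab[tab["marker_id"] == qtl_id]
        if row.empty or not np.isfinite(row["pvalue"].iloc[0]):
            continue  # QTL marker lost to QC in this replicate
        valid += 1
        chrom = row["chrom"].iloc[0]
        sub = tab[(tab["chrom"] == chrom) & np.isfinite(tab["pvalue"])]
        if sub.loc[sub["pvalue"].idxmin(), "marker_id"] == qtl_id:
            wins += 1
    return {
        "n_top": wins,
        "n_valid": valid,
        "top_fraction": wins / valid if valid else float("nan"),
    }
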