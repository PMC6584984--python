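"""File-based pipeline: read inputs, delegate to the in-memory driver,
collect the run report. Errors are re-raised tagged with the stage name."""
from __future__ import annotations

from contextlib import contextmanager

import numpy as np
import pandas as pd

from . import genomic
from . import pedigree as ped_mod
from . import ssgblup_core as core
from .analysis import AssociationRun, emmax_reference_scan, run_association
from .config import RunConfig
from .exceptions import InputError, SSGwasError
from .genomic import GenotypeMatrix
from .gwas import GwasResult


@contextmanager
def _stage(name: str):
    try:
        yield
    except SSGwasError as e:
        e.args = (f"[{name}] {e.args[0]}",) + e.args[1:]
        raise


def _attach_map(g: GenotypeMatrix, map_file: str) -> GenotypeMatrix:
    if not map_file:
        return g
    mp = pd.read_csv(map_file, sep=None, engine="python", dtype={"marker_id": str})
    for col in ("marker_id", "chrom", "pos"):
        if col not in mp.columns:
            raise InputError(f"map file lacks column {col!r}")
    mp = mp.set_index("marker_id")
    missing = [m for m in g.marker_ids if m not in mp.index]
    if missing:
        raise InputError(f"map file lacks marker {missing[0]!r}")
    g.chrom = mp.loc[list(g.marker_ids), "chrom"].to_numpy()
    g.pos = mp.loc[list(g.marker_ids), "pos"].to_numpy()
    return g


def _load(cfg: RunConfig):
    with _stage("read"):
        ped = ped_mod.sort_pedigree(
            ped_mod.read_pedigree(cfg.pedigree, unknown_code=cfg.unknown_code)
        )
        geno = genomic.read_genotypes(cfg.genotypes, dialect=cfg.genotype_dialect)
        geno = _attach_map(geno, cfg.map_file)
        pheno = pd.read_csv(cfg.phenotypes, sep=None, engine="python", dtype=str)
    return ped, geno, pheno


def _run(cfg: RunConfig) -> AssociationRun:
    ped, geno, pheno = _load(cfg)
    vc = core.VarianceComponents(
        cfg.sigma_u2, cfg.sigma_e2, cfg.sigma_pe2 if cfg.pe_col else None
    )
    with _stage("analysis"):
        return run_association(
            ped,
            geno,
            pheno,
            vc,
            trait=cfg.trait,
            animal_col=cfg.animal_col,
            fixed_categorical=tuple(cfg.fixed_categorical),
            covariates=tuple(cfg.covariates),
            pe_col=cfg.pe_col or None,
            alpha=cfg.alpha,
            maf_min=cfg.maf_min,
            callrate_min=cfg.callrate_min,
        )


def run_pipeline(cfg: RunConfig) -> tuple[GwasResult, dict]:
    run = _run(cfg)
    return run.result, run.report


def emmax_compare(cfg: RunConfig) -> tuple[pd.DataFrame, float]:
    """Back-solved p-values vs the single-marker mixed-model scan, per marker.

    Exact agreement is expected when every phenotyped animal is genotyped
    (and holds to solver precision for any invertible G); with ungenotyped
    phenotyped animals the scan cannot form its marker covariates and an
    input error is raised.
    """
    run = _run(cfg)
    vc = core.VarianceComponents(
        cfg.sigma_u2, cfg.sigma_e2, cfg.sigma_pe2 if cfg.pe_col else None
    )
    with _stage("emmax"):
        scan = emmax_reference_scan(run, vc)
    cmp = pd.DataFrame(
        {
            "marker_id": run.result.table["marker_id"],
            "p_ssgwas": run.result.table["pvalue"].to_numpy(),
            "p_emmax": scan["pvalue"].to_numpy(),
        }
    )
    cmp["abs_dp"] = np.abs(cmp["p_ssgwas"] - cmp["p_emmax"])
    max_dp = float(np.nanmax(cmp["abs_dp"].to_numpy()))
    return cmp, max_dp
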