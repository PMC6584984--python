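"""Desk-scale livestock data simulator: pedigree, gene-dropped genotypes,
and phenotypes with planted QTL.

The generator emulates a beef-cattle-like design: discrete generations of
random mating, phenotypes on all non-founder animals recorded in
contemporary groups with a dam permanent-environment effect, and genotypes
on a subset of animals chosen sires-first (heavily used sires are genotyped,
most phenotyped animals are not). Default variance components put the
phenotypic variance at 1 with heritability 0.48 and a maternal
permanent-environment share of 0.10.

Markers are laid out on 29 autosomes (cattle karyotype) and segregate by
Mendelian gene dropping from Hardy–Weinberg founders; loci are unlinked by
default, with an optional complete-linkage block mode (``ld_block_size``)
to create local LD. The polygenic component is sampled recursively through
the pedigree with Mendelian-sampling variances that account for parental
inbreeding, so Var(u) = A·σ²_poly exactly matches the relationship matrix
the estimation side builds.

Everything is a pure function of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .genomic import GenotypeMatrix
from .pedigree import (
    UNKNOWN,
    Pedigree,
    _mendelian_variances,
    inbreeding_coefficients,
)


@dataclass(frozen=True)
class SimConfig:
    n_founders: int = 250
    n_generations: int = 3
    offspring_per_mating: int = 2
    sire_fraction: float = 0.5  # fraction of each generation that is male
    n_markers: int = 1000
    n_chromosomes: int = 29
    founder_freq_low: float = 0.05
    founder_freq_high: float = 0.95
    ld_block_size: int = 1  # markers per fully linked block (1 = unlinked)
    qtl: tuple[tuple[int, float], ...] = ()  # (marker index, effect/allele)
    sigma_u2: float = 0.48
    sigma_e2: float = 0.42
    sigma_pe2: float | None = 0.10
    genotyping_rule: str = "fraction"  # all | sires_only | fraction
    genotyping_fraction: float = 0.3
    n_cg: int = 20
    cg_effect_sd: float = 1.0
    mu: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_founders, self.n_generations, self.offspring_per_mating,
               self.n_markers, self.n_chromosomes, self.n_cg) < 1:
            raise InputError("all simulation counts must be >= 1")
        if not (0.0 < self.founder_freq_low < self.founder_freq_high < 1.0):
            raise InputError("founder frequency law must satisfy 0 < low < high < 1")
        if not (0.0 < self.sire_fraction < 1.0):
            raise InputError("sire_fraction must be in (0, 1)")
        if self.genotyping_rule not in ("all", "sires_only", "fraction"):
            raise InputError(f"unknown genotyping rule {self.genotyping_rule!r}")
        for j, eff in self.qtl:
            if not (0 <= j < self.n_markers) or not np.isfinite(eff):
                raise InputError(f"invalid QTL specification ({j}, {eff})")
        if self.sigma_u2 <= 0 or self.sigma_e2 <= 0:
            raise InputError("variances must be positive")


@dataclass
class SimPedigree:
    pedigree: Pedigree
    generation: np.ndarray
    sex: np.ndarray  # 'M' / 'F'


@dataclass
class SyntheticDataset:
    """Simulated truth plus the observable files' in-memory equivalents."""

    config: SimConfig
    pedigree: Pedigree
    generation: np.ndarray
    sex: np.ndarray
    genotypes_full: GenotypeMatrix  # every animal (truth side)
    genotypes: GenotypeMatrix  # the genotyped subset, pedigree order
    genotyped_ids: tuple[str, ...]
    phenotypes: pd.DataFrame  # record, animal, dam, cg, y
    true_u: np.ndarray  # total breeding values, pedigree order
    base_freq: np.ndarray  # founder allele frequencies per marker
    qtl: pd.DataFrame  # marker_id, marker_index, effect, base_freq


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimPedigree:
    """Discrete-generation random-mating pedigree, sorted by construction.

    Each generation's females are all mated, each to a sire drawn uniformly
    from the previous generation's males, producing
    ``offspring_per_mating`` offspring; pedigree size is therefore exact
    given the configuration.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_m0 = max(1, round(cfg.n_founders * cfg.sire_fraction))
    if n_m0 >= cfg.n_founders:
        raise InputError("founder generation needs at least one female")
    ids: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []
    sex: list[str] = []
    gen: list[int] = []

    def add(s: str | None, d: str | None, g: int, sx: str) -> str:
        ident = f"A{len(ids) + 1}"
        ids.append(ident)
        sires.append(s)
        dams.append(d)
        gen.append(g)
        sex.append(sx)
        return ident

    males = [add(None, None, 0, "M") for _ in range(n_m0)]
    females = [add(None, None, 0, "F") for _ in range(cfg.n_founders - n_m0)]
    for g in range(1, cfg.n_generations + 1):
        if not males or not females:
            raise InputError(f"generation {g - 1} lacks one sex; cannot mate")
        offspring: list[tuple[str, str]] = []
        sire_draw = rng.integers(0, len(males), size=len(females))
        for dam, si in zip(females, sire_draw):
            for _ in range(cfg.offspring_per_mating):
                offspring.append((males[si], dam))
        n_off = len(offspring)
        n_male = max(1, round(n_off * cfg.sire_fraction))
        males, females = [], []
        for k, (s, d) in enumerate(offspring):
            sx = "M" if k < n_male else "F"
            ident = add(s, d, g, sx)
            (males if sx == "M" else females).append(ident)
    ped = Pedigree(tuple(ids), tuple(sires), tuple(dams))
    return SimPedigree(ped, np.array(gen), np.array(sex))


def _marker_map(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chromosome, within-chromosome position, and linkage-block id per marker."""
    j = np.arange(cfg.n_markers)
    chrom = (j * cfg.n_chromosomes) // cfg.n_markers + 1
    pos = np.ones_like(j)
    block = np.zeros(cfg.n_markers, dtype=np.intp)
    bid = 0
    for k in range(1, cfg.n_markers):
        pos[k] = pos[k - 1] + 1 if chrom[k] == chrom[k - 1] else 1
        if chrom[k] != chrom[k - 1] or (k % cfg.ld_block_size) == 0:
            bid += 1
        block[k] = bid
    return chrom, pos, block


def gene_drop(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop alleles through the pedigree; returns genotypes for every animal
    and the founder (base) allele frequencies drawn from the configured law.

    Founders are Hardy–Weinberg at the base frequencies; each offspring
    inherits one allele per parent, chosen uniformly per linkage block.
    With ``ld_block_size > 1`` the markers of a block share one uniform draw
    per founder haplotype (comonotone alleles), which plants strong positive
    LD within blocks that block-wise inheritance then preserves.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if not ped.is_sorted:
        raise InputError("gene_drop needs a sorted pedigree")
    n, m = ped.n, cfg.n_markers
    base_p = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, size=m)
    chrom, pos, block = _marker_map(cfg)
    n_blocks = int(block[-1]) + 1
    h = np.zeros((2, n, m), dtype=np.int8)
    sire, dam = ped.sire_index, ped.dam_index
    for i in range(n):
        for which, par in ((0, sire[i]), (1, dam[i])):
            if par == UNKNOWN:
                h[which, i] = rng.random(n_blocks)[block] < base_p
            else:
                coin = rng.integers(0, 2, size=n_blocks)[block]  # one draw per block
                h[which, i] = np.where(coin == 0, h[0, par], h[1, par])
    values = (h[0] + h[1]).astype(float)
    gm = GenotypeMatrix(
        values, ped.ids, tuple(f"M{j + 1}" for j in range(m)), chrom=chrom, pos=pos
    )
    return gm, base_p


def simulate_phenotypes(
    sim_ped: SimPedigree,
    genotypes_full: GenotypeMatrix,
    base_p: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Phenotypes y = μ + CG + u + pe(dam) + e for all non-founder animals.

    The total breeding value u is a pedigree-sampled polygenic term plus the
    planted QTL effects acting through the (base-frequency-centered) gene
    contents; the polygenic variance is reduced so the total additive
    variance equals ``sigma_u2``. Returns (phenotype table, true u per
    pedigree animal, QTL table).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    ped = sim_ped.pedigree
    n = ped.n
    qtl_idx = np.array([j for j, _ in cfg.qtl], dtype=np.intp)
    qtl_eff = np.array([e for _, e in cfg.qtl], dtype=float)
    var_qtl = 0.0
    if qtl_idx.size:
        pq = base_p[qtl_idx] * (1.0 - base_p[qtl_idx])
        var_qtl = float(np.sum(2.0 * pq * qtl_eff**2))
    sigma_poly = cfg.sigma_u2 - var_qtl
    if sigma_poly <= 0:
        raise InputError(
            f"QTL effects imply additive variance {var_qtl:.4g} exceeding "
            f"sigma_u2 = {cfg.sigma_u2}"
        )
    # polygenic values by recursive Mendelian sampling: Var(u_poly) = A sigma_poly
    F = inbreeding_coefficients(ped)
    d = _mendelian_variances(ped, F)
    u_poly = np.zeros(n)
    sire, dam = ped.sire_index, ped.dam_index
    noise = rng.standard_normal(n)
    for i in range(n):
        parent_mean = 0.0
        if sire[i] != UNKNOWN:
            parent_mean += 0.5 * u_poly[sire[i]]
        if dam[i] != UNKNOWN:
            parent_mean += 0.5 * u_poly[dam[i]]
        u_poly[i] = parent_mean + noise[i] * np.sqrt(d[i] * sigma_poly)
    true_u = u_poly.copy()
    if qtl_idx.size:
        Zq = genotypes_full.values[:, qtl_idx] - 2.0 * base_p[qtl_idx]
        true_u += Zq @ qtl_eff

    recorded = np.flatnonzero(sim_ped.generation >= 1)
    cg = rng.integers(0, cfg.n_cg, size=recorded.size)
    cg_eff = rng.normal(0.0, cfg.cg_effect_sd, size=cfg.n_cg)
    pe = np.zeros(recorded.size)
    if cfg.sigma_pe2 is not None:
        dam_labels = [ped.dams[i] for i in recorded]
        uniq = sorted({x for x in dam_labels if x is not None})
        dam_pe = dict(zip(uniq, rng.normal(0.0, np.sqrt(cfg.sigma_pe2), len(uniq))))
        pe = np.array([dam_pe.get(x, 0.0) for x in dam_labels])
    e = rng.normal(0.0, np.sqrt(cfg.sigma_e2), size=recorded.size)
    y = cfg.mu + cg_eff[cg] + true_u[recorded] + pe + e
    pheno = pd.DataFrame(
        {
            "record": [f"R{k + 1}" for k in range(recorded.size)],
            "animal": [ped.ids[i] for i in recorded],
            "dam": [ped.dams[i] if ped.dams[i] is not None else "0" for i in recorded],
            "cg": [f"CG{c + 1}" for c in cg],
            "y": y,
        }
    )
    qtl_df = pd.DataFrame(
        {
            "marker_id": [genotypes_full.marker_ids[j] for j in qtl_idx],
            "marker_index": qtl_idx,
            "effect": qtl_eff,
            "base_freq": base_p[qtl_idx] if qtl_idx.size else np.array([]),
        }
    )
    return pheno, true_u, qtl_df


def _select_genotyped(ped: Pedigree, cfg: SimConfig) -> np.ndarray:
    """Pedigree indices of the genotyped subset, sires first (by progeny count)."""
    n = ped.n
    if cfg.genotyping_rule == "all":
        return np.arange(n)
    counts = np.zeros(n, dtype=int)
    for s in ped.sire_index:
        if s != UNKNOWN:
            counts[s] += 1
    sires = np.flatnonzero(counts > 0)
    sires = sires[np.lexsort((sires, -counts[sires]))]
    if cfg.genotyping_rule == "sires_only":
        chosen = sires
    else:
        target = max(1, round(cfg.genotyping_fraction * n))
        if sires.size >= target:
            chosen = sires[:target]
        else:
            rest = np.setdiff1d(np.arange(n), sires, assume_unique=True)
            chosen = np.concatenate([sires, rest[: target - sires.size]])
    return np.sort(chosen)


def make_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Run the full generator from one seed: pedigree → genotypes → phenotypes."""
    rng = np.random.default_rng(cfg.seed)
    sim_ped = simulate_pedigree(cfg, rng)
    geno_full, base_p = gene_drop(sim_ped.pedigree, cfg, rng)
    pheno, true_u, qtl_df = simulate_phenotypes(sim_ped, geno_full, base_p, cfg, rng)
    idx = _select_genotyped(sim_ped.pedigree, cfg)
    sub = GenotypeMatrix(
        geno_full.values[idx],
        tuple(sim_ped.pedigree.ids[i] for i in idx),
        geno_full.marker_ids,
        chrom=geno_full.chrom,
        pos=geno_full.pos,
    )
    return SyntheticDataset(
        config=cfg,
        pedigree=sim_ped.pedigree,
        generation=sim_ped.generation,
        sex=sim_ped.sex,
        genotypes_full=geno_full,
        genotypes=sub,
        genotyped_ids=sub.animal_ids,
        phenotypes=pheno,
        true_u=true_u,
        base_freq=base_p,
        qtl=qtl_df,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write pedigree, genotypes (both dialects), phenotypes, map and truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped = ds.pedigree
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "genotypes_blupf90": outdir / "genotypes.txt",
        "genotypes_matrix": outdir / "genotypes_matrix.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "map": outdir / "map.tsv",
        "truth": outdir / "truth.csv",
        "qtl": outdir / "qtl.csv",
    }
    with open(paths["pedigree"], "w") as fh:
        for a, s, d in zip(ped.ids, ped.sires, ped.dams):
            fh.write(f"{a},{s or '0'},{d or '0'}\n")
    with open(paths["genotypes_blupf90"], "w") as fh:
        for k, a in enumerate(ds.genotypes.animal_ids):
            digits = "".join(str(int(v)) for v in ds.genotypes.values[k])
            fh.write(f"{a} {digits}\n")
    gm = pd.DataFrame(
        ds.genotypes.values.astype(int),
        index=list(ds.genotypes.animal_ids),
        columns=list(ds.genotypes.marker_ids),
    )
    gm.to_csv(paths["genotypes_matrix"])
    ds.phenotypes.to_csv(paths["phenotypes"], index=False)
    pd.DataFrame(
        {
            "marker_id": list(ds.genotypes.marker_ids),
            "chrom": ds.genotypes.chrom,
            "pos": ds.genotypes.pos,
        }
    ).to_csv(paths["map"], sep="\t", index=False)
    pd.DataFrame({"animal": list(ped.ids), "true_u": ds.true_u}).to_csv(
        paths["truth"], index=False
    )
    ds.qtl.to_csv(paths["qtl"], index=False)
    return paths
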