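"""Genotype I/O, QC, allele frequencies, and the genomic relationship matrix G.

G is VanRaden-style: Z holds gene contents centered at per-marker allele
frequencies and G_raw = ZZ′ / 2Σp_i q_i. When frequencies are observed from
the data itself, G_raw is singular (columns of Z sum to zero), so the raw
matrix is blended with the pedigree block A22,

    G = (1 − α)(a + b·G_raw) + α·A22,

with a, b fitted so the mean diagonal and mean off-diagonal of G match those
of A22 — this makes genomic and pedigree relationships compatible and G
invertible.

Two text dialects are supported: a blupf90-style file (ID then an unbroken
digit string, 5 = missing) and a delimited matrix with a marker-ID header
(empty/NA = missing).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RelationshipMatrix
from .exceptions import InputError, NumericalError


@dataclass
class GenotypeMatrix:
    """Gene contents (0/1/2 copies of the reference allele), animals × markers.

    Missing entries are stored as NaN until centering, where they become 0
    (mean imputation under the centering convention). Optional ``chrom`` and
    ``pos`` arrays carry map metadata for plotting.
    """

    values: np.ndarray
    animal_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.animal_ids = tuple(str(a) for a in self.animal_ids)
        self.marker_ids = tuple(str(m) for m in self.marker_ids)
        if self.values.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise InputError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.marker_ids)} markers"
            )
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise InputError("duplicate animal IDs in genotype matrix")
        ok = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise InputError(
                f"invalid gene content {self.values[i, j]!r} for animal "
                f"{self.animal_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class MarkerFrequencies:
    """Reference-allele frequencies per marker and the scaling constant 2Σpq."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise InputError("allele frequencies must lie strictly in (0, 1); "
                             "run qc_filter to drop monomorphic markers")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def sum2pq(self) -> float:
        return float(np.sum(2.0 * self.p * self.q))


@dataclass
class BlendParams:
    """Blending weights for G = (1−α)(a + b·G_raw) + α·A22."""

    alpha: float = 0.05
    a: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise InputError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.b <= 0:
            raise InputError(f"multiplicative adjustment b must be > 0, got {self.b}")


def read_genotypes(path: str | Path, dialect: str = "blupf90") -> GenotypeMatrix:
    """Read genotypes from text.

    ``blupf90``: each line is ``ID<whitespace><digits>`` where the digit
    string holds one 0/1/2 per marker and 5 means missing; marker IDs are
    generated as ``M1..Mm``. ``matrix``: delimited table, header row of
    marker IDs, first column animal IDs, empty/NA = missing.
    """
    path = Path(path)
    if dialect == "blupf90":
        return _read_blupf90(path)
    if dialect == "matrix":
        return _read_matrix(path)
    raise InputError(f"unknown genotype dialect {dialect!r}")


def _read_blupf90(path: Path) -> GenotypeMatrix:
    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_markers = None
    with open(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise InputError(
                    f"{path}:{ln_no}: expected 'ID <digits>', got {line.strip()!r}"
                )
            ident, digits = parts
            codes = np.frombuffer(digits.encode("ascii"), dtype=np.uint8) - ord("0")
            if not np.isin(codes, (0, 1, 2, 5)).all():
                bad = digits[int(np.argmax(~np.isin(codes, (0, 1, 2, 5))))]
                raise InputError(f"{path}:{ln_no}: invalid genotype digit {bad!r}")
            if n_markers is None:
                n_markers = codes.size
            elif codes.size != n_markers:
                raise InputError(
                    f"{path}:{ln_no}: {codes.size} markers but previous lines "
                    f"had {n_markers} (ragged file)"
                )
            vals = codes.astype(float)
            vals[codes == 5] = np.nan
            ids.append(ident)
            rows.append(vals)
    if not rows:
        raise InputError(f"genotype file {path} is empty")
    marker_ids = tuple(f"M{j + 1}" for j in range(n_markers))
    return GenotypeMatrix(np.vstack(rows), tuple(ids), marker_ids)


def _read_matrix(path: Path) -> GenotypeMatrix:
    sep = "," if "," in Path(path).read_text(encoding="ascii", errors="ignore")[:4096].splitlines()[0] else r"\s+"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""], dtype=str)
    if df.empty:
        raise InputError(f"genotype file {path} is empty")
    vals = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    return GenotypeMatrix(vals, tuple(map(str, df.index)), tuple(map(str, df.columns)))


def qc_filter(
    g: GenotypeMatrix, maf_min: float = 0.01, callrate_min: float = 0.9
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop monomorphic markers and those failing MAF or call-rate thresholds.

    Returns the filtered matrix and a report listing each dropped marker with
    its reason (first failing rule in order: call rate, monomorphic, MAF).
    """
    if not (0.0 <= maf_min < 0.5):
        raise InputError(f"maf_min must be in [0, 0.5), got {maf_min}")
    if not (0.0 < callrate_min <= 1.0):
        raise InputError(f"callrate_min must be in (0, 1], got {callrate_min}")
    observed = ~np.isnan(g.values)
    callrate = observed.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g.values, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    dropped: list[tuple[str, str]] = []
    keep = np.ones(g.n_markers, dtype=bool)
    for j in range(g.n_markers):
        if callrate[j] < callrate_min or callrate[j] == 0:
            reason = "call_rate"
        elif np.isnan(p[j]) or p[j] <= 0.0 or p[j] >= 1.0:
            reason = "monomorphic"
        elif maf[j] < maf_min:
            reason = "maf"
        else:
            continue
        keep[j] = False
        dropped.append((g.marker_ids[j], reason))
    if not keep.any():
        raise InputError("quality control dropped every marker")
    report = pd.DataFrame(dropped, columns=["marker_id", "reason"])
    out = GenotypeMatrix(
        g.values[:, keep],
        g.animal_ids,
        tuple(np.asarray(g.marker_ids)[keep]),
        chrom=None if g.chrom is None else np.asarray(g.chrom)[keep],
        pos=None if g.pos is None else np.asarray(g.pos)[keep],
    )
    return out, report


def allele_frequencies(g: GenotypeMatrix) -> MarkerFrequencies:
    """Observed reference-allele frequencies, ignoring missing entries."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g.values, axis=0) / 2.0
    return MarkerFrequencies(p)


def center_genotypes(g: GenotypeMatrix, f: MarkerFrequencies) -> np.ndarray:
    """Centered gene-content matrix Z: entry = content − 2p_i; missing → 0."""
    if f.p.size != g.n_markers:
        raise InputError(
            f"{f.p.size} frequencies supplied for {g.n_markers} markers"
        )
    Z = g.values - 2.0 * f.p[None, :]
    Z[np.isnan(Z)] = 0.0
    return Z


def build_G_raw(Z: np.ndarray, f: MarkerFrequencies, ids=None) -> RelationshipMatrix:
    """Raw genomic relationship matrix G = ZZ′ / 2Σp_i q_i."""
    s2pq = f.sum2pq
    if s2pq <= 0:
        raise NumericalError("2*sum(p*q) is not positive")
    G = (Z @ Z.T) / s2pq
    if ids is None:
        ids = tuple(str(i) for i in range(Z.shape[0]))
    return RelationshipMatrix(G, ids, kind="G_raw")


def fit_blending(G_raw: RelationshipMatrix, A22: RelationshipMatrix) -> tuple[float, float]:
    """Fit (a, b) so mean diagonal and mean off-diagonal of a + b·G_raw match A22.

    Two equations in two unknowns. With a single genotyped animal the
    off-diagonal means do not exist, so the fallback a = 0,
    b = diag(A22)/diag(G_raw) is returned.
    """
    if G_raw.ids != A22.ids:
        raise InputError("G and A22 must carry the same animals in the same order")
    n = G_raw.n
    dg = float(np.mean(np.diag(G_raw.values)))
    da = float(np.mean(np.diag(A22.values)))
    if n < 2:
        if dg <= 0:
            raise NumericalError("cannot scale G: non-positive diagonal")
        return 0.0, da / dg
    off = ~np.eye(n, dtype=bool)
    og = float(np.mean(G_raw.values[off]))
    oa = float(np.mean(A22.values[off]))
    denom = dg - og
    if abs(denom) < 1e-12:
        raise NumericalError(
            "blending system is singular (mean diagonal of G equals mean "
            "off-diagonal); fix a = 0 and set b from the diagonal match instead"
        )
    b = (da - oa) / denom
    a = oa - b * og
    return a, b


def blend_G(
    G_raw: RelationshipMatrix,
    A22: RelationshipMatrix,
    params: BlendParams,
) -> RelationshipMatrix:
    """G = (1−α)(a + b·G_raw) + α·A22, checked for invertibility."""
    if G_raw.ids != A22.ids:
        raise InputError("G and A22 must carry the same animals in the same order")
    al, a, b = params.alpha, params.a, params.b
    G = (1.0 - al) * (a + b * G_raw.values) + al * A22.values
    try:
        np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        raise NumericalError(
            "blended G is numerically singular; increase alpha or check genotypes"
        ) from None
    return RelationshipMatrix(G, G_raw.ids, kind="G_blended")
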