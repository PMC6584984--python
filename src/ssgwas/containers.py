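"""Shared labelled-matrix containers used across the pedigree and genomic modules."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError


@dataclass
class RelationshipMatrix:
    """A symmetric additive-relationship matrix with its animal ordering.

    ``kind`` records provenance: pedigree-based (``A``, ``A22``), genomic
    (``G_raw``, ``G_blended``), or the combined matrix ``H``.
    """

    values: np.ndarray
    ids: tuple[str, ...]
    kind: str = "A"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = tuple(str(i) for i in self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError(
                f"relationship matrix is {self.values.shape} but carries {n} ids"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_symmetric(self, tol: float = 1e-10) -> bool:
        return bool(np.max(np.abs(self.values - self.values.T), initial=0.0) <= tol)

    def index_of(self, ids) -> np.ndarray:
        """Positions of ``ids`` within this matrix's ordering."""
        lookup = {a: k for k, a in enumerate(self.ids)}
        try:
            return np.array([lookup[str(a)] for a in ids], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - message formatting
            raise InputError(f"animal {e.args[0]!r} not present in {self.kind} matrix")
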