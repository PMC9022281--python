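"""Linkage-disequilibrium matrices: container, stabilization, file I/O.

An :class:`LdMatrix` holds pairwise allelic correlations (signed r, oriented
to the effect alleles of its variants).  It can be built from an
individual-level genotype panel or read from a whitespace-delimited square
matrix with a header row of variant IDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import config


class LdError(ValueError):
    pass


@dataclass
class LdMatrix:
    """Pairwise allelic correlation matrix for an ordered set of variants."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise LdError(f"LD matrix must be square; got shape {self.r.shape}")
        if len(self.variant_ids) != self.r.shape[0]:
            raise LdError("variant_ids length does not match matrix dimension")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise LdError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise LdError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise LdError("LD entries must lie in [-1, 1]")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def index_of(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise LdError(f"variant {variant_id!r} absent from LD matrix") from None

    def subset(self, ids: Sequence[str]) -> "LdMatrix":
        idx = [self.index_of(v) for v in ids]
        return LdMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def r2(self, id_a: str, id_b: str) -> float:
        return float(self.r[self.index_of(id_a), self.index_of(id_b)] ** 2)

    @classmethod
    def from_panel(cls, genotypes: np.ndarray, variant_ids: Sequence[str]) -> "LdMatrix":
        """Correlation matrix of a (individuals x variants) dosage panel."""
        g = np.asarray(genotypes, dtype=float)
        if g.ndim != 2:
            raise LdError("genotype panel must be 2-dimensional")
        if g.shape[1] != len(variant_ids):
            raise LdError("panel column count does not match variant_ids")
        sd = g.std(axis=0)
        if np.any(sd == 0):
            bad = [variant_ids[i] for i in np.flatnonzero(sd == 0)]
            raise LdError(f"monomorphic variants in panel: {bad[:5]}")
        r = np.corrcoef(g, rowvar=False)
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        return cls(list(variant_ids), r)


def stabilize_ld(
    ld: LdMatrix,
    schedule: Sequence[float] = config.LD_RIDGE_SCHEDULE,
    min_eigenvalue: float = config.LD_MIN_EIGENVALUE,
) -> tuple[LdMatrix, float]:
    """Shrink an LD matrix toward the identity until it is positive definite.

    Tries ``(1 - lam) * R + lam * I`` for each ``lam`` in the schedule (in
    order) and returns the first result whose smallest eigenvalue reaches
    ``min_eigenvalue``, with the diagonal restored to exactly 1.  Returns the
    stabilized matrix and the ridge weight that was applied.
    """
    for lam in schedule:
        m = (1.0 - lam) * ld.r + lam * np.eye(ld.n_variants)
        np.fill_diagonal(m, 1.0)
        if np.linalg.eigvalsh(m).min() >= min_eigenvalue:
            return LdMatrix(list(ld.variant_ids), m), float(lam)
    raise LdError(
        "LD matrix could not be stabilized with the configured ridge schedule"
    )


def write_ld_matrix(ld: LdMatrix, path: str) -> None:
    pd.DataFrame(ld.r, columns=ld.variant_ids).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_ld_matrix(path: str) -> LdMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    return LdMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_genotype_panel(genotypes: np.ndarray, variant_ids: Sequence[str], path: str) -> None:
    pd.DataFrame(np.asarray(genotypes, dtype=int), columns=list(variant_ids)).to_csv(
        path, sep="\t", index=False
    )


def read_genotype_panel(path: str) -> tuple[np.ndarray, list[str]]:
    """Read an (individuals x variants) 0/1/2 dosage table with a header."""
    df = pd.read_csv(path, sep=r"\s+")
    g = df.to_numpy(dtype=float)
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise LdError(f"{path}: genotype panel entries must be 0/1/2")
    return g, list(df.columns)


def read_ld_input(path: str) -> LdMatrix:
    """Read LD from either a square correlation matrix or a genotype panel.

    A file whose entries are all 0/1/2 with more rows than columns is treated
    as a panel; otherwise it must be a square correlation matrix.
    """
    df = pd.read_csv(path, sep=r"\s+")
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] == arr.shape[1] and np.abs(arr).max() <= 1 + 1e-8:
        return LdMatrix(list(df.columns), arr)
    g, ids = read_genotype_panel(path)
    return LdMatrix.from_panel(g, ids)
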