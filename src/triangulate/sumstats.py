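"""Summary-statistic data model, TSV I/O, harmonization, and conversions.

The record types mirror one row of a GWAS or cis-QTL summary-statistic
table: a variant, its per-allele effect (beta, SE), the implied z-score and
two-sided p-value, and optionally the effect-allele frequency and sample
size.  Internal consistency (z = beta/se, p = 2*Phi(-|z|)) is enforced at
construction; missing z or p are recomputed rather than imputed.

Allele harmonization follows the usual two-sample conventions: swapped
alleles flip the outcome effect sign, strand complements are flipped then
matched, and palindromic variants are oriented by effect-allele frequency
when both frequencies are available and informative, otherwise dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import config
from .config import ConfigurationError

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ValidationError(ValueError):
    """A record violates a type invariant."""


# ---------------------------------------------------------------------------
# elementary conversions
# ---------------------------------------------------------------------------

def p_from_z(z, log: bool = False):
    """Two-sided normal p-value for a z-score, p = 2*Phi(-|z|).

    Accepts scalars or arrays.  With ``log=True`` returns the natural log of
    the p-value, which stays finite far beyond the double-precision
    underflow point of the p-value itself.
    """
    z = np.abs(np.asarray(z, dtype=float))
    if log:
        out = stats.norm.logsf(z) + math.log(2.0)
        return float(out) if out.ndim == 0 else out
    out = np.minimum(2.0 * stats.norm.sf(z), 1.0)
    return float(out) if out.ndim == 0 else out


def z_from_p(p: float) -> float:
    """|z| implied by a two-sided p-value."""
    if not (0 < p <= 1):
        raise ValidationError(f"p must lie in (0, 1]; got {p}")
    return float(-stats.norm.ppf(p / 2.0))


def or_ci_from_beta(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio and confidence bounds from a log-odds effect and its SE."""
    if se <= 0:
        raise ValidationError(f"se must be positive; got {se}")
    if not (0 < level < 1):
        raise ValidationError(f"confidence level must lie in (0, 1); got {level}")
    z_crit = float(stats.norm.ppf(1 - (1 - level) / 2.0))
    return (
        math.exp(beta),
        math.exp(beta - z_crit * se),
        math.exp(beta + z_crit * se),
    )


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with an explicit effect-allele orientation."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(f"{self.id}: non-ACGT effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(f"{self.id}: non-ACGT other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.id}: effect and other allele are identical")
        if self.pos < 1:
            raise ValidationError(f"{self.id}: position must be >= 1; got {self.pos}")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


# Below this p-value the z<->p consistency check is skipped: double
# precision cannot represent the tail accurately and comparisons move to
# log space (see p_from_z(log=True)).
_P_UNDERFLOW_GUARD = 1e-290


def _check_consistency(beta: float, se: float, z: float, p: float, label: str) -> None:
    if se <= 0:
        raise ValidationError(f"{label}: se must be positive; got {se}")
    if not (0 < p <= 1):
        raise ValidationError(f"{label}: p must lie in (0, 1]; got {p}")
    implied = beta / se
    if abs(z - implied) > 1e-6 * max(1.0, abs(implied)):
        raise ValidationError(
            f"{label}: z={z} inconsistent with beta/se={implied:.6g}"
        )
    # p must agree with the two-sided normal tail of z up to the rounding of
    # a value printed to ~3 significant figures.
    if _P_UNDERFLOW_GUARD < p < 1:
        z_implied = z_from_p(p)
        if abs(z_implied - abs(z)) > max(0.02 * abs(z), 0.02):
            raise ValidationError(
                f"{label}: p={p:.4g} inconsistent with |z|={abs(z):.4g}"
            )


@dataclass(frozen=True)
class GwasRecord:
    """One variant's association summary for the outcome trait."""

    variant: Variant
    beta: float
    se: float
    z: float = None  # type: ignore[assignment]
    p: float = None  # type: ignore[assignment]
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.z is None:
            object.__setattr__(self, "z", self.beta / self.se if self.se else math.nan)
        if self.p is None:
            object.__setattr__(self, "p", max(p_from_z(self.z), 5e-324))
        _check_consistency(self.beta, self.se, self.z, self.p, self.variant.id)
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.variant.id}: eaf must lie in (0, 1); got {self.eaf}")
        if self.n is not None and self.n < 2:
            raise ValidationError(f"{self.variant.id}: n must be >= 2")


@dataclass(frozen=True)
class QtlRecord:
    """One variant's association summary for a gene's molecular trait."""

    gene_id: str
    variant: Variant
    beta: float
    se: float
    z: float = None  # type: ignore[assignment]
    p: float = None  # type: ignore[assignment]
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.z is None:
            object.__setattr__(self, "z", self.beta / self.se if self.se else math.nan)
        if self.p is None:
            object.__setattr__(self, "p", max(p_from_z(self.z), 5e-324))
        _check_consistency(self.beta, self.se, self.z, self.p, f"{self.gene_id}:{self.variant.id}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.variant.id}: eaf must lie in (0, 1); got {self.eaf}")
        if self.n is not None and self.n < 2:
            raise ValidationError(f"{self.variant.id}: n must be >= 2")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

DEFAULT_LAYOUT: dict[str, str] = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "FRQ",
    "beta": "BETA",
    "se": "SE",
    "z": "Z",
    "p": "P",
    "n": "N",
    "gene_id": "GENE",
}

REQUIRED_FIELDS = ("id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se")


@dataclass
class RowError:
    row: int
    message: str


@dataclass
class ReadResult:
    records: list
    errors: list[RowError]


def _get(row, col):
    if col is None or col not in row or pd.isna(row[col]):
        return None
    return row[col]


def read_summary_table(
    path: str | Path,
    layout: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read a tab-separated summary-statistic table into validated records.

    ``layout`` maps record field names to column names; unspecified fields
    fall back to the default dialect (SNP/CHR/POS/A1/A2/FRQ/BETA/SE/Z/P/N,
    plus GENE for QTL tables).  Rows violating a record invariant are
    collected in ``errors`` with their row index rather than silently
    dropped; a missing required *column* raises immediately.
    """
    cols = dict(DEFAULT_LAYOUT)
    if layout:
        cols.update(layout)
    df = pd.read_csv(path, sep="\t", dtype={cols["chrom"]: str})
    for field in REQUIRED_FIELDS:
        if cols[field] not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {cols[field]!r} (field {field!r}) missing"
            )
    is_qtl = cols["gene_id"] in df.columns
    records: list = []
    errors: list[RowError] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            variant = Variant(
                id=str(row[cols["id"]]),
                chrom=str(row[cols["chrom"]]),
                pos=int(row[cols["pos"]]),
                effect_allele=str(row[cols["effect_allele"]]),
                other_allele=str(row[cols["other_allele"]]),
            )
            common = dict(
                variant=variant,
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                z=None if _get(row, cols["z"]) is None else float(row[cols["z"]]),
                p=None if _get(row, cols["p"]) is None else float(row[cols["p"]]),
                eaf=None if _get(row, cols["eaf"]) is None else float(row[cols["eaf"]]),
                n=None if _get(row, cols["n"]) is None else int(row[cols["n"]]),
            )
            if is_qtl:
                records.append(QtlRecord(gene_id=str(row[cols["gene_id"]]), **common))
            else:
                records.append(GwasRecord(**common))
        except (ValidationError, ValueError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return ReadResult(records=records, errors=errors)


def write_summary_table(records: Iterable, path: str | Path) -> None:
    """Write records back to the default TSV dialect at full precision."""
    rows = []
    for rec in records:
        v = rec.variant
        row = {
            "SNP": v.id,
            "CHR": v.chrom,
            "POS": v.pos,
            "A1": v.effect_allele,
            "A2": v.other_allele,
            "FRQ": rec.eaf,
            "BETA": rec.beta,
            "SE": rec.se,
            "Z": rec.z,
            "P": rec.p,
            "N": rec.n,
        }
        if isinstance(rec, QtlRecord):
            row = {"GENE": rec.gene_id, **row}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonizationDrop:
    """Signal that an exposure/outcome pair could not be oriented."""

    variant_id: str
    reason: str


def _flip_outcome(outcome: GwasRecord, effect: str, other: str) -> GwasRecord:
    """Reverse the outcome's effect orientation onto alleles (effect, other)."""
    return GwasRecord(
        variant=replace(outcome.variant, effect_allele=effect, other_allele=other),
        beta=-outcome.beta,
        se=outcome.se,
        z=-outcome.z,
        p=outcome.p,
        eaf=None if outcome.eaf is None else 1.0 - outcome.eaf,
        n=outcome.n,
    )


def _relabel(outcome: GwasRecord, effect: str, other: str) -> GwasRecord:
    return replace(
        outcome, variant=replace(outcome.variant, effect_allele=effect, other_allele=other)
    )


def harmonize(
    exposure: QtlRecord,
    outcome: GwasRecord,
    eaf_band: tuple[float, float] = config.PALINDROME_EAF_BAND,
):
    """Orient an outcome record onto the exposure's effect allele.

    Returns ``(exposure, outcome)`` with the outcome possibly sign-flipped
    and relabelled, or a :class:`HarmonizationDrop` when the pair cannot be
    reconciled (irreconcilable alleles, or a palindromic variant whose
    frequency is uninformative).  Harmonizing an already-harmonized pair is
    a no-op.
    """
    ev, ov = exposure.variant, outcome.variant
    if ev.id != ov.id:
        raise ValidationError(f"variant ids differ: {ev.id} vs {ov.id}")
    e1, e2 = ev.effect_allele, ev.other_allele
    o1, o2 = ov.effect_allele, ov.other_allele

    if ev.is_palindromic:
        if {o1, o2} != {e1, e2}:
            return HarmonizationDrop(ev.id, "allele mismatch")
        if exposure.eaf is None or outcome.eaf is None:
            return HarmonizationDrop(ev.id, "ambiguous palindrome")
        lo, hi = eaf_band
        if lo <= exposure.eaf <= hi or lo <= outcome.eaf <= hi:
            return HarmonizationDrop(ev.id, "ambiguous palindrome")
        out = outcome
        out_eaf = outcome.eaf
        if (o1, o2) != (e1, e2):  # swapped labels
            out = _flip_outcome(out, e1, e2)
            out_eaf = 1.0 - out_eaf
        # labels now agree; frequencies on opposite sides of 0.5 indicate the
        # outcome was reported on the opposite strand orientation
        if (exposure.eaf < 0.5) != (out_eaf < 0.5):
            out = _flip_outcome(out, e1, e2)
        return exposure, out

    if (o1, o2) == (e1, e2):
        return exposure, outcome
    if (o1, o2) == (e2, e1):
        return exposure, _flip_outcome(outcome, e1, e2)
    f1, f2 = COMPLEMENT[o1], COMPLEMENT[o2]
    if (f1, f2) == (e1, e2):
        return exposure, _relabel(outcome, e1, e2)
    if (f1, f2) == (e2, e1):
        return exposure, _flip_outcome(outcome, e1, e2)
    return HarmonizationDrop(ev.id, "allele mismatch")


def harmonize_many(
    exposures: Sequence[QtlRecord],
    outcomes_by_id: Mapping[str, GwasRecord],
    eaf_band: tuple[float, float] = config.PALINDROME_EAF_BAND,
) -> tuple[list[tuple[QtlRecord, GwasRecord]], list[HarmonizationDrop]]:
    """Harmonize each exposure record against the matching outcome record."""
    pairs: list[tuple[QtlRecord, GwasRecord]] = []
    drops: list[HarmonizationDrop] = []
    for exp in exposures:
        out = outcomes_by_id.get(exp.variant.id)
        if out is None:
            drops.append(HarmonizationDrop(exp.variant.id, "absent from outcome"))
            continue
        result = harmonize(exp, out, eaf_band)
        if isinstance(result, HarmonizationDrop):
            drops.append(result)
        else:
            pairs.append(result)
    return pairs, drops
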