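"""Two-sample Mendelian randomization from harmonized summary statistics.

Instrument selection at genome-wide significance, greedy LD clumping to a
strict independence threshold, causal-effect estimation by the Wald ratio
(single instrument) or inverse-variance weighting (several instruments,
with a Cochran's-Q-driven switch to multiplicative random effects), and the
Steiger directionality test comparing the variance the instruments explain
in the exposure versus the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import config
from .ld import LdMatrix
from .sumstats import (
    GwasRecord,
    HarmonizationDrop,
    QtlRecord,
    harmonize_many,
    p_from_z,
)


class MrError(ValueError):
    pass


@dataclass(frozen=True)
class Instrument:
    """One harmonized instrument: exposure and outcome effects."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    n_exp: int | None = None
    n_out: int | None = None

    @property
    def z_exp(self) -> float:
        return self.beta_exp / self.se_exp

    @property
    def z_out(self) -> float:
        return self.beta_out / self.se_out


@dataclass
class MrResult:
    """Causal estimate for one gene-outcome pair."""

    gene_id: str
    beta: float = math.nan
    se: float = math.nan
    p: float = math.nan
    n_instruments: int = 0
    method: str | None = None  # wald | ivw_fixed | ivw_random
    q_stat: float = math.nan
    q_p: float = math.nan
    steiger_correct: bool | None = None
    steiger_p: float = math.nan
    pass_bonferroni: bool | None = None
    reason: str | None = None


def instrument_from_pair(exposure: QtlRecord, outcome: GwasRecord) -> Instrument:
    return Instrument(
        variant_id=exposure.variant.id,
        beta_exp=exposure.beta,
        se_exp=exposure.se,
        beta_out=outcome.beta,
        se_out=outcome.se,
        n_exp=exposure.n,
        n_out=outcome.n,
    )


# ---------------------------------------------------------------------------
# instrument selection and clumping
# ---------------------------------------------------------------------------

def select_instruments(
    qtl: Sequence[QtlRecord], p_threshold: float = config.DEFAULT_INSTRUMENT_P
) -> list[QtlRecord]:
    """Exposure records below the significance threshold, strongest first.

    Ties at identical p are ordered by variant id so selection is
    deterministic under input reordering.
    """
    hits = [r for r in qtl if r.p < p_threshold]
    return sorted(hits, key=lambda r: (r.p, r.variant.id))


def ld_clump(
    candidates: Sequence[QtlRecord],
    ld: LdMatrix,
    r2_threshold: float = config.DEFAULT_CLUMP_R2,
) -> list[QtlRecord]:
    """Greedy clumping: keep index variants, remove their LD partners.

    Repeatedly takes the lowest-p remaining candidate as an index variant
    and removes every remaining candidate whose r^2 with it exceeds the
    threshold, so the retained set has pairwise r^2 <= r2_threshold.
    """
    ordered = sorted(candidates, key=lambda r: (r.p, r.variant.id))
    for rec in ordered:
        ld.index_of(rec.variant.id)  # raises naming the variant if absent
    kept: list[QtlRecord] = []
    remaining = list(ordered)
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        remaining = [
            r for r in remaining if ld.r2(index.variant.id, r.variant.id) <= r2_threshold
        ]
    return kept


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(inst: Instrument, second_order: bool = False) -> tuple[float, float]:
    """Single-instrument causal estimate beta_out / beta_exp.

    The default SE is the first-order delta method se_out/|beta_exp|,
    which ignores exposure uncertainty; ``second_order=True`` adds the
    exposure-side term of the delta expansion.
    """
    if inst.beta_exp == 0:
        raise MrError(f"{inst.variant_id}: Wald ratio undefined for beta_exp = 0")
    beta = inst.beta_out / inst.beta_exp
    var = (inst.se_out / inst.beta_exp) ** 2
    if second_order:
        var += inst.beta_out**2 * inst.se_exp**2 / inst.beta_exp**4
    return beta, math.sqrt(var)


def ivw(
    instruments: Sequence[Instrument],
    gene_id: str = "gene",
    alpha: float = config.DEFAULT_ALPHA,
) -> MrResult:
    """Inverse-variance-weighted meta-analysis of per-instrument ratios.

    Fixed-effects by default; when Cochran's Q is significant at ``alpha``
    and at least 4 instruments are available, the SE is inflated by the
    multiplicative heterogeneity factor sqrt(max(1, Q/(k-1))).
    """
    k = len(instruments)
    if k < 2:
        raise MrError("IVW requires >= 2 instruments; use wald_ratio for one")
    ratios = np.empty(k)
    weights = np.empty(k)
    for i, inst in enumerate(instruments):
        b, s = wald_ratio(inst)
        ratios[i] = b
        weights[i] = 1.0 / s**2
    beta = float(weights @ ratios / weights.sum())
    se = float(1.0 / math.sqrt(weights.sum()))
    q = float(weights @ (ratios - beta) ** 2)
    q_p = float(stats.chi2.sf(q, k - 1))
    method = "ivw_fixed"
    if q_p < alpha and k >= 4:
        se *= math.sqrt(max(1.0, q / (k - 1)))
        method = "ivw_random"
    return MrResult(
        gene_id=gene_id,
        beta=beta,
        se=se,
        p=max(p_from_z(beta / se), 5e-324),
        n_instruments=k,
        method=method,
        q_stat=q,
        q_p=q_p,
    )


# ---------------------------------------------------------------------------
# Steiger directionality
# ---------------------------------------------------------------------------

def _r2_sum(zs: Sequence[float], ns: Sequence[int]) -> float:
    # summary-data approximation of variance explained per instrument
    return float(sum(z**2 / (z**2 + n) for z, n in zip(zs, ns)))


def steiger_test(instruments: Sequence[Instrument]) -> tuple[bool, float]:
    """Does the instrument set explain more of the exposure than the outcome?

    Per-instrument variance explained is approximated as z^2/(z^2 + n) for
    each trait and summed.  The difference of the Fisher-transformed
    correlation magnitudes is tested with a two-sample z-test using the two
    sample sizes.  An exact tie is resolved conservatively as not correct.
    """
    if not instruments:
        raise MrError("Steiger test needs at least one instrument")
    for inst in instruments:
        if inst.n_exp is None or inst.n_out is None:
            raise MrError(f"{inst.variant_id}: sample size required for Steiger")
    r2_exp = min(_r2_sum([i.z_exp for i in instruments], [i.n_exp for i in instruments]), 1 - 1e-12)
    r2_out = min(_r2_sum([i.z_out for i in instruments], [i.n_out for i in instruments]), 1 - 1e-12)
    n_exp = float(np.mean([i.n_exp for i in instruments]))
    n_out = float(np.mean([i.n_out for i in instruments]))
    fz = math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))
    denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    p = float(p_from_z(fz / denom))
    return r2_exp > r2_out, p


# ---------------------------------------------------------------------------
# per-gene screen
# ---------------------------------------------------------------------------

def mr_gene_screen(
    qtl_by_gene: Mapping[str, Sequence[QtlRecord]],
    gwas: Sequence[GwasRecord],
    ld_by_gene: Mapping[str, LdMatrix] | LdMatrix,
    n_genes_tested: int,
    *,
    p_instrument: float = config.DEFAULT_INSTRUMENT_P,
    clump_r2: float = config.DEFAULT_CLUMP_R2,
    alpha: float = config.DEFAULT_ALPHA,
) -> list[MrResult]:
    """Select -> clump -> harmonize -> estimate -> Steiger, per gene.

    Genes yielding no usable instruments are reported with a reason rather
    than silently omitted.  ``pass_bonferroni`` flags p below
    alpha / n_genes_tested.
    """
    if n_genes_tested < 1:
        raise MrError("n_genes_tested must be >= 1")
    gate = alpha / n_genes_tested
    outcomes = {rec.variant.id: rec for rec in gwas}
    results: list[MrResult] = []
    for gene_id, records in qtl_by_gene.items():
        ld = ld_by_gene if isinstance(ld_by_gene, LdMatrix) else ld_by_gene[gene_id]
        selected = select_instruments(records, p_instrument)
        if not selected:
            results.append(MrResult(gene_id=gene_id, reason="no significant instruments"))
            continue
        clumped = ld_clump(selected, ld, clump_r2)
        pairs, drops = harmonize_many(clumped, outcomes)
        if not pairs:
            results.append(MrResult(gene_id=gene_id, reason="no valid instruments"))
            continue
        instruments = [instrument_from_pair(e, o) for e, o in pairs]
        if len(instruments) == 1:
            beta, se = wald_ratio(instruments[0])
            res = MrResult(
                gene_id=gene_id,
                beta=beta,
                se=se,
                p=max(p_from_z(beta / se), 5e-324),
                n_instruments=1,
                method="wald",
            )
        else:
            res = ivw(instruments, gene_id=gene_id, alpha=alpha)
        try:
            res.steiger_correct, res.steiger_p = steiger_test(instruments)
        except MrError:
            res.steiger_correct, res.steiger_p = None, math.nan
        res.pass_bonferroni = res.p < gate
        results.append(res)
    return results
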