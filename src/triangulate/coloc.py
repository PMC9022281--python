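"""Bayesian colocalization of two association signals at one locus.

Each variant's evidence of association with each trait is summarized by a
Wakefield approximate Bayes factor computed from the effect estimate and
its standard error under a normal prior on the true effect.  Enumerating
which variant (if any) is causal for each trait yields five mutually
exclusive hypotheses:

  H0  neither trait has a causal variant at the locus
  H1  only trait 1 (the molecular trait) has one
  H2  only trait 2 (the outcome) has one
  H3  both do, at two different variants
  H4  both do, at the same variant

Posterior probabilities follow from per-configuration prior weights
(p1, p2, p12) times the Bayes-factor products, normalized.  All
accumulation is done in log space: at |z| beyond ~30 the Bayes factors
overflow doubles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import config
from .sumstats import GwasRecord, QtlRecord, ValidationError, z_from_p


class ColocError(ValueError):
    pass


@dataclass(frozen=True)
class ColocConfig:
    """Priors and effect-variance hyperparameters for colocalization."""

    p1: float = config.DEFAULT_COLOC_P1
    p2: float = config.DEFAULT_COLOC_P2
    p12: float = config.DEFAULT_COLOC_P12
    w1: float = config.DEFAULT_COLOC_W1
    w2: float = config.DEFAULT_COLOC_W2

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ColocError(
                f"require 0 < p12 <= min(p1, p2); got p1={self.p1}, p2={self.p2}, p12={self.p12}"
            )
        if not (self.p1 + self.p2 + self.p12 < 1):
            raise ColocError("p1 + p2 + p12 must be < 1")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ColocError("prior effect variances must be positive")


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    gene_id: str
    pp: np.ndarray  # PP(H0)..PP(H4)
    n_snps: int
    strong_h4: bool

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])


def wakefield_abf(beta: float, se: float, prior_var: float) -> float:
    """Log approximate Bayes factor for association at one variant.

    log BF = 0.5*log(V/(V+w)) + z^2/2 * w/(V+w), with V = se^2 and w the
    prior variance of the true effect.  Positive values favor association.
    """
    if se <= 0:
        raise ValidationError(f"se must be positive; got {se}")
    if prior_var <= 0:
        raise ValidationError(f"prior_var must be positive; got {prior_var}")
    v = se**2
    z2 = (beta / se) ** 2
    return 0.5 * math.log(v / (v + prior_var)) + 0.5 * z2 * prior_var / (v + prior_var)


def abf_from_p_maf_n(p: float, maf: float, n: int, prior_var: float) -> float:
    """Fallback log ABF when beta/se are unavailable.

    Reconstructs |z| from the p-value and approximates the SE of a
    standardized per-allele effect as 1/sqrt(2*maf*(1-maf)*n).
    """
    if not (0 < maf < 1):
        raise ValidationError(f"maf must lie in (0, 1); got {maf}")
    z = z_from_p(p)
    se = 1.0 / math.sqrt(2.0 * maf * (1.0 - maf) * n)
    return wakefield_abf(z * se, se, prior_var)


def _log_posteriors(l1: np.ndarray, l2: np.ndarray, cfg: ColocConfig) -> np.ndarray:
    s0 = 0.0
    s1 = math.log(cfg.p1) + logsumexp(l1)
    s2 = math.log(cfg.p2) + logsumexp(l2)
    # H3 sums BF1_i * BF2_j over i != j; done on the full (i, j) grid in log
    # space because the algebraic shortcut (sum_i)(sum_j) - sum_ii cancels
    # catastrophically when one shared variant dominates both traits.
    grid = l1[:, None] + l2[None, :]
    np.fill_diagonal(grid, -np.inf)
    s3 = math.log(cfg.p1) + math.log(cfg.p2) + float(logsumexp(grid))
    s4 = math.log(cfg.p12) + float(logsumexp(l1 + l2))
    logs = np.array([s0, s1, s2, s3, s4])
    return logs - logsumexp(logs)


def coloc_posteriors(
    qtl: Sequence[QtlRecord],
    gwas: Sequence[GwasRecord],
    cfg: ColocConfig | None = None,
    *,
    gene_id: str | None = None,
    pph4_strong: float = config.DEFAULT_PPH4_STRONG,
) -> ColocResult:
    """Colocalize a gene's QTL signal with the outcome GWAS at its locus.

    Only variants present in both datasets are used (intersection
    semantics); at least two shared variants are required for the
    enumeration to be meaningful.
    """
    cfg = cfg or ColocConfig()
    by_id = {rec.variant.id: rec for rec in gwas}
    shared = [rec for rec in qtl if rec.variant.id in by_id]
    if len(shared) < 2:
        raise ColocError(
            f"insufficient locus overlap: {len(shared)} shared variant(s), need >= 2"
        )
    l1 = np.array([wakefield_abf(rec.beta, rec.se, cfg.w1) for rec in shared])
    l2 = np.array(
        [wakefield_abf(by_id[rec.variant.id].beta, by_id[rec.variant.id].se, cfg.w2) for rec in shared]
    )
    pp = np.exp(_log_posteriors(l1, l2, cfg))
    pp = pp / pp.sum()
    gid = gene_id if gene_id is not None else shared[0].gene_id
    return ColocResult(
        gene_id=gid,
        pp=pp,
        n_snps=len(shared),
        strong_h4=bool(pp[4] >= pph4_strong),
    )
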