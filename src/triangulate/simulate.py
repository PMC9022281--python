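"""Synthetic genotype panels and summary statistics under causal scenarios.

The generator produces everything the downstream stages consume, with truth
files, so the full chain (weight training, xWAS, MR, colocalization,
tiering) is exercisable offline:

* diploid genotypes with blockwise AR(1)-style linkage disequilibrium,
  sampled through a latent Gaussian copula thresholded at per-SNP allele
  frequencies;
* a quantitative molecular trait (expression or protein abundance) with a
  specified cis-heritability, driven by one or more causal cis variants;
* an outcome trait generated in an independent, non-overlapping sample
  (two-sample design) under one of six scenarios:

  - ``null``          neither trait has a causal variant;
  - ``qtl_only``      the molecular trait has causal variants, the outcome
                      is pure noise (the null of gene->outcome tests);
  - ``outcome_only``  the outcome has a causal variant, the molecular trait
                      is noise;
  - ``mediation``     the outcome is downstream of the molecular trait,
                      Y = gamma * E + noise;
  - ``pleiotropy``    the molecular trait's causal variants also affect the
                      outcome directly (shared variant, no mediation);
  - ``linkage``       the outcome's causal variant is distinct from the
                      molecular trait's, with pairwise r^2 kept below 0.05.

Marginal per-SNP regressions in each sample yield the QTL and GWAS summary
statistics; by construction z = beta/se for every emitted record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import config
from .ld import LdMatrix
from .sumstats import GwasRecord, QtlRecord, Variant, p_from_z

SCENARIOS = ("null", "mediation", "pleiotropy", "linkage", "qtl_only", "outcome_only")

# Scenarios in which the molecular trait has no causal variant.
_NO_QTL_SIGNAL = ("null", "outcome_only")
# Scenarios in which the outcome carries a genetic signal.
_OUTCOME_SIGNAL = ("mediation", "pleiotropy", "linkage", "outcome_only")

_BASE_POS = 1_000_000
_SNP_SPACING = 5_000


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative conditions for one simulated cis locus."""

    scenario: str = "null"
    n_snps: int = 200
    n_qtl: int = 10_000
    n_gwas: int = 10_000
    cis_h2: float = 0.01
    gamma: float = 1.0
    maf_range: tuple[float, float] = config.DEFAULT_MAF_RANGE
    ld_decay: float = 0.9
    n_causal_qtl: int = 1
    seed: int = config.DEFAULT_SEED
    gene_id: str = "G1"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SimulationError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if not (0 <= self.cis_h2 < 1):
            raise SimulationError(f"cis_h2 must lie in [0, 1); got {self.cis_h2}")
        if self.n_causal_qtl > self.n_snps:
            raise SimulationError("n_causal_qtl cannot exceed n_snps")
        if not (0 <= self.ld_decay < 1):
            raise SimulationError(f"ld_decay must lie in [0, 1); got {self.ld_decay}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError(f"maf_range must lie within (0, 0.5]; got {self.maf_range}")

    @property
    def outcome_h2(self) -> float:
        """Variance of the outcome explained by its causal variant(s).

        For the direct-effect scenarios (pleiotropy, linkage, outcome_only)
        the outcome-side signal is scaled to gamma^2 * cis_h2 so its
        strength is commensurate with the exposure-side signal.
        """
        return self.gamma**2 * self.cis_h2


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated gene, for recovery tests."""

    gene_id: str
    scenario: str
    causal_variant_ids: tuple[str, ...]
    outcome_variant_ids: tuple[str, ...]
    true_gamma: float
    realized_cis_h2: float


@dataclass
class LocusSimulation:
    """All artefacts of one simulated locus."""

    qtl_records: list[QtlRecord]
    gwas_records: list[GwasRecord]
    ld: LdMatrix
    truth: TruthRecord
    variants: list[Variant]
    mafs: np.ndarray
    exposure_genotypes: np.ndarray
    exposure_phenotype: np.ndarray
    outcome_genotypes: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    outcome_phenotype: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# genotype panels
# ---------------------------------------------------------------------------

def _haplotypes(rng: np.random.Generator, n: int, mafs: np.ndarray, rho: float) -> np.ndarray:
    """One haplotype per row via an AR(1) latent Gaussian copula."""
    m = len(mafs)
    if rho == 0.0:
        return (rng.random((n, m)) < mafs).astype(np.int8)
    latent = np.empty((n, m))
    latent[:, 0] = rng.standard_normal(n)
    innov = rng.standard_normal((n, m - 1)) * np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        latent[:, j] = rho * latent[:, j - 1] + innov[:, j - 1]
    return (latent < stats.norm.ppf(mafs)).astype(np.int8)


def _genotypes(rng: np.random.Generator, n: int, mafs: np.ndarray, rho: float) -> np.ndarray:
    g = _haplotypes(rng, n, mafs, rho) + _haplotypes(rng, n, mafs, rho)
    # guard against monomorphic columns in small panels: plant a heterozygote
    for j in np.flatnonzero(g.std(axis=0) == 0):
        g[rng.integers(n), j] = 1 if g[0, j] != 1 else 2
    return g.astype(np.float64)


def _default_variants(n_snps: int, chrom: str = "1") -> list[Variant]:
    # non-palindromic A/G variants spaced uniformly within a 1 Mb cis block
    return [
        Variant(
            id=f"rs{j + 1}",
            chrom=chrom,
            pos=_BASE_POS + j * _SNP_SPACING,
            effect_allele="A",
            other_allele="G",
        )
        for j in range(n_snps)
    ]


def simulate_panel(
    n_individuals: int,
    n_snps: int,
    maf_range: tuple[float, float] = config.DEFAULT_MAF_RANGE,
    ld_decay: float = 0.9,
    seed: int = config.DEFAULT_SEED,
) -> tuple[np.ndarray, LdMatrix]:
    """Simulate a diploid reference panel and its realized LD matrix.

    Latent Gaussian AR(1) correlation ``ld_decay**|i-j|`` is thresholded at
    each SNP's allele-frequency quantile, so realized LD decays with
    distance along the locus.  Returns the (individuals x SNPs) dosage
    matrix and the correlation matrix computed from it.
    """
    if n_individuals < 2:
        raise SimulationError("n_individuals must be >= 2")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise SimulationError(f"maf_range must lie within (0, 0.5]; got {maf_range}")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    g = _genotypes(rng, n_individuals, mafs, ld_decay)
    ids = [v.id for v in _default_variants(n_snps)]
    return g, LdMatrix.from_panel(g, ids)


# ---------------------------------------------------------------------------
# summary statistics from individual-level data
# ---------------------------------------------------------------------------

def marginal_stats(genotypes: np.ndarray, trait: np.ndarray) -> pd.DataFrame:
    """Per-SNP simple-regression summary statistics (beta, se, z, p, eaf)."""
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    n = len(y)
    xm = g.mean(axis=0)
    xc = g - xm
    xv = (xc**2).mean(axis=0)
    yc = y - y.mean()
    beta = (xc.T @ yc) / (n * xv)
    resid_var = yc @ yc / n - beta**2 * xv
    se = np.sqrt(np.maximum(resid_var, 1e-300) / (n * xv))
    z = beta / se
    return pd.DataFrame(
        {"beta": beta, "se": se, "z": z, "p": p_from_z(z), "eaf": xm / 2.0, "n": n}
    )


def _records_from_stats(df: pd.DataFrame, variants: Sequence[Variant], gene_id: str | None):
    out = []
    for v, row in zip(variants, df.itertuples(index=False)):
        common = dict(
            variant=v,
            beta=float(row.beta),
            se=float(row.se),
            z=float(row.z),
            p=max(float(row.p), 5e-324),
            eaf=float(np.clip(row.eaf, 1e-6, 1 - 1e-6)),
            n=int(row.n),
        )
        out.append(GwasRecord(**common) if gene_id is None else QtlRecord(gene_id=gene_id, **common))
    return out


# ---------------------------------------------------------------------------
# locus simulation under causal scenarios
# ---------------------------------------------------------------------------

def _standardize(g: np.ndarray) -> np.ndarray:
    return (g - g.mean(axis=0)) / g.std(axis=0)


def _scaled_genetic_value(
    x_std: np.ndarray, idx: np.ndarray, b: np.ndarray, target_var: float
) -> tuple[np.ndarray, np.ndarray]:
    """Genetic value with sample variance rescaled to exactly target_var."""
    gv = x_std[:, idx] @ b
    v = gv.var()
    if v <= 0:
        raise SimulationError("degenerate genetic value; increase sample size")
    c = np.sqrt(target_var / v)
    return gv * c, b * c


def _pick_outcome_variant(
    rng: np.random.Generator, ld: LdMatrix, causal_idx: np.ndarray, max_r2: float
) -> int:
    """A variant nearly uncorrelated with every exposure causal variant."""
    m = ld.n_variants
    order = rng.permutation(m)
    r2 = ld.r**2
    for j in order:
        if j in causal_idx:
            continue
        if len(causal_idx) == 0 or r2[j, causal_idx].max() < max_r2:
            return int(j)
    raise SimulationError(
        f"no variant with r^2 < {max_r2} to all exposure causal variants; "
        "lower ld_decay or raise n_snps"
    )


def simulate_locus(spec: ScenarioSpec) -> LocusSimulation:
    """Simulate one cis locus: two independent samples, both summary sets.

    The exposure (molecular trait) and outcome samples are disjoint, so the
    emitted QTL and GWAS summary statistics realize a two-sample design.
    The returned LD matrix is computed from the exposure panel, which also
    serves as the LD reference downstream.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=spec.n_snps)
    variants = _default_variants(spec.n_snps)
    ids = [v.id for v in variants]

    g_exp = _genotypes(rng, spec.n_qtl, mafs, spec.ld_decay)
    g_out = _genotypes(rng, spec.n_gwas, mafs, spec.ld_decay)
    ld = LdMatrix.from_panel(g_exp, ids)
    x_exp = _standardize(g_exp)
    x_out = _standardize(g_out)

    has_qtl_signal = spec.scenario not in _NO_QTL_SIGNAL and spec.cis_h2 > 0
    causal_idx = np.array([], dtype=int)
    b = np.array([])
    realized_h2 = 0.0
    if has_qtl_signal:
        causal_idx = np.sort(rng.choice(spec.n_snps, size=spec.n_causal_qtl, replace=False))
        b_raw = rng.standard_normal(spec.n_causal_qtl)
        gv_exp, b = _scaled_genetic_value(x_exp, causal_idx, b_raw, spec.cis_h2)
        noise = rng.normal(0.0, np.sqrt(1.0 - spec.cis_h2), size=spec.n_qtl)
        exposure = gv_exp + noise
        realized_h2 = float(gv_exp.var() / exposure.var())
    else:
        exposure = rng.standard_normal(spec.n_qtl)

    outcome_idx: tuple[str, ...] = ()
    if spec.scenario in ("null", "qtl_only"):
        outcome = rng.standard_normal(spec.n_gwas)
    elif spec.scenario == "mediation":
        # outcome is downstream of the molecular trait itself
        gv_out = x_out[:, causal_idx] @ b
        e_out = gv_out + rng.normal(0.0, np.sqrt(1.0 - spec.cis_h2), size=spec.n_gwas)
        outcome = spec.gamma * e_out + rng.standard_normal(spec.n_gwas)
        outcome_idx = tuple(ids[j] for j in causal_idx)
    elif spec.scenario == "pleiotropy":
        # the shared variants act on the outcome directly, not through E
        target = spec.outcome_h2
        if not (0 <= target < 1):
            raise SimulationError(
                f"outcome heritability gamma^2*cis_h2={target:.3g} must lie in [0, 1)"
            )
        gv_out, _ = _scaled_genetic_value(x_out, causal_idx, b, target)
        outcome = gv_out + rng.normal(0.0, np.sqrt(1.0 - target), size=spec.n_gwas)
        outcome_idx = tuple(ids[j] for j in causal_idx)
    elif spec.scenario in ("linkage", "outcome_only"):
        target = spec.outcome_h2
        if not (0 <= target < 1):
            raise SimulationError(
                f"outcome heritability gamma^2*cis_h2={target:.3g} must lie in [0, 1)"
            )
        max_r2 = config.LINKAGE_MAX_R2 if spec.scenario == "linkage" else 1.0
        j_out = _pick_outcome_variant(rng, ld, causal_idx, max_r2)
        b_out = np.array([1.0])
        gv_out, _ = _scaled_genetic_value(x_out, np.array([j_out]), b_out, target)
        outcome = gv_out + rng.normal(0.0, np.sqrt(1.0 - target), size=spec.n_gwas)
        outcome_idx = (ids[j_out],)

    qtl_df = marginal_stats(g_exp, exposure)
    gwas_df = marginal_stats(g_out, outcome)
    truth = TruthRecord(
        gene_id=spec.gene_id,
        scenario=spec.scenario,
        causal_variant_ids=tuple(ids[j] for j in causal_idx),
        outcome_variant_ids=outcome_idx,
        true_gamma=spec.gamma if spec.scenario == "mediation" else 0.0,
        realized_cis_h2=realized_h2,
    )
    return LocusSimulation(
        qtl_records=_records_from_stats(qtl_df, variants, spec.gene_id),
        gwas_records=_records_from_stats(gwas_df, variants, None),
        ld=ld,
        truth=truth,
        variants=variants,
        mafs=mafs,
        exposure_genotypes=g_exp,
        exposure_phenotype=exposure,
        outcome_genotypes=g_out,
        outcome_phenotype=outcome,
    )


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (kept below 2**31) from one root seed."""
    rng = np.random.default_rng(root_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
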