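"""Cis prediction-weight training and the xWAS association statistic.

The proteome-/transcriptome-wide association test asks whether genetically
predicted molecular abundance is associated with an outcome, using only the
outcome's GWAS z-scores, a set of per-variant cis weights, and an LD
reference:

    z_xwas = (w' z) / sqrt(w' R w)

where ``w`` are the gene's prediction weights, ``z`` the outcome z-scores
aligned to the same effect alleles, and ``R`` the (stabilized) LD matrix.

Weights are trained from an individual-level panel.  A gene must first show
evidence of cis heritability (single-variance-component linear mixed model,
restricted-likelihood-ratio test) before any predictive model is fitted;
four models are then trained - the single best marginal variant (top1),
the LMM-equivalent ridge (blup), lasso, and elastic net - and the one with
the best k-fold cross-validated R^2 supplies the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from . import config
from .config import ConfigurationError
from .ld import LdMatrix, stabilize_ld
from .sumstats import Variant, p_from_z

MODEL_LABELS = ("top1", "blup", "lasso", "enet")


class XwasError(ValueError):
    pass


@dataclass
class WeightModel:
    """A gene's cis prediction weights with training metadata."""

    gene_id: str
    variants: list[Variant]
    weights: np.ndarray
    model_label: str
    cv_r2: float
    h2_hat: float
    h2_p: float
    cv_scores: dict | None = None  # per-model out-of-fold R^2 from training

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.model_label not in MODEL_LABELS:
            raise XwasError(f"unknown model label {self.model_label!r}")
        if len(self.variants) != len(self.weights):
            raise XwasError("variants and weights length mismatch")
        if not np.any(self.weights != 0):
            raise XwasError(f"{self.gene_id}: all weights are zero")


@dataclass
class XwasResult:
    gene_id: str
    z_xwas: float
    p: float
    n_snps_used: int
    p_bonferroni: float | None = None
    q_bh: float | None = None


# ---------------------------------------------------------------------------
# cis heritability (single-component LMM, REML via spectral decomposition)
# ---------------------------------------------------------------------------

def _standardize(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return (g - g.mean(axis=0)) / sd


def estimate_cis_h2(genotypes: np.ndarray, phenotype: np.ndarray) -> tuple[float, float]:
    """Estimate the fraction of trait variance from cis genotypes.

    Fits y ~ N(mu, sigma_g^2 K + sigma_e^2 I) with K = X X'/m (X the
    per-SNP standardized genotypes) by maximizing the restricted likelihood
    over h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).  The spectrum of K is
    obtained from the thin SVD of X, so the cost is O(n m^2) regardless of
    sample size.  The null h^2 = 0 is tested by a likelihood-ratio test
    against the boundary mixture 0.5*chi2_0 + 0.5*chi2_1.

    Returns ``(h2_hat, p_value)`` with h2_hat clamped to [0, 1].
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n < 30:
        raise XwasError(f"need >= 30 individuals for heritability estimation; got {n}")
    if y.var() == 0:
        raise XwasError("zero variance phenotype")
    x = _standardize(genotypes)
    m = x.shape[1]
    yc = y - y.mean()

    u, s, _ = linalg.svd(x, full_matrices=False)
    lam = s**2 / m
    keep = lam > 1e-12
    lam = lam[keep]
    a = u[:, keep].T @ yc
    rss = float(max(yc @ yc - a @ a, 0.0))
    df = n - 1
    n_free = df - len(lam)  # dimensions orthogonal to the genetic spectrum

    def loglik(h2: float) -> float:
        v = h2 * lam + (1.0 - h2)
        quad = float(a**2 @ (1.0 / v))
        logdet = float(np.log(v).sum())
        if n_free > 0:
            quad += rss / (1.0 - h2)
            logdet += n_free * np.log(1.0 - h2)
        elif rss > 1e-12 * (yc @ yc):
            quad += rss / (1.0 - h2)
        sigma2 = quad / df
        return -0.5 * (logdet + df * np.log(sigma2))

    grid = np.linspace(0.0, 0.9999, 201)
    values = np.array([loglik(h) for h in grid])
    i_best = int(values.argmax())
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda h: -loglik(h), bounds=(lo, hi), method="bounded"
    )
    h2_hat = float(res.x) if -res.fun >= values[i_best] else float(grid[i_best])
    ll_best = max(-res.fun, values[i_best])
    lrt = 2.0 * (ll_best - loglik(0.0))
    p = 1.0 if lrt <= 0 else 0.5 * float(stats.chi2.sf(lrt, 1))
    return min(max(h2_hat, 0.0), 1.0), p


# ---------------------------------------------------------------------------
# weight training with CV model selection
# ---------------------------------------------------------------------------

def _fit_top1(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    score = np.abs(x.T @ y)
    j = int(score.argmax())
    w = np.zeros(x.shape[1])
    w[j] = (x[:, j] @ y) / (x[:, j] @ x[:, j])
    return w


def _fit_blup(x: np.ndarray, y: np.ndarray, h2: float) -> np.ndarray:
    m = x.shape[1]
    h2 = min(max(h2, 0.01), 0.99)
    lam = m * (1.0 - h2) / h2
    return linalg.solve(x.T @ x + lam * np.eye(m), x.T @ y, assume_a="pos")


def train_weights(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    *,
    gene_id: str = "gene",
    variants: Sequence[Variant] | None = None,
    h2_gate: float = config.DEFAULT_H2_GATE_P,
    k_folds: int = 5,
    seed: int = 0,
) -> WeightModel | None:
    """Train cis prediction weights for one gene, or None below the h2 gate.

    Genes whose heritability LRT p-value is at or above ``h2_gate`` are not
    trained.  Otherwise top1, blup, lasso, and elastic net (l1_ratio 0.5)
    are fitted; lasso/enet penalties are chosen once by their own internal
    cross-validation, and all four models are then compared on a shared
    k-fold split by out-of-fold R^2.  The winner is refit on the full panel.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    if n < k_folds:
        raise ConfigurationError(f"{n} individuals cannot support {k_folds}-fold CV")
    h2_hat, h2_p = estimate_cis_h2(g, y)
    if h2_p >= h2_gate:
        return None

    x = _standardize(g)
    yc = y - y.mean()
    rng_state = seed % (2**31 - 1)
    alpha_lasso = LassoCV(cv=k_folds, random_state=rng_state, alphas=50).fit(x, yc).alpha_
    alpha_enet = (
        ElasticNetCV(l1_ratio=0.5, cv=k_folds, random_state=rng_state, alphas=50)
        .fit(x, yc)
        .alpha_
    )

    fitters = {
        "top1": lambda xt, yt: _fit_top1(xt, yt),
        "blup": lambda xt, yt: _fit_blup(xt, yt, h2_hat),
        "lasso": lambda xt, yt: Lasso(alpha=alpha_lasso).fit(xt, yt).coef_,
        "enet": lambda xt, yt: ElasticNet(alpha=alpha_enet, l1_ratio=0.5).fit(xt, yt).coef_,
    }

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=rng_state)
    ss_tot = float(yc @ yc)
    cv_r2: dict[str, float] = {}
    for label, fit in fitters.items():
        ss_res = 0.0
        for train, test in kf.split(x):
            w = fit(x[train], yc[train])
            resid = yc[test] - x[test] @ w
            ss_res += float(resid @ resid)
        cv_r2[label] = 1.0 - ss_res / ss_tot

    full_weights = {label: np.asarray(fit(x, yc), dtype=float) for label, fit in fitters.items()}
    candidates = [lab for lab in MODEL_LABELS if np.any(full_weights[lab] != 0)]
    best = max(candidates, key=lambda lab: cv_r2[lab])
    if variants is None:
        variants = [
            Variant(f"v{j + 1}", "1", 1 + j, "A", "G") for j in range(m)
        ]
    return WeightModel(
        gene_id=gene_id,
        variants=list(variants),
        weights=full_weights[best],
        model_label=best,
        cv_r2=float(cv_r2[best]),
        h2_hat=h2_hat,
        h2_p=h2_p,
        cv_scores={lab: float(v) for lab, v in cv_r2.items()},
    )


# ---------------------------------------------------------------------------
# association statistic
# ---------------------------------------------------------------------------

def xwas_assoc(
    model: WeightModel,
    gwas_z: Mapping[str, float],
    ld: LdMatrix,
) -> XwasResult:
    """Association between predicted abundance and the outcome.

    ``gwas_z`` maps variant id to the outcome z-score, harmonized to the
    same effect alleles as the weights.  Weight variants missing from the
    GWAS are dropped jointly from the weights and the LD matrix; the count
    of variants actually used is recorded.
    """
    present = [i for i, v in enumerate(model.variants) if v.id in gwas_z]
    if not present:
        raise XwasError(f"{model.gene_id}: no overlap between weight variants and GWAS")
    ids = [model.variants[i].id for i in present]
    w = model.weights[present]
    if not np.any(w != 0):
        raise XwasError(f"{model.gene_id}: all overlapping weights are zero")
    z = np.array([gwas_z[i] for i in ids], dtype=float)
    sub, _ = stabilize_ld(ld.subset(ids))
    denom = float(w @ sub.r @ w)
    z_x = float(w @ z) / np.sqrt(denom)
    return XwasResult(
        gene_id=model.gene_id,
        z_xwas=z_x,
        p=max(p_from_z(z_x), 5e-324),
        n_snps_used=len(ids),
    )


def write_weights(models: Sequence[WeightModel], path: str) -> None:
    """Write weight models to the package's TSV dialect (one row per SNP)."""
    import pandas as pd

    rows = []
    for model in models:
        for v, w in zip(model.variants, model.weights):
            if w == 0:
                continue
            rows.append(
                {
                    "GENE": model.gene_id,
                    "SNP": v.id,
                    "CHR": v.chrom,
                    "POS": v.pos,
                    "A1": v.effect_allele,
                    "A2": v.other_allele,
                    "WEIGHT": w,
                    "MODEL": model.model_label,
                    "CV_R2": model.cv_r2,
                    "H2": model.h2_hat,
                    "H2_P": model.h2_p,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weights(path: str) -> list[WeightModel]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    models = []
    for gene_id, sub in df.groupby("GENE", sort=True):
        variants = [
            Variant(str(r.SNP), str(r.CHR), int(r.POS), str(r.A1), str(r.A2))
            for r in sub.itertuples(index=False)
        ]
        models.append(
            WeightModel(
                gene_id=str(gene_id),
                variants=variants,
                weights=sub["WEIGHT"].to_numpy(dtype=float),
                model_label=str(sub["MODEL"].iloc[0]),
                cv_r2=float(sub["CV_R2"].iloc[0]),
                h2_hat=float(sub["H2"].iloc[0]),
                h2_p=float(sub["H2_P"].iloc[0]),
            )
        )
    return models


def adjust_pvalues(results: Sequence[XwasResult], n_tests: int) -> list[XwasResult]:
    """Fill Bonferroni-adjusted p and Benjamini-Hochberg q for each result.

    ``n_tests`` may exceed the number of results (genes tested but not
    reported); the BH step-up then behaves as if the missing tests had
    p = 1, which leaves the q-values of the reported genes unchanged.
    """
    if n_tests < len(results):
        raise ConfigurationError("n_tests must be at least the number of results")
    if not results:
        return []
    p = np.array([r.p for r in results])
    padded = np.concatenate([p, np.ones(n_tests - len(p))])
    _, q, _, _ = multipletests(padded, method="fdr_bh")
    return [
        replace(r, p_bonferroni=min(1.0, r.p * n_tests), q_bh=float(qi))
        for r, qi in zip(results, q[: len(p)])
    ]
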