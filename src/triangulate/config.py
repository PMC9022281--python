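"""Pipeline configuration.

Every analysis threshold used anywhere in the package is defined in this
module and nowhere else, so that a single config object fully determines a
run and the resolved configuration can be logged verbatim.  The defaults are
the conventional values for this kind of summary-statistic integration:
genome-wide significance for instrument selection, a very strict clumping
r-squared, a per-gene cis-heritability gate, coloc's default priors, and a
0.75 posterior-probability bound for "strong" colocalization.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Any

import yaml

logger = logging.getLogger("triangulate")

# --- instrument / clumping / weight-training gates ---
DEFAULT_INSTRUMENT_P = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_H2_GATE_P = 0.01
DEFAULT_CIS_WINDOW_BP = 1_000_000

# --- colocalization priors and decision bound ---
DEFAULT_COLOC_P1 = 1e-4
DEFAULT_COLOC_P2 = 1e-4
DEFAULT_COLOC_P12 = 1e-5
DEFAULT_PPH4_STRONG = 0.75
# Prior effect variances (sd^2): 0.15 for a quantitative molecular trait,
# 0.20 on the log-odds scale for a disease outcome.
DEFAULT_COLOC_W1 = 0.15**2
DEFAULT_COLOC_W2 = 0.20**2

# --- significance level used for Bonferroni gates and heterogeneity ---
DEFAULT_ALPHA = 0.05

# --- reproducibility ---
DEFAULT_SEED = 20220421

# --- numerical/stabilization constants shared across modules ---
# Ridge schedule for LD-matrix stabilization: smallest value making the
# matrix numerically positive definite is used.
LD_RIDGE_SCHEDULE = (0.0, 1e-4, 1e-3, 1e-2, 0.1)
LD_MIN_EIGENVALUE = 1e-8
# Effect-allele-frequency band inside which a palindromic (A/T, C/G) variant
# cannot be oriented and is dropped.
PALINDROME_EAF_BAND = (0.42, 0.58)
# Maximum r^2 allowed between the two distinct causal variants of a
# simulated linkage locus.
LINKAGE_MAX_R2 = 0.05
# Default minor-allele-frequency range for simulated panels.
DEFAULT_MAF_RANGE = (0.05, 0.5)


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its invariants."""


@dataclass
class PipelineConfig:
    """All tunable thresholds for one pipeline run.

    Attributes
    ----------
    instrument_p:
        Exposure p-value below which a QTL variant is eligible as an MR
        instrument (genome-wide significance).
    clump_r2:
        Variants with r^2 above this to a retained index variant are removed
        during greedy LD clumping.
    h2_gate_p:
        Cis-heritability likelihood-ratio p-value a gene must beat before
        prediction weights are trained.
    cis_window_bp:
        Half-width of the cis window around a gene's transcription start.
    p1, p2, p12:
        Colocalization priors: a variant associates with trait 1 only, with
        trait 2 only, or with both.
    w1, w2:
        Prior effect variances for the two traits' approximate Bayes factors.
    pph4_strong:
        Posterior probability of a shared causal variant at or above which
        colocalization counts as strong evidence.
    alpha:
        Family-wise significance level used in Bonferroni gates and for the
        heterogeneity-driven fixed/random IVW switch.
    seed:
        Root seed for every source of randomness in a run.
    """

    instrument_p: float = DEFAULT_INSTRUMENT_P
    clump_r2: float = DEFAULT_CLUMP_R2
    h2_gate_p: float = DEFAULT_H2_GATE_P
    cis_window_bp: int = DEFAULT_CIS_WINDOW_BP
    p1: float = DEFAULT_COLOC_P1
    p2: float = DEFAULT_COLOC_P2
    p12: float = DEFAULT_COLOC_P12
    w1: float = DEFAULT_COLOC_W1
    w2: float = DEFAULT_COLOC_W2
    pph4_strong: float = DEFAULT_PPH4_STRONG
    alpha: float = DEFAULT_ALPHA
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ConfigurationError(
                f"coloc priors require 0 < p12 <= min(p1, p2); got "
                f"p1={self.p1}, p2={self.p2}, p12={self.p12}"
            )
        if not (self.p1 + self.p2 + self.p12 < 1):
            raise ConfigurationError("coloc priors must sum to less than 1")
        for name in ("instrument_p", "clump_r2", "h2_gate_p", "alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must lie in (0, 1); got {v}")
        if not (0 < self.pph4_strong <= 1):
            raise ConfigurationError("pph4_strong must lie in (0, 1]")
        if self.cis_window_bp <= 0:
            raise ConfigurationError("cis_window_bp must be positive")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ConfigurationError("prior effect variances must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def log_resolved(self) -> None:
        """Log the fully resolved configuration, one line per field."""
        for key, value in sorted(self.to_dict().items()):
            logger.info("config %s = %r", key, value)

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "PipelineConfig":
        """Load a config from a YAML mapping; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a YAML mapping")
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
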