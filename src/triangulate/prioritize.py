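"""Cross-method evidence merging and causal-gene tier assignment.

A gene is examined per tissue (brain or blood) and per molecular layer
(protein or transcript).  Four criteria feed the tier logic: an xWAS pass
at the Bonferroni gate, an MR pass at the Bonferroni gate, a correct
Steiger direction, and strong colocalization (PP(H4) at or above the
configured bound).  Colocalization is not required for blood protein
evidence, where it is not performed.

Tiers:

* ``tier1``       the full chain holds at both molecular layers;
* ``tier2``       the full chain holds at exactly one layer;
* ``supportive``  significant in at least one method (xWAS or MR) but the
                  full chain never completes - e.g. MR and xWAS agree yet
                  colocalization stays weak;
* ``none``        otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

TISSUES = ("brain", "blood")
LAYERS = ("protein", "transcript")
TIERS = ("tier1", "tier2", "supportive", "none")


class MergeError(ValueError):
    pass


@dataclass(frozen=True)
class GeneEvidence:
    """Merged per-gene evidence for one tissue and molecular layer."""

    gene_id: str
    tissue: str
    layer: str
    xwas_pass: bool
    mr_pass: bool
    steiger_correct: bool
    coloc_strong: bool | None  # None when colocalization was not performed
    tier: str | None = None
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise MergeError(f"unknown tissue {self.tissue!r}")
        if self.layer not in LAYERS:
            raise MergeError(f"unknown layer {self.layer!r}")
        if self.tier is not None and self.tier not in TIERS:
            raise MergeError(f"unknown tier {self.tier!r}")


def coloc_required(tissue: str, layer: str) -> bool:
    """Colocalization is run for all brain evidence but only for blood
    transcript evidence; a blood protein chain is complete without it."""
    return not (tissue == "blood" and layer == "protein")


def full_chain(ev: GeneEvidence) -> bool:
    """All required criteria hold for this gene/tissue/layer record."""
    coloc_ok = True if not coloc_required(ev.tissue, ev.layer) else bool(ev.coloc_strong)
    return ev.xwas_pass and ev.mr_pass and ev.steiger_correct and coloc_ok


def assign_tier(evidence: Sequence[GeneEvidence]) -> list[GeneEvidence]:
    """Assign one tier to a gene from its per-layer evidence records.

    All records must belong to the same gene and tissue.  Duplicate records
    for a layer must agree exactly; conflicting duplicates raise a
    :class:`MergeError` naming the layer.  The returned records (one per
    distinct layer, input order preserved) all carry the gene-level tier,
    so the assignment is order-independent by construction.
    """
    if not evidence:
        raise MergeError("no evidence records supplied")
    gene_ids = {ev.gene_id for ev in evidence}
    tissues = {ev.tissue for ev in evidence}
    if len(gene_ids) != 1 or len(tissues) != 1:
        raise MergeError(
            f"evidence mixes genes/tissues: genes={sorted(gene_ids)}, tissues={sorted(tissues)}"
        )
    by_layer: dict[str, GeneEvidence] = {}
    for ev in evidence:
        bare = replace(ev, tier=None, reason=None)
        prev = by_layer.get(ev.layer)
        if prev is not None and prev != bare:
            raise MergeError(
                f"conflicting duplicate records for {ev.gene_id}/{ev.tissue}/{ev.layer}"
            )
        by_layer.setdefault(ev.layer, bare)

    chains = {layer: full_chain(ev) for layer, ev in by_layer.items()}
    n_full = sum(chains.values())
    if n_full >= 2:
        tier, reason = "tier1", "full evidence chain at both molecular layers"
    elif n_full == 1:
        layer = next(l for l, ok in chains.items() if ok)
        tier, reason = "tier2", f"full evidence chain at the {layer} layer only"
    elif any(ev.xwas_pass or ev.mr_pass for ev in by_layer.values()):
        tier, reason = "supportive", "significant in >= 1 method but the chain is incomplete"
    else:
        tier, reason = "none", "no significant evidence"
    return [replace(ev, tier=tier, reason=reason) for ev in by_layer.values()]


@dataclass
class TissueComparison:
    """Overlap of prioritized genes between brain and blood."""

    brain_genes: set[str]
    blood_genes: set[str]
    intersection: set[str]
    brain_only: set[str]
    blood_only: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "brain": len(self.brain_genes),
            "blood": len(self.blood_genes),
            "intersection": len(self.intersection),
            "brain_only": len(self.brain_only),
            "blood_only": len(self.blood_only),
        }


def compare_tissues(
    brain: Iterable[GeneEvidence],
    blood: Iterable[GeneEvidence],
    min_tier: str = "tier2",
) -> TissueComparison:
    """Set overlap of genes reaching at least ``min_tier`` in each tissue."""
    if min_tier not in TIERS:
        raise MergeError(f"unknown tier {min_tier!r}")
    rank = {t: i for i, t in enumerate(TIERS)}
    cutoff = rank[min_tier]

    def genes(records: Iterable[GeneEvidence]) -> set[str]:
        out = set()
        for ev in records:
            if ev.tier is None:
                raise MergeError(f"{ev.gene_id}: tier not assigned; run assign_tier first")
            if rank[ev.tier] <= cutoff:
                out.add(ev.gene_id)
        return out

    b, bl = genes(brain), genes(blood)
    return TissueComparison(
        brain_genes=b,
        blood_genes=bl,
        intersection=b & bl,
        brain_only=b - bl,
        blood_only=bl - b,
    )
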