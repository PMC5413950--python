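"""Signature-versus-signature GSEA.

Two differential signatures (e.g. reprogrammed-tissue vs control, and normal
tissue vs control) are compared by turning one into a gene set — its top-k
up- or bottom-k down-regulated genes — and scoring that set on the other,
ranked, signature with the same weighted running-sum ES and gene-permutation
NES/p used for regulon enrichment (all modes +1, unit weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, nes_by_gene_permutation, running_sum_profile
from .network import GeneSignature, Regulon, RegulatoryEdge

__all__ = ["GeneSet", "signature_geneset", "gsea", "gsea_profile"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("gene set must be non-empty")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


def signature_geneset(sig: GeneSignature, k: int, direction: str = "up") -> GeneSet:
    """Top-k (up) or bottom-k (down) genes of a signature as a gene set.

    Ties at the boundary are broken by gene id (the signature's canonical
    order is already deterministic), so the same inputs always give the same
    set.
    """
    if not 1 <= k <= sig.n:
        raise ValueError(f"k must be in [1, {sig.n}], got {k}")
    if direction == "up":
        members = list(sig.genes[:k])
    elif direction == "down":
        bottom = sorted(sig.genes, key=lambda g: (sig.scores[g], g))[:k]
        members = bottom
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return GeneSet(f"{direction}{k}", frozenset(members), direction)


def _as_regulon(gene_set: GeneSet) -> Regulon:
    name = f"geneset:{gene_set.name}"
    return Regulon(
        name,
        [RegulatoryEdge(name, g, 1, 1.0) for g in sorted(gene_set.members)],
    )


def gsea(
    gene_set: GeneSet,
    sig: GeneSignature,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted-ES enrichment of *gene_set* on *sig* with gene-permutation p.

    Set members absent from the signature are dropped; no overlap is an error.
    """
    return nes_by_gene_permutation(sig, _as_regulon(gene_set), n_perm=n_perm, seed=seed)


def gsea_profile(gene_set: GeneSet, sig: GeneSignature) -> pd.DataFrame:
    """Running-sum curve as a position/value table for plot export."""
    positions, values = running_sum_profile(sig, _as_regulon(gene_set))
    return pd.DataFrame({"position": positions, "running_sum": values})
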