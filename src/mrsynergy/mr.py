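"""Master-regulator inference: regulon enrichment, NES ranking, DA/DE tables.

A candidate master regulator is a regulator whose targets are significantly
enriched among the most differentially expressed genes of a two-condition
signature.  Differential activity (DA) is the regulon's normalized enrichment
score; differential expression (DE) is the regulator's own signature score,
reported side by side because a regulator can change activity without
changing its own transcript level (and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrichment import EnrichmentResult, nes_by_gene_permutation
from .network import GeneSignature, Interactome
from .signatures import signature_de

__all__ = ["MRRecord", "infer_master_regulators", "mr_table"]


@dataclass
class MRRecord:
    """Per-regulator enrichment result on one signature."""

    regulator: str
    enrichment: EnrichmentResult
    da: float  # = NES ("differential activity")
    de: float  # regulator's own signature score, NaN if not represented
    fdr: float
    status: str  # "activated" | "repressed", by sign of NES

    @property
    def nes(self) -> float:
        return self.enrichment.nes

    @property
    def p_value(self) -> float:
        return self.enrichment.p_value


def infer_master_regulators(
    net: Interactome,
    sig: GeneSignature,
    n_perm: int = 1000,
    seed: int = 0,
    unweighted: bool = False,
) -> list[MRRecord]:
    """Rank every regulon of *net* by differential activity on *sig*.

    One record per regulon, sorted by descending NES, with Benjamini-Hochberg
    FDR attached across regulators.  The top-level seed is expanded
    deterministically into one child seed per regulon (in sorted regulator
    order), so results do not depend on iteration order and individual
    regulators can be re-run in isolation.
    """
    if np.all(sig._score_arr == 0):
        raise ValueError("degenerate signature: all scores are zero")
    regulators = sorted(net.regulons)
    children = np.random.SeedSequence(seed).spawn(len(regulators))
    records = []
    for regulator, child in zip(regulators, children):
        enr = nes_by_gene_permutation(
            sig, net[regulator], n_perm=n_perm, seed=child, unweighted=unweighted
        )
        records.append(
            MRRecord(
                regulator=regulator,
                enrichment=enr,
                da=enr.nes,
                de=signature_de(sig, regulator),
                fdr=np.nan,
                status="activated" if enr.nes >= 0 else "repressed",
            )
        )
    fdr = multipletests([r.p_value for r in records], method="fdr_bh")[1]
    for rec, q in zip(records, fdr):
        rec.fdr = float(q)
    records.sort(key=lambda r: (-r.nes, r.regulator))
    return records


def mr_table(records: list[MRRecord]) -> pd.DataFrame:
    """MR results as a regulator / es / nes / p / fdr / de / status table."""
    return pd.DataFrame(
        {
            "regulator": [r.regulator for r in records],
            "es": [r.enrichment.es for r in records],
            "nes": [r.nes for r in records],
            "p": [r.p_value for r in records],
            "fdr": [r.fdr for r in records],
            "de": [r.de for r in records],
            "status": [r.status for r in records],
        }
    )
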