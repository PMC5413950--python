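"""Pairwise master-regulator synergy via shared-target enrichment.

Two regulators are called synergistic when the enrichment of their *shared*
transcriptional targets in the signature is statistically stronger than the
enrichment of size-matched random subsets of either regulator's individual
targets.  The null is built by drawing, for each parent regulon, random
subsets the size of the shared set (excluding the shared targets whenever
the parent is large enough) and scoring each with the same two-tail ES; the
pooled empirical tail gives the synergy p-value.

Candidate pairs for experimental follow-up are then filtered the way the
discovery workflow does: keep synergistic pairs whose members are both
activated and at least one of which is strongly differentially expressed,
and rank them by the pair's combined DE.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import (
    _es_batch,
    _es_single,
    _increments,
    _regulon_arrays,
    sample_ranks_without_replacement,
)
from .network import GeneSignature, Interactome, Regulon, RegulatoryEdge, is_represented
from .mr import MRRecord

logger = logging.getLogger(__name__)

__all__ = ["MRPair", "shared_regulon", "synergy_test", "score_top_pairs", "select_candidate_pairs", "pair_table"]


@dataclass
class MRPair:
    """Synergy result for one unordered regulator pair."""

    regulators: tuple[str, str]  # sorted
    shared: Regulon
    shared_es: float
    shared_nes: float
    synergy_p: float
    n_null: int
    combined_de: float = float("nan")


def shared_regulon(r1: Regulon, r2: Regulon, mode_rule: str = "strict") -> Regulon | None:
    """Common targets of two regulons.

    Under ``strict`` only targets regulated with the same mode by both parents
    are kept; the shared edge takes that mode with weight = min of the parent
    weights.  Under ``any`` the mode and weight come from *r1* and
    disagreements are logged.  Returns None for an empty intersection
    (the caller filters; emptiness is not an error).
    """
    if mode_rule not in ("strict", "any"):
        raise ValueError(f"mode_rule must be 'strict' or 'any', got {mode_rule!r}")
    name = f"{r1.regulator}&{r2.regulator}"
    edges = []
    for t in r1.targets:
        if t not in r2:
            continue
        e1, e2 = r1[t], r2[t]
        if e1.mode != e2.mode:
            if mode_rule == "strict":
                continue
            logger.info("mode disagreement for shared target %s of %s", t, name)
        edges.append(
            RegulatoryEdge(name, t, e1.mode, min(e1.weight, e2.weight))
        )
    if not edges:
        return None
    return Regulon(name, edges)


def _parent_null(
    sig: GeneSignature,
    parent: Regulon,
    shared_targets: frozenset[str],
    size: int,
    n_null: int,
    rng: np.random.Generator,
    unweighted: bool,
) -> np.ndarray:
    """ES of *n_null* random size-matched subsets of one parent regulon."""
    targets, ranks, modes, weights = _regulon_arrays(sig, parent)
    keep = np.array([t not in shared_targets for t in targets])
    if keep.sum() >= size:  # exclusive of the shared set being scored
        ranks, modes, weights = ranks[keep], modes[keep], weights[keep]
    m = ranks.size
    if m < size:
        raise ValueError(
            f"parent {parent.regulator!r} has only {m} scorable targets < shared size {size}"
        )
    idx = sample_ranks_without_replacement(rng, n_null, size, m) - 1
    r = ranks[idx]
    pos = np.where(modes[idx] > 0, r, sig.n + 1 - r).astype(float)
    if unweighted:
        inc = np.ones_like(pos)
    else:
        inc = weights[idx] * sig._abs_arr[r - 1]
    order = np.argsort(pos, axis=1, kind="stable")
    return _es_batch(
        np.take_along_axis(pos, order, axis=1),
        np.take_along_axis(inc, order, axis=1),
        sig.n,
    )


def synergy_test(
    sig: GeneSignature,
    r1: Regulon,
    r2: Regulon,
    n_null: int = 500,
    seed: int | np.random.SeedSequence = 0,
    mode_rule: str = "strict",
    min_shared: int = 10,
    unweighted: bool = False,
) -> MRPair:
    """Shared-target synergy test for one regulator pair.

    synergy_p = (1 + #{null ES >= shared ES}) / (2*n_null + 1) over the pooled
    parent nulls.  The pair is put in canonical (sorted) order before any
    random draw, so the test is exactly symmetric in its arguments.
    Deterministic given *seed*.
    """
    if r2.regulator < r1.regulator:  # canonical ordering for exact symmetry
        r1, r2 = r2, r1
    shared = shared_regulon(r1, r2, mode_rule=mode_rule)
    size = 0 if shared is None else sum(t in sig for t in shared.targets)
    if shared is None or size < min_shared:
        raise ValueError(
            f"pair ({r1.regulator}, {r2.regulator}): {size} scorable shared "
            f"targets < min_shared={min_shared}"
        )
    _, ranks, modes, weights = _regulon_arrays(sig, shared)
    inc = _increments(sig, ranks, weights, unweighted)
    pos = np.where(modes > 0, ranks, sig.n + 1 - ranks).astype(float)
    es, _, _, _ = _es_single(pos, inc, sig.n)

    rng = np.random.default_rng(seed)
    shared_targets = frozenset(shared.targets)
    null = np.concatenate(
        [
            _parent_null(sig, parent, shared_targets, len(ranks), n_null, rng, unweighted)
            for parent in (r1, r2)
        ]
    )
    p = min(1.0, (1 + int(np.count_nonzero(null >= es))) / (2 * n_null + 1))
    sd = null.std(ddof=1)
    nes = (es - null.mean()) / sd if sd > 0 else np.nan
    return MRPair(
        regulators=(r1.regulator, r2.regulator),
        shared=shared,
        shared_es=float(es),
        shared_nes=float(nes),
        synergy_p=float(p),
        n_null=2 * n_null,
    )


def score_top_pairs(
    net: Interactome,
    sig: GeneSignature,
    mrs: list[MRRecord],
    top_k: int = 25,
    n_null: int = 500,
    seed: int = 0,
    mode_rule: str = "strict",
    min_shared: int = 10,
    unweighted: bool = False,
) -> list[MRPair]:
    """Synergy-test every pair among the top-K regulators by |DA|.

    Pairs whose shared regulon is smaller than *min_shared* are skipped (the
    subset null is too discrete below that); each tested pair gets a child
    seed derived deterministically from the pair's sorted names.
    """
    by_da = sorted(mrs, key=lambda r: (-abs(r.da), r.regulator))[:top_k]
    top = sorted(r.regulator for r in by_da)
    de_by_reg = {r.regulator: r.de for r in mrs}
    pairs = []
    candidates = list(itertools.combinations(top, 2))
    children = np.random.SeedSequence(seed).spawn(len(candidates))
    for (a, b), child in zip(candidates, children):
        shared = shared_regulon(net[a], net[b], mode_rule=mode_rule)
        if shared is None or sum(t in sig for t in shared.targets) < min_shared:
            continue
        pair = synergy_test(
            sig, net[a], net[b],
            n_null=n_null, seed=child, mode_rule=mode_rule,
            min_shared=min_shared, unweighted=unweighted,
        )
        des = [de_by_reg[a], de_by_reg[b]]
        finite = [d for d in des if is_represented(d)]
        pair.combined_de = max(finite) if finite else float("nan")
        pairs.append(pair)
    pairs.sort(key=lambda p: (p.synergy_p, p.regulators))
    return pairs


def select_candidate_pairs(
    pairs: list[MRPair],
    mrs: list[MRRecord],
    synergy_alpha: float = 0.05,
    de_threshold: float = 2.0,
    combine: str = "max",
) -> list[MRPair]:
    """Filter synergistic pairs down to experimentally actionable candidates.

    Keeps pairs with synergy_p <= synergy_alpha whose members are both
    activated and at least one of which is represented in the signature with
    DE >= de_threshold (overexpression is what a reprogramming experiment can
    deliver).  combined_de summarizes the pair by the max (default) or mean of
    the members' DE; the result is ranked by combined_de, descending.
    """
    if combine not in ("max", "mean"):
        raise ValueError(f"combine must be 'max' or 'mean', got {combine!r}")
    by_reg = {r.regulator: r for r in mrs}
    out = []
    for pair in pairs:
        try:
            members = [by_reg[g] for g in pair.regulators]
        except KeyError as exc:
            raise ValueError(f"unknown regulator in pair {pair.regulators}") from exc
        if pair.synergy_p > synergy_alpha:
            continue
        if any(m.status != "activated" for m in members):
            continue
        des = [m.de for m in members]
        represented = [d for d in des if is_represented(d)]
        if not represented or max(represented) < de_threshold:
            continue
        agg = max(represented) if combine == "max" else float(np.mean(represented))
        out.append(
            MRPair(
                regulators=pair.regulators,
                shared=pair.shared,
                shared_es=pair.shared_es,
                shared_nes=pair.shared_nes,
                synergy_p=pair.synergy_p,
                n_null=pair.n_null,
                combined_de=agg,
            )
        )
    out.sort(key=lambda p: (-p.combined_de, p.regulators))
    return out


def pair_table(pairs: list[MRPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "regA": [p.regulators[0] for p in pairs],
            "regB": [p.regulators[1] for p in pairs],
            "n_shared": [len(p.shared) for p in pairs],
            "shared_es": [p.shared_es for p in pairs],
            "synergy_p": [p.synergy_p for p in pairs],
            "combined_de": [p.combined_de for p in pairs],
        }
    )
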