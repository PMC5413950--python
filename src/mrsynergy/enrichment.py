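"""Weighted two-tail enrichment scores and gene-permutation significance.

The enrichment score (ES) is a weighted Kolmogorov-Smirnov-style running sum
over a signature ranked descending by score.  Each activated (mode +1) target
contributes a "hit" at its own rank; each repressed (mode -1) target
contributes at the rank it would occupy in the sign-inverted signature
(rank reflection), so a single signed ES captures both tails.  Hit increments
are proportional to edge weight x |signature score of the target|, normalized
to total mass 1; every non-hit position decrements by 1/(N - n_hits).  ES is
the maximum-magnitude excursion of the running sum, positive when targets
concentrate at the top.

Significance is assessed by gene permutation: target identities are
reassigned (keeping sizes, modes and weights) to genes drawn uniformly
without replacement from the signature universe.  NES standardizes the
observed ES by the null mean and standard deviation; the permutation p-value
is two-sided on |ES|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import GeneSignature, Regulon

__all__ = ["EnrichmentResult", "two_tail_enrichment_score", "nes_by_gene_permutation"]


@dataclass
class EnrichmentResult:
    """ES with its permutation-null standardization.

    Attributes
    ----------
    es : signed running-sum extremum
    nes : (es - mean(null)) / sd(null)
    p_value : (1 + #{|null ES| >= |ES|}) / (n_permutations + 1), two-sided
    leading_edge : targets contributing to the extremum excursion
    """

    es: float
    nes: float
    p_value: float
    n_permutations: int
    leading_edge: frozenset[str]


def _regulon_arrays(sig: GeneSignature, reg: Regulon):
    """Ranks, modes and weights of the regulon targets present in *sig*."""
    present = [i for i, t in enumerate(reg.targets) if t in sig]
    if not present:
        raise ValueError(
            f"regulon {reg.regulator!r} has no overlap with the signature"
        )
    targets = [reg.targets[i] for i in present]
    ranks = np.array([sig.rank_of(t) for t in targets], dtype=np.int64)
    modes = reg.modes[present].astype(np.int64)
    weights = reg.weights[present]
    return targets, ranks, modes, weights


def _increments(sig: GeneSignature, ranks: np.ndarray, weights, unweighted: bool):
    """Hit increments: weight x |score of the assigned gene| (its own rank)."""
    if unweighted:
        return np.ones_like(ranks, dtype=float)
    return weights * sig._abs_arr[ranks - 1]


def _es_batch(pos: np.ndarray, inc: np.ndarray, n_genes: int) -> np.ndarray:
    """Signed ES for each row of already-sorted hit positions.

    ``pos`` (B, n) holds effective positions sorted ascending per row and
    ``inc`` the aligned raw increments.  The running-sum extrema over all N
    positions occur just before or just after a hit, which is all this
    evaluates.
    """
    b, n = pos.shape
    total = inc.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("degenerate enrichment: total hit mass is zero")
    mass = inc / total
    cum = np.cumsum(mass, axis=1)
    # two targets may share an effective position (rank reflection); misses
    # are counted per *distinct* position, so track the distinct-count d_k
    new_pos = np.ones_like(pos, dtype=bool)
    new_pos[:, 1:] = pos[:, 1:] != pos[:, :-1]
    d = np.cumsum(new_pos, axis=1)
    denom = max(n_genes - n, 1)
    after = cum - (pos - d) / denom
    before = after - mass
    mx = after.max(axis=1)
    mn = np.minimum(before.min(axis=1), 0.0)
    # exact |max| == |min| ties resolve positive (tolerance beats fp noise)
    return np.where(mx >= -mn - 1e-12, mx, mn)


def _es_single(pos: np.ndarray, inc: np.ndarray, n_genes: int):
    """ES plus the index of the extremum hit (for the leading edge)."""
    order = np.argsort(pos, kind="stable")
    pos, inc = pos[order], inc[order]
    n = pos.size
    if inc.sum() <= 0:
        raise ValueError("degenerate enrichment: total hit mass is zero")
    mass = inc / inc.sum()
    cum = np.cumsum(mass)
    new_pos = np.ones_like(pos, dtype=bool)
    new_pos[1:] = pos[1:] != pos[:-1]
    d = np.cumsum(new_pos)
    denom = max(n_genes - n, 1)
    after = cum - (pos - d) / denom
    before = after - mass
    mx, mn = after.max(), min(before.min(), 0.0)
    if mx >= -mn - 1e-12:  # ties resolve positive, robust to fp noise
        return float(mx), order, int(after.argmax()), True
    return float(mn), order, int(before.argmin()), False


def two_tail_enrichment_score(
    sig: GeneSignature, reg: Regulon, unweighted: bool = False
) -> float:
    """Signed two-tail ES of a regulon on a signature.

    Targets absent from the signature are dropped; an empty overlap is an
    error.  With ``unweighted=True`` all hit increments are equal (classic
    unweighted KS statistic), ignoring both edge weights and score magnitudes.
    """
    _, ranks, modes, weights = _regulon_arrays(sig, reg)
    inc = _increments(sig, ranks, weights, unweighted)
    pos = np.where(modes > 0, ranks, sig.n + 1 - ranks).astype(float)
    es, _, _, _ = _es_single(pos, inc, sig.n)
    return es


def sample_ranks_without_replacement(
    rng: np.random.Generator, n_draws: int, n: int, n_genes: int
) -> np.ndarray:
    """(n_draws, n) ranks drawn uniformly without replacement from 1..n_genes.

    Rejection sampling of whole rows when collisions are rare, argpartition of
    a random matrix otherwise; both are exactly uniform over subsets.
    """
    if n > n_genes:
        raise ValueError(f"cannot draw {n} distinct ranks from {n_genes}")
    if n == n_genes:
        return np.tile(np.arange(1, n_genes + 1), (n_draws, 1))
    if n * (n - 1) / (2 * n_genes) > 0.4:
        idx = np.argpartition(rng.random((n_draws, n_genes)), n - 1, axis=1)[:, :n]
        return idx + 1
    r = rng.integers(1, n_genes + 1, size=(n_draws, n))
    while True:
        s = np.sort(r, axis=1)
        bad = (np.diff(s, axis=1) == 0).any(axis=1)
        if not bad.any():
            return r
        r[bad] = rng.integers(1, n_genes + 1, size=(int(bad.sum()), n))


def _null_es(
    sig: GeneSignature,
    modes: np.ndarray,
    weights: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    unweighted: bool,
) -> np.ndarray:
    """Null ES values from gene permutations preserving modes and weights."""
    n = modes.size
    r = sample_ranks_without_replacement(rng, n_perm, n, sig.n)
    pos = np.where(modes[None, :] > 0, r, sig.n + 1 - r).astype(float)
    if unweighted:
        inc = np.ones_like(pos)
    else:
        inc = weights[None, :] * sig._abs_arr[r - 1]
    order = np.argsort(pos, axis=1, kind="stable")
    pos = np.take_along_axis(pos, order, axis=1)
    inc = np.take_along_axis(inc, order, axis=1)
    return _es_batch(pos, inc, sig.n)


def nes_by_gene_permutation(
    sig: GeneSignature,
    reg: Regulon,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    unweighted: bool = False,
) -> EnrichmentResult:
    """ES, NES and two-sided permutation p for one regulon on one signature.

    Deterministic given *seed*.  The p-value floor is 1/(n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    targets, ranks, modes, weights = _regulon_arrays(sig, reg)
    inc = _increments(sig, ranks, weights, unweighted)
    pos = np.where(modes > 0, ranks, sig.n + 1 - ranks).astype(float)
    es, order, extremum, positive = _es_single(pos, inc, sig.n)
    sorted_targets = [targets[i] for i in order]
    if positive:
        leading = frozenset(sorted_targets[: extremum + 1])
    else:
        leading = frozenset(sorted_targets[extremum:])

    rng = np.random.default_rng(seed)
    null = _null_es(sig, modes, weights, n_perm, rng, unweighted)
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate signature: permutation null has zero spread")
    nes = (es - null.mean()) / sd
    p = (1 + int(np.count_nonzero(np.abs(null) >= abs(es)))) / (n_perm + 1)
    return EnrichmentResult(es, float(nes), float(p), n_perm, leading)


def running_sum_profile(sig: GeneSignature, reg: Regulon, unweighted: bool = False):
    """Full N-step running sum of the ES walk, for plot export.

    Returns (positions 1..N, running-sum values), computed position by
    position; intended for rendering enrichment panels, not for scoring.
    """
    _, ranks, modes, weights = _regulon_arrays(sig, reg)
    inc = _increments(sig, ranks, weights, unweighted)
    pos = np.where(modes > 0, ranks, sig.n + 1 - ranks)
    hit = np.zeros(sig.n)
    np.add.at(hit, pos - 1, inc / inc.sum())
    miss = 1.0 / max(sig.n - len(pos), 1)
    steps = np.where(hit > 0, hit, -miss)
    return np.arange(1, sig.n + 1), np.cumsum(steps)
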