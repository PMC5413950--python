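import math
from collections import defaultdict

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrsynergy import ExpressionMatrix, GeneSignature, Regulon, RegulatoryEdge

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)


def oracle_es(scores: dict[str, float], regulon: list[tuple[str, int, float]]) -> float:
    """Brute-force two-tail running-sum ES, walking every signature position."""
    order = sorted(scores, key=lambda g: (-scores[g], g))
    rank = {g: i + 1 for i, g in enumerate(order)}
    n_genes = len(order)
    mass = defaultdict(float)
    total = 0.0
    n_hits = 0
    for gene, mode, weight in regulon:
        if gene not in rank:
            continue
        r = rank[gene]
        pos = r if mode == 1 else n_genes + 1 - r
        inc = weight * abs(scores[gene])
        mass[pos] += inc
        total += inc
        n_hits += 1
    assert n_hits > 0 and total > 0
    miss = 1.0 / (n_genes - n_hits) if n_genes > n_hits else 0.0
    running = 0.0
    hi, lo = -math.inf, math.inf
    for p in range(1, n_genes + 1):
        if p in mass:
            running += mass[p] / total
        else:
            running -= miss
        hi = max(hi, running)
        lo = min(lo, running)
    return hi if hi >= -lo - 1e-12 else lo  # ties resolve positive


def oracle_fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Exact-integer minimum-likelihood two-tailed Fisher p by enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    num_obs = math.comb(r1, a) * math.comb(r2, c)
    total = math.comb(n, c1)
    acc = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        num_k = math.comb(r1, k) * math.comb(r2, c1 - k)
        # same 1e-7 relative tolerance on "point prob <= observed", exact ints
        if num_k * 10**7 <= num_obs * (10**7 + 1):
            acc += num_k
    return acc / total


# ---------------------------------------------------------------------------
# small shared fixtures


@pytest.fixture
def ladder_signature() -> GeneSignature:
    """10-gene signature with scores 10, 9, ..., 1 (g01 highest)."""
    return GeneSignature({f"g{i:02d}": 11 - i for i in range(1, 11)})


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    df = pd.DataFrame(
        {"s1": [1.0, 4.0], "s2": [2.0, 5.0], "s3": [4.0, 1.0], "s4": [5.0, 2.0]},
        index=["gA", "gB"],
    )
    return ExpressionMatrix(df, {"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


def make_regulon(regulator: str, edges_by_target: dict[str, tuple[int, float]]) -> Regulon:
    return Regulon(
        regulator,
        [RegulatoryEdge(regulator, t, mode, w) for t, (mode, w) in edges_by_target.items()],
    )


@pytest.fixture
def interactome_tsv(tmp_path):
    path = tmp_path / "net.tsv"
    path.write_text(
        "# regulator\ttarget\tmode\tweight\n"
        "A\tx\t+1\t0.9\n"
        "A\ty\t-1\t0.8\n"
        "B\tx\t+1\t1.0\n"
    )
    return path


def random_signature(rng: np.random.Generator, n: int) -> GeneSignature:
    return GeneSignature({f"n{i:05d}": x for i, x in enumerate(rng.normal(size=n))})


def random_regulon(
    rng: np.random.Generator, sig: GeneSignature, size: int, name: str = "RND"
) -> Regulon:
    genes = rng.choice(np.asarray(sig.genes), size=size, replace=False)
    return Regulon(
        name,
        [
            RegulatoryEdge(
                name, g, 1 if rng.random() < 0.7 else -1, float(rng.uniform(0.5, 1.0))
            )
            for g in genes
        ],
    )
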