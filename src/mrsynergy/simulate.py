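"""Synthetic regulatory networks, expression experiments and graft replicates.

The generators provide every statistical structure the inference pipeline
assumes, so the whole workflow can be exercised and validated without any
external download:

* a regulator->target interactome with disjoint-by-default regulon target
  blocks, one planted *synergistic* pair sharing a block of targets, and
  optional "decoy" overlapping pairs that share targets without any
  interaction effect;
* a two-condition expression experiment (defaults: 3 samples per condition,
  unit Gaussian noise on a log-like scale) in which targets of planted active
  regulators shift by mode x weight x effect_size, and the shared targets of
  the planted pair gain an *additional* interaction shift only when both
  members are active;
* binomial graft outcomes at specified per-group efficiencies, giving the
  replicate structure the experimental synergy t-test requires;
* the published renal-grafting count table used throughout the graft
  statistics (10 groups, verbatim counts).

Every generator is a pure function of its configuration and seed; repeated
calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ExpressionMatrix, Interactome, Regulon, RegulatoryEdge
from .grafts import GraftGroup

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "simulate_interactome",
    "simulate_expression",
    "simulate_graft_replicates",
    "table1_fixture",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the discovery setting the pipeline is validated under:
    100 regulators with 20-50 targets each, 5 planted active regulators at an
    effect of 2 noise standard deviations, one planted synergistic pair
    sharing 20 targets, and 3 biological replicates per condition.
    """

    n_regulators: int = 100
    targets_per_regulon: tuple[int, int] = (20, 50)
    n_background_genes: int = 500
    n_active_regulators: int = 5
    n_shared: int = 20
    plant_interaction: bool = True
    n_decoy_pairs: int = 5
    effect_size: float = 2.0
    interaction_effect: float | None = None  # default: = effect_size
    noise_sd: float = 1.0
    activation_prob: float = 0.7
    weight_range: tuple[float, float] = (0.5, 1.0)
    samples_per_condition: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.targets_per_regulon
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid targets_per_regulon range {self.targets_per_regulon}")
        if self.plant_interaction and self.n_shared > lo:
            raise ValueError(
                f"n_shared={self.n_shared} exceeds the minimum regulon size {lo}"
            )
        if self.samples_per_condition < 2:
            raise ValueError("samples_per_condition must be >= 2")
        if self.plant_interaction and self.n_active_regulators < 2:
            raise ValueError("an interaction pair needs >= 2 active regulators")

    @property
    def interaction(self) -> float:
        return self.effect_size if self.interaction_effect is None else self.interaction_effect


@dataclass
class PlantedTruth:
    """Ground truth of a simulated study, for recovery experiments."""

    active_regulators: dict[str, int]  # regulator -> activity sign in condition B
    synergistic_pair: tuple[str, str] | None
    shared_targets: tuple[str, ...]
    decoy_pairs: list[tuple[str, str]] = field(default_factory=list)
    expected_shift: dict[str, float] = field(default_factory=dict)


def simulate_interactome(cfg: SimulationConfig) -> tuple[Interactome, PlantedTruth]:
    """Build a synthetic interactome with planted active and synergistic structure.

    Regulon target sets are disjoint blocks of a shuffled target pool, except
    that the planted interaction pair (the first two active regulators) and
    each decoy pair share exactly ``cfg.n_shared`` targets with matching
    modes.  Modes are +1 with probability ``activation_prob``; weights are
    Uniform over ``weight_range``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.targets_per_regulon
    regs = [f"R{i:04d}" for i in range(1, cfg.n_regulators + 1)]
    sizes = rng.integers(lo, hi + 1, size=cfg.n_regulators)
    pool_size = int(sizes.sum())
    pool = [f"G{i:05d}" for i in range(1, pool_size + 1)]
    pool = list(np.array(pool)[rng.permutation(pool_size)])

    blocks: dict[str, list[str]] = {}
    start = 0
    for reg, size in zip(regs, sizes):
        blocks[reg] = pool[start : start + int(size)]
        start += int(size)

    actives = regs[: cfg.n_active_regulators]
    truth = PlantedTruth(
        active_regulators={r: 1 for r in actives},
        synergistic_pair=None,
        shared_targets=(),
    )

    def overlap_pair(a: str, b: str) -> tuple[str, ...]:
        # replace the first n_shared targets of b with a's first n_shared
        shared = tuple(blocks[a][: cfg.n_shared])
        blocks[b] = list(shared) + blocks[b][cfg.n_shared :]
        return shared

    shared_modes: dict[str, int] = {}
    if cfg.plant_interaction:
        pair = (actives[0], actives[1])
        truth.synergistic_pair = pair
        truth.shared_targets = overlap_pair(*pair)

    decoy_candidates = regs[cfg.n_active_regulators :]
    for i in range(min(cfg.n_decoy_pairs, len(decoy_candidates) // 2)):
        a, b = decoy_candidates[2 * i], decoy_candidates[2 * i + 1]
        if min(len(blocks[a]), len(blocks[b])) < cfg.n_shared + 1:
            continue
        overlap_pair(a, b)
        truth.decoy_pairs.append((a, b))

    regulons = []
    for reg in regs:
        edges = []
        for t in blocks[reg]:
            if t in shared_modes:
                mode = shared_modes[t]
            else:
                mode = 1 if rng.random() < cfg.activation_prob else -1
                shared_modes[t] = mode  # shared targets keep matching modes
            w = float(rng.uniform(*cfg.weight_range))
            edges.append(RegulatoryEdge(reg, t, mode, w))
        regulons.append(Regulon(reg, edges))
    net = Interactome(regulons)

    # pad the gene universe with unregulated background genes by storing them
    # on the truth; expression simulation includes them as pure noise
    truth.expected_shift = _expected_shift(net, truth, cfg, joint=True)
    return net, truth


def _background_genes(cfg: SimulationConfig) -> list[str]:
    return [f"B{i:05d}" for i in range(1, cfg.n_background_genes + 1)]


def _expected_shift(
    net: Interactome, truth: PlantedTruth, cfg: SimulationConfig, joint: bool
) -> dict[str, float]:
    """Condition-B mean shift per gene implied by the planted activities."""
    active = dict(truth.active_regulators)
    if not joint and truth.synergistic_pair is not None:
        active.pop(truth.synergistic_pair[1], None)  # second member silent
    shift: dict[str, float] = {}
    for reg, sign in active.items():
        shift[reg] = shift.get(reg, 0.0) + sign * cfg.effect_size
        for e in net[reg].edges:
            shift[e.target] = shift.get(e.target, 0.0) + sign * e.mode * e.weight * cfg.effect_size
    if joint and truth.synergistic_pair is not None:
        a, _ = truth.synergistic_pair
        for t in truth.shared_targets:
            e = net[a][t]
            shift[t] = shift.get(t, 0.0) + e.mode * cfg.interaction
    return shift


def _one_matrix(
    universe: list[str],
    shift: dict[str, float],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_prefix: str = "",
) -> ExpressionMatrix:
    spc = cfg.samples_per_condition
    samples = [f"{sample_prefix}A{i+1}" for i in range(spc)] + [
        f"{sample_prefix}B{i+1}" for i in range(spc)
    ]
    values = rng.normal(0.0, cfg.noise_sd, size=(len(universe), 2 * spc))
    mu = np.array([shift.get(g, 0.0) for g in universe])
    values[:, spc:] += mu[:, None]
    df = pd.DataFrame(values, index=universe, columns=samples)
    conditions = {s: ("A" if s.startswith(f"{sample_prefix}A") else "B") for s in samples}
    return ExpressionMatrix(df, conditions)


def simulate_expression(
    net: Interactome,
    truth: PlantedTruth,
    cfg: SimulationConfig,
    design: str = "joint_active",
):
    """Two-condition expression data driven by the planted regulator activities.

    Designs
    -------
    ``joint_active``
        All planted regulators are active in condition B; the shared targets
        of the synergistic pair gain the interaction shift on top of their
        main effects.
    ``single_active``
        The second member of the pair is silenced and no interaction applies:
        shared targets shift by parent main effects only.
    ``concordant_pair``
        Returns *two* matrices with independent noise from the same
        joint-active truth, for signature-concordance (GSEA) experiments.
    """
    if design not in ("joint_active", "single_active", "concordant_pair"):
        raise ValueError(f"unknown design {design!r}")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    universe = sorted(net.gene_universe) + _background_genes(cfg)
    if design == "concordant_pair":
        shift = _expected_shift(net, truth, cfg, joint=True)
        return (
            _one_matrix(universe, shift, cfg, rng, "r1_"),
            _one_matrix(universe, shift, cfg, rng, "r2_"),
        )
    shift = _expected_shift(net, truth, cfg, joint=design == "joint_active")
    return _one_matrix(universe, shift, cfg, rng)


def simulate_graft_replicates(
    efficiencies: dict[str, float],
    grown_per_replicate: int = 20,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial graft outcomes per replicate at the specified percent rates.

    Returns a ``label / replicate / grown / positive`` table, the
    replicate-level input the experimental synergy t-test requires.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for label in sorted(efficiencies):
        rate = efficiencies[label]
        if not 0 <= rate <= 100:
            raise ValueError(f"{label!r}: efficiency must be in [0, 100]%, got {rate}")
        positives = rng.binomial(grown_per_replicate, rate / 100.0, size=n_replicates)
        for i, pos in enumerate(positives, start=1):
            rows.append((label, i, grown_per_replicate, int(pos)))
    return pd.DataFrame(rows, columns=["label", "replicate", "grown", "positive"])


#: verbatim counts of the published renal-grafting summary table
_TABLE1_ROWS = [
    ("UGM only", 5, 0, 0),
    ("MEFs", 5, 0, 0),
    ("MEFs+Nkx3.1+AR+Foxa1", 10, 0, 0),
    ("iEpt", 22, 18, 1),
    ("iEpt+Nkx3.1", 8, 3, 0),
    ("iEpt+Foxa1", 4, 4, 0),
    ("iEpt+AR", 10, 9, 3),
    ("iEpt+Nkx3.1+Foxa1", 13, 10, 4),
    ("iEpt+Nkx3.1+AR", 21, 13, 6),
    ("iEpt+Nkx3.1+AR+Foxa1", 56, 46, 18),
]


def table1_fixture() -> list[GraftGroup]:
    """The published renal grafting assay counts, one GraftGroup per row."""
    return [GraftGroup(label, p, g, pos) for label, p, g, pos in _TABLE1_ROWS]


#: which master-regulator factors each grafted group expresses
TABLE1_FACTORS: dict[str, frozenset[str]] = {
    "iEpt": frozenset(),
    "iEpt+Nkx3.1": frozenset({"Nkx3.1"}),
    "iEpt+Foxa1": frozenset({"Foxa1"}),
    "iEpt+AR": frozenset({"AR"}),
    "iEpt+Nkx3.1+Foxa1": frozenset({"Nkx3.1", "Foxa1"}),
    "iEpt+Nkx3.1+AR": frozenset({"Nkx3.1", "AR"}),
    "iEpt+Nkx3.1+AR+Foxa1": frozenset({"Nkx3.1", "AR", "Foxa1"}),
}
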