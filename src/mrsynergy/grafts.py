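"""Graft-efficiency statistics: Fisher contrasts and the log-linear synergy model.

A grafting experiment reports, per group, how many grafts were performed, how
many grew, and how many contained the tissue of interest.  Efficiency is the
percentage of positive grafts (among grown grafts by default, which is what
the published percentages use).  Group-versus-control contrasts use the
two-tailed Fisher exact test.

Experimental synergy is assessed with a log-linear additive model: the log
efficiency of each single-factor group minus the log efficiency of the
control gives a per-factor slope; summing slopes over a factor combination
(optionally on top of an observed pair group) predicts the combination's
"additive" efficiency.  A one-sample, one-tailed t-test of replicate log
efficiencies against the log prediction asks whether the observed combined
effect exceeds additivity — the experimental definition of synergy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "GraftGroup",
    "ContingencyTable",
    "EfficiencyModel",
    "SynergyTestResult",
    "efficiency",
    "fisher_exact_two_tailed",
    "contingency_vs_control",
    "fit_additive_model",
    "predict_additive",
    "synergy_t_test",
]

#: relative tolerance for "point probability <= observed" in the two-tailed sum
_FISHER_RELTOL = 1e-7


@dataclass(frozen=True)
class GraftGroup:
    """One grafting condition: counts of performed / grown / positive grafts."""

    label: str
    performed: int
    grown: int
    positive: int

    def __post_init__(self) -> None:
        if not 0 <= self.positive <= self.grown <= self.performed:
            raise ValueError(
                f"{self.label!r}: need 0 <= positive <= grown <= performed, "
                f"got {self.positive}/{self.grown}/{self.performed}"
            )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows are groups, columns positive/negative outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")


@dataclass
class EfficiencyModel:
    """Log-linear additive model of grafting efficiency.

    ``base_log_eff`` is the log efficiency (percent scale) of the control
    group; ``slopes[f]`` is the log-efficiency increment of factor *f* over
    control; ``group_log_eff`` keeps every fitted group's log efficiency so a
    prediction can also start from an observed pair group.  Zero efficiencies
    are replaced by a strictly positive floor before taking logs.
    """

    base_log_eff: float
    slopes: dict[str, float]
    floor: dict[str, float]  # per-group floor actually applied (percent)
    group_log_eff: dict[str, float] = field(default_factory=dict)
    slope_groups: dict[str, str] = field(default_factory=dict)  # factor -> group label
    denominator: str = "grown"

    def floor_factors(self) -> set[str]:
        """Factors whose defining single-factor group had zero efficiency."""
        return {f for f, label in self.slope_groups.items() if label in self.floor}


@dataclass
class SynergyTestResult:
    predicted_additive_eff: float
    observed_effs: list[float]
    t_stat: float
    p_one_tailed: float
    df: int


def efficiency(g: GraftGroup, denominator: str = "grown") -> float:
    """Percent of positive grafts, among grown (default) or performed grafts."""
    if denominator not in ("grown", "performed"):
        raise ValueError(f"denominator must be 'grown' or 'performed', got {denominator!r}")
    denom = g.grown if denominator == "grown" else g.performed
    if denom == 0:
        raise ValueError(f"{g.label!r}: denominator {denominator!r} count is zero")
    return 100.0 * g.positive / denom


def fisher_exact_two_tailed(t: ContingencyTable) -> float:
    """Two-tailed Fisher exact p by full enumeration with log-factorials.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability is <= that of the observed table (with
    relative tolerance 1e-7) — the minimum-likelihood definition.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # single feasible configuration
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)

    def log_comb(m, j):
        return gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1)

    logp = log_comb(r1, k) + log_comb(r2, c1 - k) - log_comb(n, c1)
    log_obs = float(logp[k == a][0])
    keep = logp <= log_obs + np.log1p(_FISHER_RELTOL)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def contingency_vs_control(
    group: GraftGroup, control: GraftGroup, denominator: str = "grown"
) -> ContingencyTable:
    """Positive/negative contingency table contrasting one group with control."""
    def counts(g: GraftGroup) -> tuple[int, int]:
        denom = g.grown if denominator == "grown" else g.performed
        return g.positive, denom - g.positive

    a, b = counts(group)
    c, d = counts(control)
    return ContingencyTable(a, b, c, d)


def _floored_log_eff(
    g: GraftGroup, denominator: str, floor: float | str
) -> tuple[float, float | None]:
    """Log efficiency with the zero-efficiency floor; returns (log_eff, floor_used)."""
    eff = efficiency(g, denominator)
    if eff > 0:
        return float(np.log(eff)), None
    denom = g.grown if denominator == "grown" else g.performed
    floor_pct = 100.0 * 0.5 / denom if floor == "half-count" else float(floor)
    if not 0 < floor_pct < 100:
        raise ValueError(f"floor must give a rate in (0, 100)%, got {floor_pct}")
    logger.info("group %r has zero efficiency; floored at %.4g%%", g.label, floor_pct)
    return float(np.log(floor_pct)), floor_pct


def fit_additive_model(
    groups: list[GraftGroup],
    control_label: str,
    factor_map: dict[str, frozenset[str] | set[str]],
    floor: float | str = "half-count",
    denominator: str = "grown",
) -> EfficiencyModel:
    """Fit per-factor log-efficiency slopes from control and single-factor groups.

    ``factor_map`` maps each group label to the set of factors it expresses
    (the control maps to the empty set).  The slope of factor *f* is
    log(eff of the {f} group) - log(eff of control); groups expressing several
    factors are recorded (for clause-(ii) predictions that start from a pair
    group) but contribute no slope.
    """
    by_label = {g.label: g for g in groups}
    if control_label not in by_label:
        raise ValueError(f"control group {control_label!r} missing from input")
    # groups with no grown (or performed) grafts carry no efficiency at all
    for label in list(by_label):
        g = by_label[label]
        if (g.grown if denominator == "grown" else g.performed) == 0:
            if label == control_label:
                raise ValueError(f"control group {control_label!r} has zero {denominator} grafts")
            logger.info("dropping group %r: zero %s grafts", label, denominator)
            del by_label[label]
    floors: dict[str, float] = {}

    def log_eff(label: str) -> float:
        val, used = _floored_log_eff(by_label[label], denominator, floor)
        if used is not None:
            floors[label] = used
        return val

    base = log_eff(control_label)
    group_log_eff = {label: log_eff(label) for label in by_label}
    slopes = {}
    slope_groups = {}
    for label, factors in factor_map.items():
        factors = frozenset(factors)
        if len(factors) == 1 and label in by_label:
            (f,) = factors
            slopes[f] = group_log_eff[label] - base
            slope_groups[f] = label
    return EfficiencyModel(
        base_log_eff=base,
        slopes=slopes,
        floor=floors,
        group_log_eff=group_log_eff,
        slope_groups=slope_groups,
        denominator=denominator,
    )


def predict_additive(
    model: EfficiencyModel,
    factors: list[str] | tuple[str, ...],
    base_group: str | None = None,
) -> float:
    """Predicted additive efficiency (%) for a factor combination.

    Clause (i): sum the named single-factor slopes over the control base.
    Clause (ii): pass an observed pair group as *base_group* and add the
    slope(s) of the remaining single factor(s) on top of it.
    """
    missing = [f for f in factors if f not in model.slopes]
    if missing:
        raise ValueError(f"no fitted slope for factor(s) {missing}")
    if base_group is None:
        base = model.base_log_eff
    else:
        if base_group not in model.group_log_eff:
            raise ValueError(f"unknown base group {base_group!r}")
        base = model.group_log_eff[base_group]
    return float(min(100.0, np.exp(base + sum(model.slopes[f] for f in factors))))


def synergy_t_test(observed: list[float], predicted: float) -> SynergyTestResult:
    """One-sample, one-tailed t-test of replicate log efficiencies vs prediction.

    Tests whether log(observed) exceeds log(predicted) (observed > additive,
    i.e. synergy).  Requires >= 2 replicate-level efficiencies; the pooled
    counts of a summary table cannot drive this test.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError(
            "need >= 2 replicate efficiencies; supply replicate-level data, "
            "not a pooled summary row"
        )
    if (obs <= 0).any() or predicted <= 0:
        raise ValueError("efficiencies must be > 0 on the log scale (apply a floor first)")
    diffs = np.log(obs) - np.log(predicted)
    if np.allclose(diffs.std(ddof=1), 0) and np.allclose(diffs.mean(), 0):
        t_stat, p = 0.0, 0.5  # all replicates exactly at the prediction
    else:
        res = stats.ttest_1samp(np.log(obs), np.log(predicted), alternative="greater")
        t_stat, p = float(res.statistic), float(res.pvalue)
    return SynergyTestResult(
        predicted_additive_eff=float(predicted),
        observed_effs=[float(x) for x in obs],
        t_stat=t_stat,
        p_one_tailed=p,
        df=int(obs.size - 1),
    )
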