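"""Domain types and I/O for regulons, interactomes, expression matrices and signatures.

A regulatory network ("interactome") is a collection of regulons: one
transcriptional regulator plus its target genes, each target carrying a mode
of regulation (+1 activated, -1 repressed) and a confidence weight in (0, 1].
Gene identifiers are opaque, case-sensitive symbols; cross-species use is
supported only through an explicit caller-supplied synonym table applied at
load time.

File formats are plain TSV throughout:

* interactome: ``regulator<TAB>target<TAB>mode<TAB>weight`` with ``#`` comments;
* expression:  genes x samples, first column gene ids, header row sample ids;
* condition map: ``sample<TAB>condition``;
* signature:   ``gene<TAB>score<TAB>rank``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: distinguished value for "gene not represented on the platform / signature"
NOT_REPRESENTED = float("nan")

_MODE_ALIASES = {
    "+1": 1, "1": 1, "+": 1, "activation": 1, "activated": 1, "a": 1,
    "-1": -1, "−1": -1, "-": -1, "repression": -1, "repressed": -1, "r": -1,
}


def is_represented(value: float) -> bool:
    """True unless *value* is the NOT_REPRESENTED marker."""
    return not (isinstance(value, float) and np.isnan(value))


@dataclass(frozen=True)
class RegulatoryEdge:
    """One regulator->target interaction with mode and confidence weight."""

    regulator: str
    target: str
    mode: int
    weight: float

    def __post_init__(self) -> None:
        if not self.regulator or not self.target:
            raise ValueError("gene symbols must be non-empty")
        if self.mode not in (1, -1):
            raise ValueError(f"mode must be +1 or -1, got {self.mode!r}")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"weight must lie in (0, 1], got {self.weight!r}")
        if self.regulator == self.target:
            logger.warning("self-loop edge %s -> %s", self.regulator, self.target)


class Regulon:
    """A regulator together with its mode-signed, weighted target list."""

    def __init__(self, regulator: str, edges: Sequence[RegulatoryEdge]):
        edges = list(edges)
        if not edges:
            raise ValueError(f"regulon {regulator!r} must have >= 1 target")
        targets = [e.target for e in edges]
        if len(set(targets)) != len(targets):
            dup = sorted({t for t in targets if targets.count(t) > 1})
            raise ValueError(f"regulon {regulator!r} has duplicate targets {dup}")
        for e in edges:
            if e.regulator != regulator:
                raise ValueError(
                    f"edge regulator {e.regulator!r} does not match regulon {regulator!r}"
                )
        self.regulator = regulator
        self.edges = tuple(sorted(edges, key=lambda e: e.target))
        self._by_target = {e.target: e for e in self.edges}

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(e.target for e in self.edges)

    @property
    def modes(self) -> np.ndarray:
        return np.array([e.mode for e in self.edges], dtype=np.int8)

    @property
    def weights(self) -> np.ndarray:
        return np.array([e.weight for e in self.edges], dtype=float)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, target: str) -> bool:
        return target in self._by_target

    def __getitem__(self, target: str) -> RegulatoryEdge:
        return self._by_target[target]

    def __eq__(self, other) -> bool:
        return isinstance(other, Regulon) and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Regulon({self.regulator!r}, {len(self)} targets)"


class Interactome:
    """A keyed collection of regulons plus the union gene universe."""

    def __init__(self, regulons: Iterable[Regulon]):
        self.regulons: dict[str, Regulon] = {}
        for reg in regulons:
            if reg.regulator in self.regulons:
                raise ValueError(f"duplicate regulon for {reg.regulator!r}")
            self.regulons[reg.regulator] = reg
        universe: set[str] = set()
        for reg in self.regulons.values():
            universe.add(reg.regulator)
            universe.update(reg.targets)
        self.gene_universe = frozenset(universe)

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self):
        return iter(self.regulons.values())

    def __getitem__(self, regulator: str) -> Regulon:
        return self.regulons[regulator]

    def __contains__(self, regulator: str) -> bool:
        return regulator in self.regulons

    def edge_set(self) -> frozenset[RegulatoryEdge]:
        return frozenset(e for r in self for e in r.edges)


class ExpressionMatrix:
    """Gene-by-sample expression values with per-sample condition labels."""

    def __init__(self, values: pd.DataFrame, conditions: Mapping[str, str]):
        if values.index.has_duplicates:
            dup = sorted(values.index[values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dup}")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if values.isna().any().any():
            gene = values.index[values.isna().any(axis=1)][0]
            sample = values.columns[values.isna().any(axis=0)][0]
            raise ValueError(f"missing value at gene {gene!r}, sample {sample!r}")
        missing = [s for s in values.columns if s not in conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        self.values = values.astype(float)
        self.conditions = pd.Series({s: conditions[s] for s in values.columns})

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]

    def condition_counts(self) -> dict[str, int]:
        return self.conditions.value_counts().to_dict()


class GeneSignature:
    """A genome-wide differential-expression score per gene and its ranking.

    Scores are signed statistics (positive = up in condition B relative to A).
    The canonical ranking is a dense 1..N permutation, descending by score
    with ties broken by gene id so that every downstream computation is
    deterministic; tie-averaged ranks are available via :meth:`average_ranks`.
    """

    def __init__(self, scores: Mapping[str, float] | pd.Series):
        s = pd.Series(dict(scores), dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
        if s.empty:
            raise ValueError("signature must contain >= 1 gene")
        if s.index.has_duplicates:
            raise ValueError("duplicate gene ids in signature")
        if not np.isfinite(s.to_numpy()).all():
            bad = s.index[~np.isfinite(s.to_numpy())].tolist()
            raise ValueError(f"non-finite signature scores for {bad}")
        order = sorted(s.index, key=lambda g: (-s[g], g))
        self.scores = s.loc[order]
        self.ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
        # rank-ordered arrays and an O(1) lookup for the enrichment engine
        self._score_arr = self.scores.to_numpy()
        self._abs_arr = np.abs(self._score_arr)
        self._rank_of = {g: i + 1 for i, g in enumerate(order)}

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    def __contains__(self, gene: str) -> bool:
        return gene in self._rank_of

    def rank_of(self, gene: str) -> int:
        return self._rank_of[gene]

    def score_of(self, gene: str) -> float:
        """Score of *gene*, or the NOT_REPRESENTED marker if absent."""
        if gene not in self._rank_of:
            return NOT_REPRESENTED
        return float(self.scores[gene])

    def average_ranks(self) -> pd.Series:
        """Tie-averaged descending ranks (not necessarily integers)."""
        return self.scores.rank(ascending=False, method="average")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneSignature)
            and self.scores.index.equals(other.scores.index)
            and np.array_equal(self._score_arr, other._score_arr)
        )


@dataclass
class SizeFactors:
    """Per-sample positive scale factors from median-of-ratios normalization."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be strictly positive")


# ---------------------------------------------------------------------------
# readers / writers


def _apply_synonyms(symbol: str, synonyms: Mapping[str, str] | None) -> str:
    if synonyms is None:
        return symbol
    return synonyms.get(symbol, symbol)


def load_synonym_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``old<TAB>new`` mapping applied to gene symbols at load."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"synonym table must have 2 columns, got {df.shape[1]}")
    return dict(zip(df[0], df[1]))


def load_interactome(
    path: str | Path,
    min_regulon_size: int = 25,
    synonyms: Mapping[str, str] | None = None,
) -> Interactome:
    """Read a ``regulator, target, mode, weight`` TSV into an :class:`Interactome`.

    Mode accepts ``+1/-1``/``+/-``/``activation/repression``.  Regulons with
    fewer than *min_regulon_size* targets are dropped (and logged): permutation
    nulls are unstable for tiny regulons.
    """
    path = Path(path)
    edges: dict[str, list[RegulatoryEdge]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            reg_s, tgt_s, mode_s, weight_s = (p.strip() for p in parts)
            mode = _MODE_ALIASES.get(mode_s.lower())
            if mode is None:
                raise ValueError(f"{path}:{lineno}: mode {mode_s!r} does not parse to +1/-1")
            try:
                weight = float(weight_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: weight {weight_s!r} is not numeric") from exc
            reg = _apply_synonyms(reg_s, synonyms)
            tgt = _apply_synonyms(tgt_s, synonyms)
            if (reg, tgt) in seen:
                raise ValueError(f"{path}:{lineno}: duplicate edge ({reg!r}, {tgt!r})")
            seen.add((reg, tgt))
            try:
                edge = RegulatoryEdge(reg, tgt, mode, weight)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            edges.setdefault(reg, []).append(edge)
    regulons = []
    for reg, es in edges.items():
        if len(es) < min_regulon_size:
            logger.info(
                "dropping regulon %s: %d targets < min_regulon_size=%d",
                reg, len(es), min_regulon_size,
            )
            continue
        regulons.append(Regulon(reg, es))
    if not regulons:
        raise ValueError(
            f"{path}: no regulon with >= {min_regulon_size} targets; nothing to analyse"
        )
    return Interactome(regulons)


def write_interactome(net: Interactome, path: str | Path) -> None:
    """Write an interactome TSV; exact round-trip with :func:`load_interactome`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# regulator\ttarget\tmode\tweight\n")
        for regulator in sorted(net.regulons):
            for e in net[regulator].edges:
                fh.write(f"{e.regulator}\t{e.target}\t{e.mode:+d}\t{float(e.weight)!r}\n")


def load_condition_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"condition map must have 2 columns, got {df.shape[1]}")
    if df[0].duplicated().any():
        raise ValueError("duplicate sample in condition map")
    return dict(zip(df[0], df[1]))


def load_expression(
    path: str | Path,
    conditions: Mapping[str, str] | str | Path,
    synonyms: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV plus a sample->condition map."""
    if not isinstance(conditions, Mapping):
        conditions = load_condition_map(conditions)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    if synonyms is not None:
        df.index = pd.Index([_apply_synonyms(g, synonyms) for g in df.index])
    non_numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = non_numeric.isna() & df.notna()
    if bad.any().any():
        gene = df.index[bad.any(axis=1)][0]
        sample = df.columns[bad.any(axis=0)][0]
        raise ValueError(f"non-numeric cell at gene {gene!r}, sample {sample!r}")
    return ExpressionMatrix(non_numeric, conditions)


def write_expression(em: ExpressionMatrix, path: str | Path, conditions_path: str | Path | None = None) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
    if conditions_path is not None:
        em.conditions.to_csv(conditions_path, sep="\t", header=False)


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene\tscore\trank\n")
        for gene in sig.genes:
            fh.write(f"{gene}\t{float(sig.scores[gene])!r}\t{int(sig.ranks[gene])}\n")


def load_signature(path: str | Path) -> GeneSignature:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("signature TSV needs gene and score columns")
    return GeneSignature(pd.Series(df[1].to_numpy(float), index=df[0]))
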