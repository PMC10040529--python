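"""Pan-matrix construction and the co-occurrence screen.

The screening statistic is the sample Pearson correlation between a gene
family's per-genome copy counts and the quantitative phenotype (maximum NaCl
tolerated, % w/v).  Families whose abundance vector is constant across
genomes (the core genome) have no defined correlation and are reported
through a separate channel rather than silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SCREEN_THRESHOLD = 0.8


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.815 -> 0.82, -0.815 -> -0.82).

    Python's builtin ``round`` is banker's rounding; results tables are
    printed at 2 decimals, so ties must resolve the same way everywhere.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PhenotypeTable:
    """Ordered strains and their maximum-NaCl values (% w/v)."""

    strains: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.strains) != len(self.values):
            raise ValueError("strains and values must have equal length")
        if len(self.strains) < 3:
            raise ValueError("need at least 3 strains for a correlation screen")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain ids in phenotype table")
        if any(v <= 0 for v in self.values):
            raise ValueError("phenotype values must be positive (% w/v NaCl)")
        if len(set(self.values)) == 1:
            raise ValueError(
                "phenotype is constant across strains; every co-occurrence "
                "would be undefined"
            )

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"strain_id": self.strains, "max_nacl_percent": self.values}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"strain_id": str})
        if not {"strain_id", "max_nacl_percent"} <= set(df.columns):
            raise ValueError(
                "phenotype TSV needs columns strain_id, max_nacl_percent"
            )
        return cls(
            strains=tuple(df["strain_id"]),
            values=tuple(float(v) for v in df["max_nacl_percent"]),
        )


def pearson_cooccurrence(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> float | None:
    """Sample Pearson correlation between abundance x and phenotype y.

    Returns ``None`` (the undefined flag) when x has zero variance: a family
    present in identical copy number everywhere carries no association
    signal.  The 1/(n-1) normalisations cancel, so sample and population
    formulas coincide.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if syy == 0.0:
        raise ValueError("phenotype vector is constant")
    if sxx == 0.0:
        return None
    r = float((dx @ dy) / np.sqrt(sxx * syy))
    # numerical guard: keep inside [-1, 1]
    return max(-1.0, min(1.0, r))


def _cluster_sort_key(cluster_id: str) -> tuple:
    """Ascending order with numeric suffixes ordered numerically.

    ``Cluster_2`` sorts before ``Cluster_10``; ids without a trailing
    integer fall back to plain lexicographic order.
    """
    m = re.fullmatch(r"(.*?)(\d+)", cluster_id)
    if m:
        return (m.group(1), int(m.group(2)), cluster_id)
    return (cluster_id, -1, cluster_id)


@dataclass(frozen=True)
class PanMatrix:
    """Gene-family x genome copy-count matrix.

    Columns follow the phenotype table's strain order so each row can be
    correlated with the phenotype vector directly.
    """

    cluster_ids: tuple[str, ...]
    genomes: tuple[str, ...]
    counts: np.ndarray  # shape (n_clusters, n_genomes), non-negative ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (len(self.cluster_ids), len(self.genomes)):
            raise ValueError("counts shape does not match ids")
        if (c < 0).any():
            raise ValueError("copy counts must be non-negative")
        if len(self.cluster_ids) and (c.sum(axis=1) == 0).any():
            raise ValueError("every cluster row must have at least one member")
        object.__setattr__(self, "counts", c)

    def row(self, cluster_id: str) -> np.ndarray:
        return self.counts[self.cluster_ids.index(cluster_id)]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.counts, index=list(self.cluster_ids), columns=list(self.genomes)
        )
        df.index.name = "cluster_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PanMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            cluster_ids=tuple(str(i) for i in df.index),
            genomes=tuple(str(c) for c in df.columns),
            counts=df.to_numpy(dtype=int),
        )


def build_pan_matrix(
    assignment: Mapping[str, str],
    orf_to_genome: Mapping[str, str],
    phenotype: PhenotypeTable,
) -> PanMatrix:
    """Count cluster members per genome, columns in phenotype strain order."""
    genome_index = {g: i for i, g in enumerate(phenotype.strains)}
    members: dict[str, list[str]] = {}
    for orf_id, cluster_id in assignment.items():
        if orf_id not in orf_to_genome:
            raise ValueError(f"ORF {orf_id!r} has no genome mapping")
        g = orf_to_genome[orf_id]
        if g not in genome_index:
            raise ValueError(f"ORF {orf_id!r} maps to unknown strain {g!r}")
        members.setdefault(cluster_id, []).append(orf_id)
    cluster_ids = tuple(sorted(members, key=_cluster_sort_key))
    counts = np.zeros((len(cluster_ids), len(phenotype.strains)), dtype=int)
    for i, cid in enumerate(cluster_ids):
        for orf_id in members[cid]:
            counts[i, genome_index[orf_to_genome[orf_id]]] += 1
    return PanMatrix(cluster_ids=cluster_ids, genomes=phenotype.strains, counts=counts)


@dataclass(frozen=True)
class CooccurrenceResult:
    """Screen output for one gene family."""

    cluster_id: str
    value: float | None  # None = undefined (constant abundance)
    n_members: int
    member_orf_ids: tuple[str, ...] = ()
    annotation: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    @property
    def value_2dp(self) -> float | None:
        return None if self.value is None else round_half_away(self.value, 2)


@dataclass(frozen=True)
class ScreenOutput:
    """Passing results plus the undefined (core-genome) side channel."""

    passing: tuple[CooccurrenceResult, ...]
    undefined: tuple[CooccurrenceResult, ...]
    all_results: tuple[CooccurrenceResult, ...]


def screen(
    pan: PanMatrix,
    phenotype: PhenotypeTable,
    threshold: float = DEFAULT_SCREEN_THRESHOLD,
    mode: str = "counts",
    signed: bool = True,
    members: Mapping[str, Sequence[str]] | None = None,
) -> ScreenOutput:
    """Screen families for co-occurrence with the phenotype.

    Parameters
    ----------
    threshold
        Strict cut on the unrounded value (``value > threshold``); the
        printed table rounds to 2 decimals but screening never does.
    mode
        ``counts`` correlates integer copy counts (default); ``binary``
        binarises to presence/absence first.
    signed
        When True only positive exceedances pass; when False the screen is
        on ``|value|``.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    if mode not in ("counts", "binary"):
        raise ValueError("mode must be 'counts' or 'binary'")
    if pan.genomes != phenotype.strains:
        raise ValueError("pan-matrix and phenotype genome order differ")
    y = phenotype.y
    results = []
    for cid, row in zip(pan.cluster_ids, pan.counts):
        x = (row > 0).astype(float) if mode == "binary" else row.astype(float)
        value = pearson_cooccurrence(x, y)
        mem = tuple(members.get(cid, ())) if members else ()
        results.append(
            CooccurrenceResult(
                cluster_id=cid,
                value=value,
                n_members=int(row.sum()),
                member_orf_ids=mem,
            )
        )
    undefined = tuple(r for r in results if not r.defined)
    defined = [r for r in results if r.defined]
    stat = (lambda v: abs(v)) if not signed else (lambda v: v)
    passing = [r for r in defined if stat(r.value) > threshold]
    passing.sort(
        key=lambda r: (-stat(r.value_2dp), _cluster_sort_key(r.cluster_id))
    )
    return ScreenOutput(
        passing=tuple(passing),
        undefined=undefined,
        all_results=tuple(results),
    )


def enumerate_patterns(
    y: Sequence[float] | np.ndarray, max_count: int = 1
) -> pd.DataFrame:
    """Exhaustive table of co-occurrence values over small count vectors.

    Enumerates every vector in {0..max_count}^n except all-zero, a
    verification oracle for printed values: which abundance patterns can
    produce a given correlation with this phenotype.
    """
    ya = np.asarray(y, dtype=float)
    if ya.size > 8:
        raise ValueError("pattern enumeration limited to <= 8 genomes")
    if not 1 <= max_count <= 4:
        raise ValueError("max_count must be in 1..4")
    rows = []
    for pattern in product(range(max_count + 1), repeat=ya.size):
        if not any(pattern):
            continue
        value = pearson_cooccurrence(pattern, ya)
        rows.append(
            {"pattern": pattern, "value": np.nan if value is None else value}
        )
    df = pd.DataFrame(rows)
    df["value"] = df["value"].astype(float)
    return df


def join_annotations(
    results: Iterable[CooccurrenceResult],
    annotations: Mapping[str, str],
    default: str = "hypothetical protein",
) -> list[CooccurrenceResult]:
    """Attach annotation text to results; unknown keys get the default.

    Annotation keys naming clusters absent from the results are ignored
    with a warning (order of results is preserved).
    """
    results = list(results)
    known = {r.cluster_id for r in results}
    for key in annotations:
        if key not in known:
            logger.warning("annotation for unknown cluster %r ignored", key)
    return [
        replace(r, annotation=annotations.get(r.cluster_id, default))
        for r in results
    ]


def results_to_tsv(results: Iterable[CooccurrenceResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "cooccurrence": "NA" if r.value is None else f"{r.value_2dp:.2f}",
                "n_members": r.n_members,
                "annotation": r.annotation or "hypothetical protein",
            }
            for r in results
        ],
        columns=["cluster_id", "cooccurrence", "n_members", "annotation"],
    )
    df.to_csv(path, sep="\t", index=False)
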