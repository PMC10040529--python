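"""Gene-family clustering by normalized local-alignment distance.

Pairwise protein distances are derived from Smith-Waterman local alignment
scores (BLOSUM62, affine gaps) via the score-normalised form

    d(a, b) = 1 - 2 * S(a, b) / (S(a, a) + S(b, b))

which is 0 for identical sequences and 1 for unalignable ones.  Families
are the connected components of the graph whose edges are pairs with
d < threshold — i.e. a single-linkage dendrogram cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cooccurrence import _cluster_sort_key

DEFAULT_CLUSTER_THRESHOLD = 0.75


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring: substitution matrix plus affine gap costs.

    A gap of length L costs ``gap_open + L * gap_extend`` (the blastp
    11/1 convention).  Defaults mirror blastp: BLOSUM62, 11, 1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=4)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _load_matrix(matrix_name)
    # PairwiseAligner charges open_gap_score for the first gapped position,
    # so open+extend reproduces the "open + L*extend" total.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_protein(seq: str, alphabet: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"residues outside scoring alphabet: {sorted(bad)}")


def local_align_score(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Smith-Waterman local alignment score; 0 if nothing aligns positively."""
    scheme = scheme or ScoringScheme()
    alphabet = str(scheme.matrix.alphabet)
    _check_protein(a, alphabet)
    _check_protein(b, alphabet)
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend)
    return max(0, int(aligner.score(a, b)))


def pairwise_distance(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Score-normalised alignment distance in [0, 1]; d(a, a) = 0."""
    scheme = scheme or ScoringScheme()
    s_ab = local_align_score(a, b, scheme)
    s_aa = local_align_score(a, a, scheme)
    s_bb = local_align_score(b, b, scheme)
    d = 1.0 - 2.0 * s_ab / (s_aa + s_bb)
    return max(0.0, min(1.0, d))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal, entries in [0, 1]."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "d", m)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))
        df.to_csv(path, sep="\t", float_format="%.4f")


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def build_distance_matrix(
    proteins: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    prefilter_k: int | None = 4,
) -> DistanceMatrix:
    """All-pairs distance matrix over a protein collection.

    Ids are sorted so the matrix is invariant under input order.  With
    ``prefilter_k`` set, pairs sharing no k-mer are assigned d = 1 without
    alignment — a cheap exact-match screen that only skips pairs far above
    any sensible clustering threshold.
    """
    scheme = scheme or ScoringScheme()
    ids = tuple(sorted(proteins))
    if len(ids) != len(proteins):
        raise ValueError("duplicate sequence ids")
    if not ids:
        raise ValueError("need at least one sequence")
    seqs = [proteins[i] for i in ids]
    alphabet = str(scheme.matrix.alphabet)
    for s in seqs:
        _check_protein(s, alphabet)
    n = len(ids)
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend)
    self_scores = np.array(
        [max(0, int(aligner.score(s, s))) for s in seqs], dtype=float
    )
    kmers = (
        [_kmer_set(s, prefilter_k) for s in seqs] if prefilter_k is not None else None
    )
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if kmers is not None and not (kmers[i] & kmers[j]):
                d[i, j] = d[j, i] = 1.0
                continue
            s_ab = max(0, int(aligner.score(seqs[i], seqs[j])))
            dist = 1.0 - 2.0 * s_ab / (self_scores[i] + self_scores[j])
            d[i, j] = d[j, i] = max(0.0, min(1.0, dist))
    return DistanceMatrix(ids=ids, d=d)


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of sequence ids into named gene families.

    Cluster ids ``Cluster_1`` ... ``Cluster_K`` are assigned by ascending
    order of each cluster's lexicographically smallest member, so the
    naming is deterministic under any permutation of the input.
    """

    mapping: Mapping[str, str]

    def members(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for orf_id, cid in self.mapping.items():
            out.setdefault(cid, []).append(orf_id)
        return {
            cid: tuple(sorted(ids))
            for cid, ids in sorted(out.items(), key=lambda kv: _cluster_sort_key(kv[0]))
        }

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.mapping.items()), columns=["orf_id", "cluster_id"]
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"orf_id", "cluster_id"} <= set(df.columns):
            raise ValueError("cluster TSV needs columns orf_id, cluster_id")
        return cls(mapping=dict(zip(df["orf_id"], df["cluster_id"])))


def single_linkage_cluster(
    D: DistanceMatrix, threshold: float = DEFAULT_CLUSTER_THRESHOLD
) -> ClusterAssignment:
    """Connected components of the strict sub-threshold distance graph.

    Two sequences join the same family whenever a chain of pairs with
    d < threshold links them (single-linkage semantics); threshold = 1.0
    therefore merges everything that is not at maximal distance.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = len(D.ids)
    adj = csr_matrix(D.d < threshold)
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(D.ids[idx])
    ordered = sorted(groups.values(), key=lambda ids: min(ids))
    mapping = {
        orf_id: f"Cluster_{k}"
        for k, ids in enumerate(ordered, start=1)
        for orf_id in ids
    }
    return ClusterAssignment(mapping=mapping)
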