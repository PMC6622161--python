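"""Family assignment at the 60% similarity threshold and duplicate detection.

A query is compared against every sequenced type protein; if its best score
reaches the threshold it is assigned to that type protein's family,
otherwise it is flagged as a candidate novel family.  Sub-threshold scores
are retained as evidence but never assign (e.g. a 57.0% second-best hit is
reported, not acted on).

Duplicate family claims — the same family published under several names —
are found by single-linkage clustering: proteins are nodes, pairs at or
above the threshold are edges, and each connected component is one family.
The Est30 / EstUT1 / EstOF4 merge into a single family (similarities 85.6%,
60.9% and 65%) is the canonical example.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .pairwise import (
    AlignmentParams,
    DEFAULT_SIMILARITY_GROUPS,
    SimilarityMatrix,
    compare,
    pairwise_matrix,
)
from .reference_registry import Registry, TypeProtein, roman_to_int

__all__ = [
    "ClassificationCall",
    "FamilyClusterSet",
    "DEFAULT_THRESHOLD_PCT",
    "classify",
    "classify_from_matrix",
    "detect_duplicate_families",
]

#: Working family-membership threshold of the classification system
#: (mean + 3 SD of the original eight families' pairwise similarity,
#: 30.9 + 3 x 9.6 = 59.7, rounded to the system's working value).
DEFAULT_THRESHOLD_PCT = 60.0


@dataclass(frozen=True)
class ClassificationCall:
    """Outcome of classifying one query against the reference set."""

    query_id: str
    verdict: str  # "assigned" | "novel_candidate"
    assigned_family: Optional[tuple[str, Optional[int]]]
    best_hit: tuple[str, float]
    hits_above_threshold: tuple[tuple[str, float], ...]
    threshold_pct: float

    def __post_init__(self) -> None:
        assigned = self.best_hit[1] >= self.threshold_pct
        if (self.verdict == "assigned") != assigned:
            raise ValueError("verdict inconsistent with best hit vs threshold")
        if self.verdict == "assigned" and self.assigned_family is None:
            raise ValueError("assigned call lacks a family")
        if self.verdict == "novel_candidate" and self.assigned_family is not None:
            raise ValueError("novel candidate must not carry a family")


def _parse_family_key(key: str) -> tuple[str, Optional[int]]:
    """Split a reference label like 'I.5' or 'XIII' into (family, subfamily)."""
    if "." in key:
        fam, sub = key.split(".", 1)
        return fam, int(sub)
    return key, None


def _family_order(key: str) -> tuple[int, int]:
    fam, sub = _parse_family_key(key)
    try:
        return (roman_to_int(fam), sub or 0)
    except Exception:
        return (10**6, sub or 0)  # non-roman labels sort after families


def _decide(
    query_id: str,
    scores: Mapping[str, float],
    threshold_pct: float,
) -> ClassificationCall:
    # ties broken by lowest family number, then subfamily number
    best = min(scores, key=lambda k: (-scores[k], _family_order(k)))
    above = sorted(
        ((k, v) for k, v in scores.items() if v >= threshold_pct),
        key=lambda kv: (-kv[1], _family_order(kv[0])),
    )
    families_above = {_parse_family_key(k)[0] for k, _ in above}
    if len(families_above) > 1:
        warnings.warn(
            f"{query_id}: {len(above)} references in different families "
            f"exceed {threshold_pct}%: {above}; assigning to best hit"
        )
    assigned = scores[best] >= threshold_pct
    return ClassificationCall(
        query_id=query_id,
        verdict="assigned" if assigned else "novel_candidate",
        assigned_family=_parse_family_key(best) if assigned else None,
        best_hit=(best, scores[best]),
        hits_above_threshold=tuple(above),
        threshold_pct=threshold_pct,
    )


def classify(
    query: str,
    registry: Union[Registry, Mapping[str, str]],
    params: Optional[AlignmentParams] = None,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    query_id: str = "query",
    metric: str = "similarity",
    groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS,
) -> ClassificationCall:
    """Classify one query sequence against every sequenced reference.

    ``registry`` is either a :class:`Registry` (entries without sequences are
    skipped) or a plain mapping of reference label -> sequence.  The score is
    percent similarity by default; ``metric="identity"`` scores on percent
    identity instead (the threshold statement in the system is phrased in
    terms of sequence identity; worked examples use similarity).
    The threshold comparison is inclusive (>= threshold assigns).
    """
    if metric not in ("similarity", "identity"):
        raise ValueError("metric must be 'similarity' or 'identity'")
    if isinstance(registry, Registry):
        refs = {e.key: e.sequence for e in registry.sequenced()}
    else:
        refs = dict(registry)
    if not refs:
        raise ValueError("no sequenced reference entries to classify against")
    scores = {
        key: getattr(
            compare(query, seq, params, id_a="__query__", id_b=key,
                    groups=groups),
            f"{metric}_pct",
        )
        for key, seq in refs.items()
    }
    return _decide(query_id, scores, threshold_pct)


def classify_from_matrix(
    similarities: Mapping[str, float],
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    query_id: str = "query",
) -> ClassificationCall:
    """Apply the assignment rule to pre-computed reference->percent scores."""
    if not similarities:
        raise ValueError("empty similarity map")
    return _decide(query_id, dict(similarities), threshold_pct)


@dataclass(frozen=True)
class FamilyClusterSet:
    """Partition of proteins into putative families (single linkage)."""

    clusters: tuple[frozenset[str], ...]
    threshold_pct: float
    linkage: str = "single"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, protein_id: str) -> frozenset[str]:
        for c in self.clusters:
            if protein_id in c:
                return c
        raise KeyError(protein_id)


def detect_duplicate_families(
    proteins: Union[Mapping[str, str], SimilarityMatrix],
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    params: Optional[AlignmentParams] = None,
) -> FamilyClusterSet:
    """Group proposed family type proteins that reach the threshold.

    Accepts either labelled sequences (aligned all-against-all first) or a
    pre-computed :class:`SimilarityMatrix`.  Returns the single-linkage
    clusters: connected components of the graph whose edges join pairs with
    similarity >= threshold.  Proteins in one component are taken to
    represent the same family discovered multiple times.
    """
    if isinstance(proteins, SimilarityMatrix):
        matrix = proteins
    elif len(proteins) == 0:
        raise ValueError("need at least 1 protein")
    elif len(proteins) == 1:
        only = next(iter(proteins))
        return FamilyClusterSet(
            clusters=(frozenset({only}),), threshold_pct=threshold_pct
        )
    else:
        matrix = pairwise_matrix(proteins, params)
    adj = matrix.values >= threshold_pct
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, connection="weak"
    )
    clusters = [
        frozenset(
            matrix.ids[i] for i in range(len(matrix.ids)) if labels[i] == c
        )
        for c in range(n_comp)
    ]
    clusters.sort(key=lambda c: min(matrix.ids.index(i) for i in c))
    return FamilyClusterSet(
        clusters=tuple(clusters), threshold_pct=threshold_pct
    )
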