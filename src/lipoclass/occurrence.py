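"""Homology-hit filtering, taxonomic occurrence summaries and origin checks.

Type proteins are searched against a genome database with BLASTP; the
resulting tabular hits are filtered at two strictness levels:

* **strict** — identity > 80% over > 80% of *both* query and subject
  (overall lower bound 0.80 x 0.80 = 64% identity);
* **expanded** — identity > 60% over > 80% of the query only
  (overall lower bound 0.60 x 0.80 = 48%).

Thresholds are exclusive, each high-scoring pair (HSP) passes or fails on
its own, and surviving hits are summarised as distinct-taxon counts per
query at the family or genus rank.

For metagenome-derived enzymes, bacterial origin is confirmed by a strict
genome match; failing that, the enzyme is included only if the taxonomic
assignments of its top 10 database matches are all bacterial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "SearchHit",
    "TaxonomyRecord",
    "OriginCheckResult",
    "STRICT_IDENTITY_PCT",
    "STRICT_COVERAGE_PCT",
    "EXPANDED_IDENTITY_PCT",
    "EXPANDED_COVERAGE_PCT",
    "strict_overall_identity_bound_pct",
    "expanded_overall_identity_bound_pct",
    "parse_search_hits",
    "write_search_hits",
    "strict_filter",
    "expanded_filter",
    "summarize_taxa",
    "origin_check",
    "load_taxonomy",
]

STRICT_IDENTITY_PCT = 80.0
STRICT_COVERAGE_PCT = 80.0
EXPANDED_IDENTITY_PCT = 60.0
EXPANDED_COVERAGE_PCT = 80.0

#: Named ranks of a semicolon-delimited lineage, outermost first.
LINEAGE_RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus")

_HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "evalue",
    "bitscore",
    "query_length",
    "subject_length",
]


def strict_overall_identity_bound_pct() -> float:
    """Overall-identity lower bound implied by the strict rule (64%)."""
    return STRICT_IDENTITY_PCT * STRICT_COVERAGE_PCT / 100.0


def expanded_overall_identity_bound_pct() -> float:
    """Overall-identity lower bound implied by the expanded rule (48%)."""
    return EXPANDED_IDENTITY_PCT * EXPANDED_COVERAGE_PCT / 100.0


@dataclass(frozen=True)
class SearchHit:
    """One HSP row of tabular protein-search output (outfmt 6 + lengths)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        for side in ("query", "subject"):
            s = getattr(self, f"{side}_start")
            e = getattr(self, f"{side}_end")
            ln = getattr(self, f"{side}_length")
            if not 1 <= s <= e <= ln:
                raise ValueError(
                    f"{side} coordinates [{s}, {e}] outside [1, {ln}] "
                    f"for hit {self.query_id} vs {self.subject_id}"
                )

    @property
    def query_coverage(self) -> float:
        """Percent of the query spanned by this HSP (aligned span / length)."""
        return 100.0 * (self.query_end - self.query_start + 1) / self.query_length

    @property
    def subject_coverage(self) -> float:
        return (
            100.0
            * (self.subject_end - self.subject_start + 1)
            / self.subject_length
        )

    def passes_strict(self) -> bool:
        return (
            self.percent_identity > STRICT_IDENTITY_PCT
            and self.query_coverage > STRICT_COVERAGE_PCT
            and self.subject_coverage > STRICT_COVERAGE_PCT
        )

    def passes_expanded(self) -> bool:
        return (
            self.percent_identity > EXPANDED_IDENTITY_PCT
            and self.query_coverage > EXPANDED_COVERAGE_PCT
        )


def parse_search_hits(path: Union[str, Path]) -> list[SearchHit]:
    """Parse a 14-column tabular hit file (BLAST outfmt "6 std qlen slen").

    Raises ValueError naming the offending row (1-based) on a wrong column
    count, a non-numeric numeric field, or coordinates outside the
    sequence.
    """
    hits: list[SearchHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 14:
                msg = f"row {lineno}: expected 14 columns, got {len(fields)}"
                if len(fields) == 12:
                    msg += (
                        " (standard outfmt-6; the query_length and "
                        "subject_length columns are missing — rerun with "
                        "-outfmt '6 std qlen slen')"
                    )
                raise ValueError(msg)
            try:
                hit = SearchHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    query_start=int(fields[6]),
                    query_end=int(fields[7]),
                    subject_start=int(fields[8]),
                    subject_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    query_length=int(fields[12]),
                    subject_length=int(fields[13]),
                )
            except ValueError as exc:
                raise ValueError(f"row {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_search_hits(
    hits: Iterable[SearchHit], path: Union[str, Path]
) -> None:
    """Write hits back out in the 14-column tabular dialect."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(getattr(h, c)) for c in _HIT_COLUMNS
                )
                + "\n"
            )


def strict_filter(hits: Sequence[SearchHit]) -> list[SearchHit]:
    """Hits with identity > 80% and both coverages > 80%, order preserved."""
    return [h for h in hits if h.passes_strict()]


def expanded_filter(hits: Sequence[SearchHit]) -> list[SearchHit]:
    """Hits with identity > 60% and query coverage > 80%, order preserved."""
    return [h for h in hits if h.passes_expanded()]


@dataclass(frozen=True)
class TaxonomyRecord:
    """Taxonomic lineage of one subject, with named ranks."""

    subject_id: str
    lineage: tuple[str, ...]  # aligned with LINEAGE_RANKS, "" = unknown

    def rank(self, name: str) -> str:
        try:
            i = LINEAGE_RANKS.index(name)
        except ValueError:
            raise KeyError(f"unknown rank {name!r}") from None
        return self.lineage[i] if i < len(self.lineage) else ""

    @property
    def superkingdom(self) -> str:
        return self.rank("superkingdom")


def load_taxonomy(path: Union[str, Path]) -> dict[str, TaxonomyRecord]:
    """Read a subject_id -> semicolon-delimited-lineage TSV mapping.

    Lineages list ranks outermost first (superkingdom;phylum;class;order;
    family;genus); trailing ranks may be absent.
    """
    out: dict[str, TaxonomyRecord] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            subject_id, lineage = line.split("\t")[:2]
            out[subject_id] = TaxonomyRecord(
                subject_id=subject_id,
                lineage=tuple(t.strip() for t in lineage.split(";")),
            )
    return out


def summarize_taxa(
    hits: Sequence[SearchHit],
    taxonomy: Mapping[str, TaxonomyRecord],
    rank: str = "genus",
) -> pd.DataFrame:
    """Distinct-taxon counts per query at a rank (family or genus).

    Each subject counts once per (query, taxon) no matter how many HSPs it
    produced; subjects without a lineage (or without the rank) are counted
    under ``"unresolved"``.  Returns a DataFrame with columns
    ``query_id, taxon, n_subjects``, sorted by query then descending count.
    """
    if rank not in LINEAGE_RANKS:
        raise ValueError(f"rank must be one of {LINEAGE_RANKS}")
    seen: dict[tuple[str, str], set[str]] = {}
    for h in hits:
        rec = taxonomy.get(h.subject_id)
        taxon = rec.rank(rank) if rec else ""
        taxon = taxon or "unresolved"
        seen.setdefault((h.query_id, taxon), set()).add(h.subject_id)
    rows = [
        {"query_id": q, "taxon": t, "n_subjects": len(s)}
        for (q, t), s in seen.items()
    ]
    df = pd.DataFrame(rows, columns=["query_id", "taxon", "n_subjects"])
    return df.sort_values(
        ["query_id", "n_subjects", "taxon"], ascending=[True, False, True]
    ).reset_index(drop=True)


@dataclass(frozen=True)
class OriginCheckResult:
    """Decision on whether a metagenome-derived enzyme is bacterial."""

    query_id: str
    decision: str  # bacterial_confirmed | included | excluded
    basis: str  # strict_genome_match | top10_all_bacterial | non_bacterial_in_top10

    def __post_init__(self) -> None:
        if (self.decision == "excluded") != (
            self.basis == "non_bacterial_in_top10"
        ):
            raise ValueError("decision/basis combination inconsistent")


def origin_check(
    query_id: str,
    strict_hits: Sequence[SearchHit],
    top_hits_taxa: Sequence[str],
    k: int = 10,
) -> OriginCheckResult:
    """Decide bacterial origin of a metagenome-derived enzyme.

    A strict genome match settles it (``bacterial_confirmed``).  Otherwise
    the first ``min(k, available)`` lineage labels of the protein-database
    search, in rank order, must all be bacterial for the enzyme to be
    ``included``; any non-bacterial lineage among them excludes it.
    """
    if strict_hits:
        return OriginCheckResult(
            query_id=query_id,
            decision="bacterial_confirmed",
            basis="strict_genome_match",
        )
    top = list(top_hits_taxa[:k])
    if not top:
        raise ValueError(
            f"{query_id}: no strict hits and no database matches — "
            "origin is indeterminate"
        )
    if all(_is_bacterial(t) for t in top):
        return OriginCheckResult(
            query_id=query_id,
            decision="included",
            basis="top10_all_bacterial",
        )
    return OriginCheckResult(
        query_id=query_id,
        decision="excluded",
        basis="non_bacterial_in_top10",
    )


def _is_bacterial(lineage_label: str) -> bool:
    first = lineage_label.split(";")[0].strip().lower()
    return first == "bacteria"
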