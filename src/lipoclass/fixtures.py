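"""Deterministic synthetic data for exercising the classification system.

Two generators, both seed-deterministic:

* sequence families — per family one random ancestor, plus members produced
  by substituting an exact number of positions so that gapless identity to
  the ancestor equals a target percentage; ancestors are re-drawn until all
  inter-family identities sit below a ceiling.  Substitution-only mutation
  (no indels) means the identity target is exact under gapless comparison
  and can only be met or exceeded by an optimal alignment.
* tabular search hits — rows engineered so that the strict / expanded
  filters recover a known label per row exactly.

The sequence model is deliberately minimal: uniform residue composition,
independent sites, no indels, no rate variation.  It controls identity, not
biological realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .occurrence import SearchHit, write_search_hits

__all__ = [
    "FamilyFixtureSpec",
    "HitFixtureSpec",
    "FamilyFixture",
    "HitFixture",
    "mutate_to_identity",
    "make_family_fixture",
    "make_hit_fixture",
]

ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FamilyFixtureSpec:
    """Conditions for a synthetic set of sequence families."""

    n_families: int = 5
    members_per_family: int = 6
    sequence_length: int = 300
    within_identity_pct: float = 80.0
    between_identity_pct: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.between_identity_pct < self.within_identity_pct <= 100:
            raise ValueError("require 0 <= between < within <= 100")
        if self.sequence_length < 20:
            raise ValueError("sequence_length must be >= 20")
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family and one member")


@dataclass(frozen=True)
class HitFixtureSpec:
    """Conditions for a synthetic tabular hit file.

    The three fractions partition rows into those engineered to pass the
    strict filter, those passing only the expanded filter, and those
    passing neither; they must sum to 1.  identity_range and coverage_range
    bound the sampled values, intersected with each category's window.
    """

    n_hits: int = 30
    frac_strict: float = 1 / 3
    frac_expanded_only: float = 1 / 3
    frac_neither: float = 1 / 3
    identity_range: tuple[float, float] = (20.0, 99.0)
    coverage_range: tuple[float, float] = (10.0, 100.0)
    query_length: int = 300
    subject_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_strict + self.frac_expanded_only + self.frac_neither
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("category fractions must sum to 1")
        if min(self.frac_strict, self.frac_expanded_only, self.frac_neither) < 0:
            raise ValueError("fractions must be non-negative")

    def category_counts(self) -> dict[str, int]:
        """Integer row counts per category (largest-remainder rounding)."""
        fracs = {
            "strict": self.frac_strict,
            "expanded_only": self.frac_expanded_only,
            "neither": self.frac_neither,
        }
        raw = {k: self.n_hits * v for k, v in fracs.items()}
        counts = {k: math.floor(v) for k, v in raw.items()}
        short = self.n_hits - sum(counts.values())
        for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[
            :short
        ]:
            counts[k] += 1
        return counts


def _mutate(seq: str, target_pct: float, rng: np.random.Generator) -> str:
    n = len(seq)
    n_sub = math.floor(n * (100.0 - target_pct) / 100.0 + 0.5)
    positions = rng.choice(n, size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        choices = ALPHABET[ALPHABET != out[p]]
        out[p] = str(rng.choice(choices))
    return "".join(out)


def mutate_to_identity(seq: str, target_pct: float, seed: int) -> str:
    """Substitute exactly round(L·(100 − target)/100) positions of a sequence.

    Positions are chosen without replacement by a seeded RNG and every
    replacement differs from the original residue, so gapless identity to
    the input equals the target up to rounding.  No indels are introduced.
    """
    if not 0 <= target_pct <= 100:
        raise ValueError("target_pct must be in [0, 100]")
    return _mutate(seq, target_pct, np.random.default_rng(seed))


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(ALPHABET, size=length))


def _gapless_identity_pct(a: str, b: str) -> float:
    same = sum(x == y for x, y in zip(a, b))
    return 100.0 * same / len(a)


@dataclass
class FamilyFixture:
    """Synthetic families: ancestors, member records and the truth table."""

    spec: FamilyFixtureSpec
    ancestors: dict[str, str]  # family label -> ancestor sequence
    records: list[tuple[str, str]]  # (member id, sequence)
    truth: dict[str, str] = field(default_factory=dict)  # member id -> family

    def write_fasta(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for name, seq in self.records:
                fh.write(f">{name}\n{seq}\n")

    def write_ancestors_fasta(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for fam, seq in self.ancestors.items():
                fh.write(f">{fam}\n{seq}\n")

    def write_truth(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("member_id\tfamily\n")
            for name, fam in self.truth.items():
                fh.write(f"{name}\t{fam}\n")


def make_family_fixture(
    spec: FamilyFixtureSpec, max_retries: int = 100
) -> FamilyFixture:
    """Generate labelled families with controlled within/between identity.

    Ancestors are drawn uniformly and re-drawn (up to ``max_retries``) until
    every inter-family gapless identity is at or below the between ceiling;
    members are ancestor copies mutated to the within-identity target.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_retries):
        ancestors = [
            _random_sequence(spec.sequence_length, rng)
            for _ in range(spec.n_families)
        ]
        ok = all(
            _gapless_identity_pct(ancestors[i], ancestors[j])
            <= spec.between_identity_pct
            for i in range(spec.n_families)
            for j in range(i + 1, spec.n_families)
        )
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not satisfy between-identity ceiling "
            f"{spec.between_identity_pct}% in {max_retries} draws"
        )
    fam_labels = [f"fam{i + 1}" for i in range(spec.n_families)]
    records: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    for fam, anc in zip(fam_labels, ancestors):
        for m in range(spec.members_per_family):
            name = f"{fam}_m{m + 1}"
            records.append(
                (name, _mutate(anc, spec.within_identity_pct, rng))
            )
            truth[name] = fam
    return FamilyFixture(
        spec=spec,
        ancestors=dict(zip(fam_labels, ancestors)),
        records=records,
        truth=truth,
    )


@dataclass
class HitFixture:
    """Synthetic tabular hits with per-row filter-outcome labels."""

    spec: HitFixtureSpec
    hits: list[SearchHit]
    labels: list[str]  # per row: strict | expanded_only | neither

    def write_hits(self, path: Union[str, Path]) -> None:
        write_search_hits(self.hits, path)

    def write_truth(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("query_id\tlabel\n")
            for h, lab in zip(self.hits, self.labels):
                fh.write(f"{h.query_id}\t{lab}\n")


def _sample_span(
    length: int,
    passing: bool,
    cov_range: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Aligned span with coverage strictly above / at-most 80% of length."""
    pivot = math.floor(0.8 * length)  # span > pivot <=> coverage > 80%
    lo_cov, hi_cov = cov_range
    lo = max(1, math.ceil(lo_cov / 100.0 * length))
    hi = min(length, math.floor(hi_cov / 100.0 * length))
    if passing:
        lo = max(lo, pivot + 1)
    else:
        hi = min(hi, pivot)
    if lo > hi:
        raise ValueError("coverage_range incompatible with category window")
    span = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(1, length - span + 2))
    return start, start + span - 1


def _sample_identity(
    window: tuple[float, float],
    id_range: tuple[float, float],
    rng: np.random.Generator,
) -> float:
    lo = max(window[0], id_range[0])
    hi = min(window[1], id_range[1])
    if lo >= hi:
        raise ValueError("identity_range incompatible with category window")
    return round(float(rng.uniform(lo, hi)), 3)


def make_hit_fixture(spec: HitFixtureSpec) -> HitFixture:
    """Generate hit rows whose strict/expanded survivor sets are known.

    Category windows (identity in percent): strict rows draw identity in
    (80.5, hi] with both coverages > 80%; expanded-only rows draw identity
    in (60.5, 80] — failing the strict identity bar — with query coverage
    > 80%; 'neither' rows draw identity at most 60%.  The 0.5-point margins
    keep sampled values clear of the exclusive thresholds after the 3-decimal
    rounding used in tabular output.
    """
    rng = np.random.default_rng(spec.seed)
    counts = spec.category_counts()
    order = (
        ["strict"] * counts["strict"]
        + ["expanded_only"] * counts["expanded_only"]
        + ["neither"] * counts["neither"]
    )
    rng.shuffle(order)
    hits: list[SearchHit] = []
    for i, label in enumerate(order):
        if label == "strict":
            ident = _sample_identity((80.5, 100.0), spec.identity_range, rng)
            q_pass, s_pass = True, True
        elif label == "expanded_only":
            ident = _sample_identity((60.5, 80.0), spec.identity_range, rng)
            q_pass, s_pass = True, bool(rng.integers(0, 2))
        else:
            ident = _sample_identity((0.0, 60.0), spec.identity_range, rng)
            q_pass, s_pass = bool(rng.integers(0, 2)), bool(rng.integers(0, 2))
        qs, qe = _sample_span(spec.query_length, q_pass, spec.coverage_range, rng)
        ss, se = _sample_span(
            spec.subject_length, s_pass, spec.coverage_range, rng
        )
        aln_len = max(qe - qs, se - ss) + 1
        mismatches = int(round(aln_len * (100.0 - ident) / 100.0))
        hits.append(
            SearchHit(
                query_id=f"q{i + 1:03d}",
                subject_id=f"s{i + 1:03d}",
                percent_identity=ident,
                alignment_length=aln_len,
                mismatches=mismatches,
                gap_opens=0,
                query_start=qs,
                query_end=qe,
                subject_start=ss,
                subject_end=se,
                evalue=1e-50,
                bitscore=200.0,
                query_length=spec.query_length,
                subject_length=spec.subject_length,
            )
        )
    return HitFixture(spec=spec, hits=hits, labels=order)
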