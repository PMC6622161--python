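"""Catalytic-serine pentapeptide motif scanning.

Most lipolytic enzymes of the alpha/beta-hydrolase fold carry their
catalytic serine inside a Gly-X-Ser-X-Gly (GxSxG) pentapeptide, where x is
any standard residue.  Some families vary the flanking positions: AxSxG
(e.g. FnL, LipA), THSTG (plaB, threonine replacing the first glycine) and
GDSIT (AcXE2, threonine in the final position).  Motifs here are
annotation: they describe families but never drive family assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .reference_registry import Registry

__all__ = [
    "MotifPattern",
    "MotifHit",
    "DEFAULT_PATTERNS",
    "scan_catalytic_motifs",
    "annotate_registry_motifs",
]

# 'x' in a template matches any of the 20 standard residues; ambiguity
# codes (X, B, Z) deliberately do not satisfy it.
_X_CLASS = "[ACDEFGHIKLMNPQRSTVWY]"


@dataclass(frozen=True)
class MotifPattern:
    """A pentapeptide template with the catalytic serine at offset 2."""

    name: str
    template: str  # 5 chars; lowercase 'x' is a wildcard
    specificity: int  # higher = more specific; wins when patterns overlap

    def __post_init__(self) -> None:
        if len(self.template) != 5 or self.template[2].upper() != "S":
            raise ValueError(
                f"template {self.template!r} must be 5 residues with Ser "
                "at position 3"
            )

    @property
    def regex(self) -> re.Pattern:
        return re.compile(
            "".join(
                _X_CLASS if c == "x" else re.escape(c.upper())
                for c in self.template
            )
        )

    def matches(self, pentapeptide: str) -> bool:
        return bool(self.regex.fullmatch(pentapeptide.upper()))


#: Literal family motifs take precedence over the generic templates;
#: among the generics, GxSxG outranks AxSxG.
DEFAULT_PATTERNS: tuple[MotifPattern, ...] = (
    MotifPattern("THSTG", "THSTG", specificity=3),
    MotifPattern("GDSIT", "GDSIT", specificity=3),
    MotifPattern("GxSxG", "GxSxG", specificity=2),
    MotifPattern("AxSxG", "AxSxG", specificity=1),
)


@dataclass(frozen=True)
class MotifHit:
    """One pentapeptide match; serine_position is 1-based in the protein."""

    pattern_name: str
    matched_pentapeptide: str
    serine_position: int

    def __post_init__(self) -> None:
        if self.matched_pentapeptide[2] != "S":
            raise ValueError("catalytic position is not serine")
        if self.serine_position < 3:
            raise ValueError("serine_position implies a truncated pentapeptide")

    @property
    def start_position(self) -> int:
        """1-based start of the pentapeptide in the protein."""
        return self.serine_position - 2


def scan_catalytic_motifs(
    seq: str,
    patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS,
) -> list[MotifHit]:
    """All catalytic-serine pentapeptide matches, in sequence order.

    Every window of 5 residues is tested against the pattern set;
    overlapping matches are all reported.  A window matching several
    patterns is reported once, under the most specific one (literal motifs
    beat GxSxG, which beats AxSxG).
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    for start in range(len(seq) - 4):
        window = seq[start : start + 5]
        best: Optional[MotifPattern] = None
        for p in patterns:
            if p.matches(window) and (
                best is None or p.specificity > best.specificity
            ):
                best = p
        if best is not None:
            hits.append(
                MotifHit(
                    pattern_name=best.name,
                    matched_pentapeptide=window,
                    serine_position=start + 3,
                )
            )
    return hits


def annotate_registry_motifs(
    registry: Registry,
    patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS,
) -> list[dict]:
    """Check each type protein's recorded motif against its sequence.

    Returns one report row per entry with a ``status`` of ``confirmed``
    (recorded motif found in the sequence), ``missing`` (sequence present
    but motif absent — flagged, not fatal), ``no_sequence`` or ``no_motif``.
    Recorded template motifs (lowercase x) are matched as wildcards.
    """
    report = []
    for entry in registry:
        row = {
            "key": entry.key,
            "protein_name": entry.protein_name,
            "motif": entry.motif or "",
            "status": "",
            "positions": [],
        }
        if not entry.motif:
            row["status"] = "no_motif"
        elif not entry.sequence:
            row["status"] = "no_sequence"
        else:
            pat = MotifPattern(entry.motif, entry.motif, specificity=0)
            positions = [
                m.start() + 1
                for m in _finditer_overlapping(pat.regex, entry.sequence)
            ]
            row["positions"] = positions
            row["status"] = "confirmed" if positions else "missing"
        report.append(row)
    return report


def _finditer_overlapping(regex: re.Pattern, seq: str) -> Iterable[re.Match]:
    pos = 0
    while True:
        m = regex.search(seq.upper(), pos)
        if m is None:
            return
        yield m
        pos = m.start() + 1
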