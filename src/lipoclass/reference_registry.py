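"""Reference registry of bacterial lipolytic enzyme families.

The classification system organises bacterial lipolytic enzymes (lipases,
EC 3.1.1.3, and carboxylesterases, EC 3.1.1.1) into 35 families identified
by roman numerals, with family I — the true lipases — further divided into
11 numbered subfamilies.  Each family or subfamily is anchored by a single
*type protein*: candidate sequences are classified by pairwise similarity
against these anchors.

The registry bundled with this package encodes the revised system: EstD and
LipR, previously lumped under one family, are split into families X and
XXVIII; the former EstUT1-based family XVIII is collapsed into family XIII
(Est30), with plaB now holding the XVIII label; and LipG is placed as true
lipase subfamily I.9.
"""

from __future__ import annotations

import re
import sys
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import pandas as pd

__all__ = [
    "TypeProtein",
    "Registry",
    "RegistryError",
    "load_reference_table",
    "write_table",
    "get_type_protein",
    "attach_sequences",
    "fetch_reference_sequences",
    "roman_to_int",
]

#: Standard amino-acid alphabet plus X for positions of unknown identity.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_TABLE_COLUMNS = [
    "family",
    "subfamily",
    "type_protein_name",
    "accession",
    "function",
    "motif",
    "source_publication",
]

_ROMAN_VALUES = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}
_ROMAN_RE = re.compile(
    r"^M{0,3}(CM|CD|D?C{0,3})(XC|XL|L?X{0,3})(IX|IV|V?I{0,3})$"
)

DEFAULT_REVISION_NOTES = (
    "Pre-revision assignments: LipG was proposed as the type protein of "
    "family XI but is a true lipase and is placed as subfamily I.9; EstD and "
    "LipR were previously combined as family X but share <30.1% similarity "
    "and distinct catalytic-serine motifs, so the family is split into X "
    "(EstD) and XXVIII (LipR); the previous family XVIII (EstUT1) shares "
    ">60% similarity with Est30 and EstOF4 and is collapsed into family "
    "XIII, freeing the XVIII label for plaB."
)


class RegistryError(ValueError):
    """Raised when a reference table violates the registry contract."""


def roman_to_int(numeral: str) -> int:
    """Convert a roman-numeral family label (e.g. ``'XXVIII'``) to an int."""
    numeral = numeral.strip().upper()
    if not numeral or not _ROMAN_RE.match(numeral):
        raise RegistryError(f"malformed roman-numeral family id: {numeral!r}")
    total = 0
    for ch, nxt in zip(numeral, list(numeral[1:]) + [None]):
        v = _ROMAN_VALUES[ch]
        total += -v if (nxt and v < _ROMAN_VALUES[nxt]) else v
    return total


@dataclass(frozen=True)
class TypeProtein:
    """One reference (type-protein) entry of the classification table."""

    family_id: str
    subfamily_id: Optional[int] = None
    protein_name: str = ""
    accession: str = ""
    function_label: str = ""
    motif: Optional[str] = None
    sequence: Optional[str] = None
    source_publication: str = ""

    def __post_init__(self) -> None:
        roman_to_int(self.family_id)  # validates the label
        if (self.subfamily_id is not None) != (self.family_id == "I"):
            raise RegistryError(
                f"{self.family_id}: subfamily_id must be present exactly for "
                "family I (the true lipases)"
            )
        if self.subfamily_id is not None and not 1 <= self.subfamily_id <= 11:
            raise RegistryError(
                f"subfamily_id {self.subfamily_id} outside 1-11"
            )
        if self.motif is not None:
            if len(self.motif) != 5 or self.motif[2].upper() != "S":
                raise RegistryError(
                    f"motif {self.motif!r} is not a catalytic-serine "
                    "pentapeptide (length 5, Ser at position 3)"
                )
        if self.sequence is not None:
            _validate_sequence(self.sequence, self.accession)

    @property
    def key(self) -> str:
        """Label such as ``'I.5'`` or ``'XIII'`` identifying this entry."""
        if self.subfamily_id is not None:
            return f"{self.family_id}.{self.subfamily_id}"
        return self.family_id

    @property
    def sort_key(self) -> tuple[int, int]:
        return (roman_to_int(self.family_id), self.subfamily_id or 0)


def _validate_sequence(seq: str, label: str) -> None:
    bad = set(seq.upper()) - VALID_RESIDUES
    if bad:
        raise RegistryError(
            f"sequence for {label!r} contains non-amino-acid characters: "
            f"{sorted(bad)}"
        )
    if not seq:
        raise RegistryError(f"sequence for {label!r} is empty")


@dataclass
class Registry:
    """Ordered collection of type proteins plus revision provenance."""

    entries: list[TypeProtein] = field(default_factory=list)
    revision_notes: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, Optional[int]]] = set()
        for e in self.entries:
            k = (e.family_id, e.subfamily_id)
            if k in seen:
                raise RegistryError(f"duplicate family key: {e.key}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def family_ids(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.family_id not in out:
                out.append(e.family_id)
        return out

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_subfamilies(self) -> int:
        return sum(1 for e in self.entries if e.family_id == "I")

    def sequenced(self) -> list[TypeProtein]:
        """Entries carrying a sequence (usable in alignment operations)."""
        return [e for e in self.entries if e.sequence]

    def validate(self) -> None:
        """Enforce the full-system cardinality: 35 families, 11 subfamilies."""
        if self.n_families != 35:
            raise RegistryError(
                f"expected 35 families, found {self.n_families}"
            )
        if self.n_subfamilies != 11:
            raise RegistryError(
                f"expected 11 family-I subfamilies, found {self.n_subfamilies}"
            )


def _bundled_table_path() -> Path:
    return Path(
        resources.files("lipoclass").joinpath("data/reference_families.tsv")
    )


def load_reference_table(
    path: Union[str, Path, None] = None, strict: Optional[bool] = None
) -> Registry:
    """Load a reference table (the bundled Table-1 transcription by default).

    Parameters
    ----------
    path
        Tab-separated table with columns ``family, subfamily,
        type_protein_name, accession, function, motif, source_publication``.
        When omitted, the bundled 35-family table is used.
    strict
        Enforce the 35-family / 11-subfamily cardinality.  Defaults to True
        for the bundled table and False for user-supplied tables.

    Raises
    ------
    RegistryError
        On a missing required column, duplicate (family, subfamily) pair,
        or malformed family id.
    """
    if strict is None:
        strict = path is None
    if path is None:
        path = _bundled_table_path()
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _TABLE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise RegistryError(f"reference table missing columns: {missing}")
    entries = []
    for _, row in df.iterrows():
        sub = row.get("subfamily", "")
        motif = row.get("motif", "") or None
        try:
            entries.append(
                TypeProtein(
                    family_id=row["family"].strip(),
                    subfamily_id=int(sub) if str(sub).strip() else None,
                    protein_name=row.get("type_protein_name", "").strip(),
                    accession=row["accession"].strip(),
                    function_label=row.get("function", "").strip(),
                    motif=motif,
                    source_publication=row.get(
                        "source_publication", ""
                    ).strip(),
                )
            )
        except ValueError as exc:  # includes int() failures
            raise RegistryError(f"row {row.to_dict()}: {exc}") from exc
    reg = Registry(entries=entries, revision_notes=DEFAULT_REVISION_NOTES)
    if strict:
        reg.validate()
    return reg


def write_table(registry: Registry, path: Union[str, Path, TextIO]) -> None:
    """Write a registry back to the TSV dialect read by load_reference_table."""
    rows = [
        {
            "family": e.family_id,
            "subfamily": "" if e.subfamily_id is None else e.subfamily_id,
            "type_protein_name": e.protein_name,
            "accession": e.accession,
            "function": e.function_label,
            "motif": e.motif or "",
            "source_publication": e.source_publication,
        }
        for e in registry
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def get_type_protein(
    registry: Registry, family_id: str, subfamily_id: Optional[int] = None
) -> TypeProtein:
    """Return the unique type protein for a (family, subfamily) pair."""
    for e in registry:
        if e.family_id == family_id and e.subfamily_id == subfamily_id:
            return e
    raise KeyError(
        f"no type protein for family {family_id!r}"
        + (f" subfamily {subfamily_id}" if subfamily_id is not None else "")
    )


def attach_sequences(
    registry: Registry, fasta: Union[str, Path, TextIO]
) -> Registry:
    """Attach amino-acid sequences to registry entries by accession.

    FASTA headers are matched against entry accessions (the accession must
    appear as a ``|``/whitespace-delimited token of the header, so NCBI-style
    ``>sp|Q3IF07|...`` headers work).  Unmatched records trigger a warning;
    entries left without a sequence stay valid but are excluded from
    alignment-based operations.
    """
    from Bio import SeqIO

    by_accession = {e.accession: i for i, e in enumerate(registry.entries)}
    entries = list(registry.entries)
    for rec in SeqIO.parse(fasta, "fasta"):
        tokens = re.split(r"[|\s]+", rec.description) + [rec.id]
        # accessions may be versioned (U78785.1)
        tokens += [t.split(".")[0] for t in tokens]
        hit = next((t for t in tokens if t in by_accession), None)
        seq = str(rec.seq).upper()
        if hit is None:
            warnings.warn(
                f"FASTA record {rec.id!r} matches no registry accession; "
                "not attached"
            )
            continue
        _validate_sequence(seq, hit)
        i = by_accession[hit]
        entries[i] = replace(entries[i], sequence=seq)
    return Registry(entries=entries, revision_notes=registry.revision_notes)


def fetch_reference_sequences(
    out_fasta: Union[str, Path],
    email: str,
    accessions: Optional[Iterable[str]] = None,
) -> int:
    """Download type-protein sequences from NCBI by accession (network!).

    Writes a FASTA usable with :func:`attach_sequences` and returns the
    number of records written.  This is an explicit, network-gated helper;
    nothing else in the package touches the network.
    """
    from Bio import Entrez, SeqIO

    if accessions is None:
        accessions = [e.accession for e in load_reference_table()]
    Entrez.email = email
    n = 0
    with open(out_fasta, "w") as fh:
        for acc in accessions:
            try:
                with Entrez.efetch(
                    db="protein", id=acc, rettype="fasta", retmode="text"
                ) as handle:
                    for rec in SeqIO.parse(handle, "fasta"):
                        SeqIO.write(rec, fh, "fasta")
                        n += 1
            except Exception as exc:  # pragma: no cover - network path
                print(f"fetch failed for {acc}: {exc}", file=sys.stderr)
    return n
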