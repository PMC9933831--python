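"""Proteome libraries: FASTA reading/writing and accession lookup.

A proteome library is an ordered collection of protein records keyed by a
unique accession. Headers may use the UniProt dialect
(``db|ACCESSION|ENTRY_NAME Description OS=... OX=...``) or be bare
(``>NAME free text``); both are parsed into the same record type.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

from Bio import SeqIO

from pepscout.exceptions import DuplicateRecordError, FastaFormatError, ProteinNotFoundError

_UNIPROT_HEADER = re.compile(r"^(?P<db>[^|\s]+)\|(?P<accession>[^|\s]+)\|(?P<entry>\S+)")
_OS_FIELD = re.compile(r"\bOS=(?P<os>.+?)(?=\s+[A-Z]{2}=|$)")
_OX_FIELD = re.compile(r"\bOX=(?P<ox>\d+)")


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome-library entry.

    Parameters
    ----------
    accession : str
        Primary identifier, unique within a library (e.g. a UniProt
        accession such as ``Q9HAU5``; isoform accessions like ``Q9HAU5-2``
        are distinct records).
    sequence : str
        Uppercase residue string; never empty, no whitespace.
    entry_name : str, optional
        Secondary mnemonic identifier (e.g. ``RENT2_HUMAN``).
    description : str
        Free-text description from the header.
    organism_name : str, optional
        Scientific name (``OS=`` field of UniProt headers).
    taxon_id : int, optional
        NCBI taxonomy identifier (``OX=`` field); positive when present.
    """

    accession: str
    sequence: str
    entry_name: Optional[str] = None
    description: str = ""
    organism_name: Optional[str] = None
    taxon_id: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence or any(c.isspace() for c in self.sequence):
            raise ValueError(f"sequence of {self.accession!r} is empty or contains whitespace")
        if self.taxon_id is not None and self.taxon_id <= 0:
            raise ValueError(f"taxon_id of {self.accession!r} must be positive")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeLibrary:
    """Ordered collection of :class:`ProteinRecord` with unique accessions."""

    records: list[ProteinRecord] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        self._by_accession: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.accession in self._by_accession:
                raise DuplicateRecordError(rec.accession)
            self._by_accession[rec.accession] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def get(self, accession: str) -> Optional[ProteinRecord]:
        return self._by_accession.get(accession)

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]


def _parse_header(header: str) -> dict:
    """Split a FASTA header (without '>') into record fields.

    UniProt dialect: accession = second pipe field, entry_name = third,
    organism_name = OS= value, taxon_id = OX= value. Bare headers: accession
    = first whitespace-delimited token, everything else is description.
    """
    first, _, rest = header.partition(" ")
    m = _UNIPROT_HEADER.match(first)
    if m:
        fields = {
            "accession": m.group("accession"),
            "entry_name": m.group("entry"),
            "description": rest.strip(),
            "organism_name": None,
            "taxon_id": None,
        }
        os_m = _OS_FIELD.search(rest)
        if os_m:
            fields["organism_name"] = os_m.group("os").strip()
        ox_m = _OX_FIELD.search(rest)
        if ox_m:
            fields["taxon_id"] = int(ox_m.group("ox"))
        return fields
    return {
        "accession": first,
        "entry_name": None,
        "description": rest.strip(),
        "organism_name": None,
        "taxon_id": None,
    }


def read_fasta(path: Union[str, Path]) -> ProteomeLibrary:
    """Read a proteome library from a FASTA file (plain or gzip).

    Multi-line sequences are concatenated and uppercased. ``*`` (stop)
    characters are stripped with a warning. Non-standard residues are kept;
    their handling is the digestion step's concern.

    Raises
    ------
    FastaFormatError
        If the file is empty or contains no ``>`` records.
    DuplicateRecordError
        If two entries share an accession.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[ProteinRecord] = []
    with opener(path, "rt", encoding="utf-8") as handle:
        try:
            parsed = list(SeqIO.parse(handle, "fasta"))
        except ValueError as exc:
            raise FastaFormatError(f"{path}: {exc}") from exc
        for seq_rec in parsed:
            fields = _parse_header(seq_rec.description)
            seq = str(seq_rec.seq).upper()
            if "*" in seq:
                warnings.warn(
                    f"stripping {seq.count('*')} stop character(s) from {fields['accession']!r}",
                    stacklevel=2,
                )
                seq = seq.replace("*", "")
            if not seq:
                raise FastaFormatError(f"record {fields['accession']!r} has an empty sequence")
            records.append(ProteinRecord(sequence=seq, **fields))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    try:
        return ProteomeLibrary(records=records, source_label=path.name)
    except DuplicateRecordError:
        raise


def write_fasta(library: ProteomeLibrary, path: Union[str, Path], width: int = 60) -> Path:
    """Write a library to FASTA.

    Records carrying an entry name are written in the UniProt dialect
    (``sp|ACC|ENTRY desc OS=... OX=...``); others get bare headers
    (``>ACC desc``).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as out:
        for rec in library:
            if rec.entry_name:
                header = f"sp|{rec.accession}|{rec.entry_name}"
                if rec.description:
                    header += f" {rec.description}"
                if rec.organism_name:
                    header += f" OS={rec.organism_name}"
                if rec.taxon_id:
                    header += f" OX={rec.taxon_id}"
            else:
                header = rec.accession
                if rec.description:
                    header += f" {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")
    return path


def get_protein(library: ProteomeLibrary, accession: str) -> ProteinRecord:
    """Return the record whose accession equals ``accession`` exactly.

    Lookup is case-sensitive; a miss raises :class:`ProteinNotFoundError`
    listing accessions that match ignoring case, if any.
    """
    rec = library.get(accession)
    if rec is not None:
        return rec
    lowered = accession.lower()
    suggestions = tuple(a for a in library.accessions if a.lower() == lowered)
    raise ProteinNotFoundError(accession, suggestions)
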