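"""Universal Spectrum Identifier (USI) parsing and serialization.

A USI is a colon-delimited identifier of a single spectrum (and optionally
its interpretation) published by a ProteomeXchange repository::

    mzspec:<collection>:<ms run>:<index type>:<index value>[:<interpretation>]

The second field — the Collection Component — is the dataset accession
(e.g. a PXD number), which is what lets spectral hits be mapped back to
datasets. Interpretations may themselves contain ':' and are rejoined after
the fifth separator; ':' inside the ms-run name is not supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from pepscout.exceptions import InvalidUSIError

PREFIX = "mzspec"
INDEX_TYPES = frozenset({"scan", "index", "nativeId"})

#: Strict-mode shape for collection accessions (PRIDE/iProX/MassIVE styles).
STRICT_COLLECTION = re.compile(r"^(PXD|MSV|IPX|RPXD)\w+$")


@dataclass(frozen=True)
class USIRecord:
    """A parsed USI; ``collection`` holds the dataset accession."""

    collection: str
    ms_run: str
    index_type: str
    index_value: str
    interpretation: Optional[str]
    raw: str

    @property
    def peptide_sequence(self) -> Optional[str]:
        """Sequence portion of the interpretation (charge stripped), if any."""
        if self.interpretation is None:
            return None
        return self.interpretation.rsplit("/", 1)[0]


def parse_usi(text: str, strict_collection: bool = False) -> USIRecord:
    """Parse a USI string.

    Raises :class:`InvalidUSIError` on a missing ``mzspec`` prefix, fewer
    than five fields, an empty collection, or an unknown index type. With
    ``strict_collection`` the collection must look like a
    PXD/MSV/IPX/RPXD-style accession.
    """
    parts = text.split(":")
    if parts[0] != PREFIX:
        raise InvalidUSIError(f"USI must begin with '{PREFIX}:': {text!r}")
    if len(parts) < 5:
        raise InvalidUSIError(f"USI has fewer than 5 fields: {text!r}")
    collection, ms_run, index_type, index_value = parts[1:5]
    if not collection:
        raise InvalidUSIError(f"USI collection component is empty: {text!r}")
    if index_type not in INDEX_TYPES:
        raise InvalidUSIError(
            f"USI index type must be one of {sorted(INDEX_TYPES)}, got {index_type!r}: {text!r}"
        )
    if strict_collection and not STRICT_COLLECTION.match(collection):
        raise InvalidUSIError(f"collection {collection!r} is not an accepted accession shape")
    interpretation = ":".join(parts[5:]) if len(parts) > 5 else None
    return USIRecord(
        collection=collection,
        ms_run=ms_run,
        index_type=index_type,
        index_value=index_value,
        interpretation=interpretation,
        raw=text,
    )


def serialize_usi(record: USIRecord) -> str:
    """Reassemble the USI string; inverse of :func:`parse_usi` on valid input."""
    fields = [PREFIX, record.collection, record.ms_run, record.index_type, record.index_value]
    if record.interpretation is not None:
        fields.append(record.interpretation)
    return ":".join(fields)


def collection_of(usis: Iterable[str]) -> tuple[list[str], int]:
    """Distinct dataset accessions of the given USIs, in first-seen order.

    Unparseable entries are skipped; the second return value tallies them.
    """
    seen: list[str] = []
    skipped = 0
    for text in usis:
        try:
            rec = parse_usi(text)
        except InvalidUSIError:
            skipped += 1
            continue
        if rec.collection not in seen:
            seen.append(rec.collection)
    return seen, skipped
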