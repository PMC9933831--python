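"""In-silico proteolysis and unique-peptide determination.

Bottom-up proteomics identifies proteins through their peptides, so the
strongest repository query terms are *unique* (proteotypic) peptides:
sequences that occur in the digest of exactly one protein in a given
library. This module digests proteins under a configurable cleavage rule
(trypsin by default: cut C-terminal to K or R unless the next residue is P),
enumerates missed cleavages, applies a peptide length window, indexes
peptides across a whole proteome, and extracts the target's unique set.

Defaults follow common bottom-up practice: trypsin, one missed cleavage,
peptide lengths 7-25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Union

from pepscout.exceptions import EmptyLibraryError, ProteinNotFoundError, UnknownProteaseError
from pepscout.proteome_io import ProteinRecord, ProteomeLibrary

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _trypsin_sites(sequence: str) -> list[int]:
    # cut after K/R unless followed by P (Keil rule); exclude the terminus
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def _lysc_sites(sequence: str) -> list[int]:
    return [i + 1 for i in range(len(sequence) - 1) if sequence[i] == "K"]


def _argc_sites(sequence: str) -> list[int]:
    return [i + 1 for i in range(len(sequence) - 1) if sequence[i] == "R"]


#: Registered cleavage rules; each maps a sequence to strictly increasing
#: 1-based positions of the residue *after which* cleavage occurs.
PROTEASE_RULES: dict[str, Callable[[str], list[int]]] = {
    "trypsin": _trypsin_sites,
    "lys-c": _lysc_sites,
    "arg-c": _argc_sites,
}


@dataclass(frozen=True)
class DigestionConfig:
    """Digestion and indexing parameters.

    protease : name of a registered cleavage rule (default ``"trypsin"``).
    max_missed_cleavages : internal cut sites a peptide may span (default 1).
    min_length, max_length : peptide length window, inclusive (default 7-25).
    exclude_nonstandard : drop peptides containing residues outside the 20
        canonical amino acids (default True) — such peptides cannot be
        meaningfully queried against repositories.
    collapse_il : treat isoleucine and leucine as equivalent when indexing
        (isobaric residues are indistinguishable by mass); default False.
    """

    protease: str = "trypsin"
    max_missed_cleavages: int = 1
    min_length: int = 7
    max_length: int = 25
    exclude_nonstandard: bool = True
    collapse_il: bool = False

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be non-negative")


@dataclass(frozen=True)
class Peptide:
    """A digest product located in its parent protein (1-based, inclusive)."""

    sequence: str
    parent_accession: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates disagree with sequence length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")


def cleavage_sites(sequence: str, protease: str = "trypsin") -> list[int]:
    """1-based positions after which the protease cuts, terminus excluded.

    Raises :class:`UnknownProteaseError` for an unregistered rule name.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    try:
        rule = PROTEASE_RULES[protease]
    except KeyError:
        raise UnknownProteaseError(protease, tuple(sorted(PROTEASE_RULES))) from None
    return rule(sequence)


def digest(record: ProteinRecord, config: DigestionConfig = DigestionConfig()) -> list[Peptide]:
    """Digest one protein, enumerating missed cleavages up to the budget.

    Every segment spanning j+1 consecutive fully-cleaved fragments, for
    j = 0..max_missed_cleavages, is emitted with ``missed_cleavages = j``,
    then filtered to the configured length window (and, by default, to
    canonical residues only). Output is ordered by start position, then
    length.
    """
    seq = record.sequence
    sites = cleavage_sites(seq, config.protease)
    boundaries = [0] + sites + [len(seq)]
    fragments = [
        (boundaries[i] + 1, boundaries[i + 1]) for i in range(len(boundaries) - 1)
    ]  # 1-based inclusive spans of the fully-cleaved fragments

    peptides: list[Peptide] = []
    for i in range(len(fragments)):
        for j in range(config.max_missed_cleavages + 1):
            if i + j >= len(fragments):
                break
            start = fragments[i][0]
            end = fragments[i + j][1]
            length = end - start + 1
            if not (config.min_length <= length <= config.max_length):
                continue
            pep_seq = seq[start - 1 : end]
            if config.exclude_nonstandard and not set(pep_seq) <= CANONICAL_RESIDUES:
                continue
            peptides.append(
                Peptide(
                    sequence=pep_seq,
                    parent_accession=record.accession,
                    start=start,
                    end=end,
                    missed_cleavages=j,
                )
            )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def _index_key(sequence: str, config: DigestionConfig) -> str:
    return sequence.replace("L", "I") if config.collapse_il else sequence


@dataclass
class PeptideIndex:
    """Map from peptide sequence to the set of parent accessions producing it.

    Built over a whole proteome library with one :class:`DigestionConfig`;
    identical peptides at different positions of the same protein contribute
    a single parent entry. With ``collapse_il`` the keys are I/L-collapsed.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    config: DigestionConfig = DigestionConfig()

    def __len__(self) -> int:
        return len(self.entries)

    def parents(self, peptide: str) -> set[str]:
        return self.entries.get(_index_key(peptide, self.config), set())

    def peptides_of(self, accession: str) -> set[str]:
        return {pep for pep, parents in self.entries.items() if accession in parents}


def build_peptide_index(
    library: ProteomeLibrary, config: DigestionConfig = DigestionConfig()
) -> PeptideIndex:
    """Digest every library record and index peptides by parent accession."""
    if len(library) == 0:
        raise EmptyLibraryError("cannot index an empty proteome library")
    entries: dict[str, set[str]] = {}
    for rec in library:
        for pep in digest(rec, config):
            entries.setdefault(_index_key(pep.sequence, config), set()).add(rec.accession)
    return PeptideIndex(entries=entries, config=config)


def unique_peptides(target: str, index: PeptideIndex) -> set[str]:
    """Peptides whose parent set is exactly ``{target}``.

    Uniqueness is evaluated at the accession level: a peptide shared between
    two isoform entries is not unique to either. Raises
    :class:`ProteinNotFoundError` if the target parents nothing in the index.
    """
    found = False
    unique: set[str] = set()
    for pep, parents in index.entries.items():
        if target in parents:
            found = True
            if parents == {target}:
                unique.add(pep)
    if not found:
        raise ProteinNotFoundError(target)
    return unique


def write_peptide_list(peptides: Iterable[str], path: Union[str, Path]) -> Path:
    """Write peptide sequences one per line, sorted, for audit."""
    path = Path(path)
    path.write_text("".join(f"{p}\n" for p in sorted(peptides)), encoding="utf-8")
    return path
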