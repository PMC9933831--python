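"""The 2D search: fan out queries and map every hit to a dataset.

Repositories are queried along two axes — the protein identifier, and each
unique peptide sequence — because repository-side identifications may use a
different identifier namespace (an entry-name mnemonic rather than the
accession), in which case only the peptide axis finds the dataset. Peptide
hits arrive as USI strings; their Collection Component is the dataset
accession, so every hit collapses to a per-dataset evidence row recording
which peptides matched, how many spectra, which repositories answered, and
whether the dataset was reached at the protein level, the peptide level, or
both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from pepscout.exceptions import InvalidUSIError, SearchFailedError
from pepscout.retrieval import Retriever
from pepscout.usi import parse_usi

logger = logging.getLogger(__name__)

ProgressCallback = Callable[[str, str, str], None]  # (source, level, term)


@dataclass
class DatasetEvidence:
    """Evidence for one dataset accumulated across levels and sources."""

    accession: str
    matched_peptides: set[str] = field(default_factory=set)
    usi_count: int = 0
    sources: set[str] = field(default_factory=set)
    protein_level_hit: bool = False

    @property
    def matched_by(self) -> str:
        if self.protein_level_hit and self.matched_peptides:
            return "both"
        return "protein" if self.protein_level_hit else "peptide"


#: Per-dataset evidence keyed by dataset accession.
EvidenceTable = dict[str, DatasetEvidence]


def _accept_usi(usi_text: str, peptide: str) -> Optional[str]:
    """Collection of the USI if it is a valid hit for ``peptide``, else None.

    A repository may return fuzzy matches; a USI counts only if its
    interpretation's sequence portion equals the query exactly (charge
    ignored). USIs without an interpretation cannot be disconfirmed and are
    accepted.
    """
    try:
        rec = parse_usi(usi_text)
    except InvalidUSIError:
        logger.warning("skipping unparseable USI: %r", usi_text)
        return None
    seq = rec.peptide_sequence
    if seq is not None and seq != peptide:
        return None
    return rec.collection


def merge_evidence(tables: Iterable[EvidenceTable]) -> EvidenceTable:
    """Union evidence tables per dataset (counts add, sets union)."""
    merged: EvidenceTable = {}
    for table in tables:
        for acc, ev in table.items():
            tgt = merged.setdefault(acc, DatasetEvidence(accession=acc))
            tgt.matched_peptides |= ev.matched_peptides
            tgt.usi_count += ev.usi_count
            tgt.sources |= ev.sources
            tgt.protein_level_hit = tgt.protein_level_hit or ev.protein_level_hit
    return merged


def run_2d_search(
    accession: str,
    unique_peps: Iterable[str],
    retrievers: list[Retriever],
    progress: Optional[ProgressCallback] = None,
) -> EvidenceTable:
    """Query every retriever at both levels and aggregate dataset evidence.

    For each retriever, one protein-level query for ``accession`` is issued
    first, then one peptide-level query per unique peptide in lexicographic
    order (deterministic logs). ``unique_peps`` may be empty — a
    protein-level-only search still runs. Partial failures are logged and
    skipped; :class:`SearchFailedError` is raised only when *every* query on
    *every* retriever failed.
    """
    if not retrievers:
        raise ValueError("at least one retriever is required")
    peptides = sorted(set(unique_peps))
    table: EvidenceTable = {}
    total_queries = 0
    failed_queries = 0

    for retriever in retrievers:
        if progress:
            progress(retriever.name, "protein", accession)
        result = retriever.query_protein_level(accession)
        total_queries += 1
        logger.info(
            "query=protein source=%s term=%s status=%s n_results=%d",
            retriever.name, accession, result.status, len(result.dataset_accessions),
        )
        if result.status == "failed":
            failed_queries += 1
        else:
            hits = list(result.dataset_accessions)
            # tolerate repositories whose protein queries answer with USIs
            for usi_text in result.usis:
                try:
                    hits.append(parse_usi(usi_text).collection)
                except InvalidUSIError:
                    logger.warning("skipping unparseable USI: %r", usi_text)
            for ds in hits:
                ev = table.setdefault(ds, DatasetEvidence(accession=ds))
                ev.protein_level_hit = True
                ev.sources.add(retriever.name)

        for pep in peptides:
            if progress:
                progress(retriever.name, "peptide", pep)
            result = retriever.query_peptide_level(pep)
            total_queries += 1
            logger.info(
                "query=peptide source=%s term=%s status=%s n_results=%d",
                retriever.name, pep, result.status, len(result.usis),
            )
            if result.status == "failed":
                failed_queries += 1
                continue
            for usi_text in result.usis:
                ds = _accept_usi(usi_text, pep)
                if ds is None:
                    continue
                ev = table.setdefault(ds, DatasetEvidence(accession=ds))
                ev.matched_peptides.add(pep)
                ev.usi_count += 1
                ev.sources.add(retriever.name)

    if total_queries > 0 and failed_queries == total_queries:
        raise SearchFailedError(
            f"all {total_queries} queries failed across {len(retrievers)} retriever(s)"
        )
    return table
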