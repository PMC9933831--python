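"""The hub: end-to-end search orchestration, organism filtering, merging, export.

``search`` composes the whole pipeline: read the proteome library, resolve
the target, build the peptide index, extract unique peptides, run the 2D
search across the configured repositories, fetch dataset metadata, filter
datasets by the target organism (a peptide hit in a mouse dataset is not
evidence for a human protein), merge per-repository metadata, and export the
report as JSON (complete records) and TSV (standardized columns).
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

from pepscout.digestion import DigestionConfig, build_peptide_index, unique_peptides
from pepscout.mapping import DatasetEvidence, EvidenceTable, ProgressCallback, run_2d_search
from pepscout.proteome_io import get_protein, read_fasta
from pepscout.retrieval import DatasetRecord, Organism, Retriever, make_retriever

_TSV_COLUMNS = (
    "accession",
    "sources",
    "matched_by",
    "matched_peptides",
    "usi_count",
    "title",
    "summary",
    "project_url",
)


@dataclass
class SearchConfig:
    """Everything one search needs; deterministic given fixture retrievers."""

    target_accession: str
    proteome_path: Union[str, Path]
    retrievers: list[Retriever]
    digestion: DigestionConfig = field(default_factory=DigestionConfig)
    target_taxon: Optional[Union[int, str]] = None  # falls back to the target's OX/OS
    output_dir: Optional[Union[str, Path]] = None
    keep_unannotated: bool = False
    progress: Optional[ProgressCallback] = None

    def __post_init__(self) -> None:
        if not self.target_accession:
            raise ValueError("target_accession must be non-empty")
        if not self.retrievers:
            raise ValueError("at least one retriever must be configured")


@dataclass
class ReportRow:
    """One retained dataset: merged metadata joined with its evidence."""

    record: DatasetRecord
    evidence: DatasetEvidence


@dataclass
class SearchReport:
    """Merged, organism-filtered search results, exportable to JSON/TSV."""

    target_accession: str
    target_taxon: Optional[Union[int, str]]
    n_unique_peptides: int
    rows: list[ReportRow]
    filtered_out: int
    timestamp: str
    config_echo: dict = field(default_factory=dict)

    @property
    def dataset_accessions(self) -> list[str]:
        return [row.record.accession for row in self.rows]

    def to_dataframe(self):
        """Standardized columns as a pandas DataFrame (same as the TSV)."""
        import pandas as pd

        return pd.DataFrame([_tsv_row(row) for row in self.rows], columns=_TSV_COLUMNS)

    def summary(self) -> str:
        return (
            f"{self.target_accession}: {self.n_unique_peptides} unique peptides; "
            f"{len(self.rows)} dataset(s) retained, {self.filtered_out} filtered out"
        )


def _taxon_as_int(target: Union[int, str]) -> Optional[int]:
    if isinstance(target, int):
        return target
    return int(target) if str(target).isdigit() else None


def filter_by_organism(
    datasets: list[DatasetRecord],
    target: Union[int, str],
    keep_unannotated: bool = False,
) -> tuple[list[DatasetRecord], int]:
    """Retain datasets whose organism set contains the target organism.

    A numeric target matches on taxon id; a name matches scientific names
    case-insensitively. Multi-organism datasets containing the target are
    retained. Datasets without organism metadata are dropped (counted in the
    removed tally) unless ``keep_unannotated``.
    """
    if target in (None, ""):
        raise ValueError("target organism must be non-empty")
    taxon = _taxon_as_int(target)
    name = None if taxon is not None else str(target).casefold()

    retained: list[DatasetRecord] = []
    for ds in datasets:
        if not ds.organisms:
            if keep_unannotated:
                retained.append(ds)
            continue
        for org in ds.organisms:
            if taxon is not None and org.taxon_id == taxon:
                retained.append(ds)
                break
            if name is not None and org.name is not None and org.name.casefold() == name:
                retained.append(ds)
                break
    return retained, len(datasets) - len(retained)


def merge_reports(per_source: list[list[DatasetRecord]]) -> list[DatasetRecord]:
    """Union dataset records across repositories, keyed by accession.

    Sources sets are unioned and organisms merged; for conflicting scalar
    metadata the first-configured source wins, and every source's verbatim
    payload is preserved under its own key in ``full_metadata``. An empty
    scalar never beats a non-empty one. Output is sorted by accession.
    """
    merged: dict[str, DatasetRecord] = {}
    for records in per_source:
        for rec in records:
            tgt = merged.get(rec.accession)
            if tgt is None:
                merged[rec.accession] = DatasetRecord(
                    accession=rec.accession,
                    title=rec.title,
                    summary=rec.summary,
                    project_url=rec.project_url,
                    organisms=set(rec.organisms),
                    sources=set(rec.sources),
                    full_metadata=dict(rec.full_metadata),
                )
                continue
            tgt.title = tgt.title or rec.title
            tgt.summary = tgt.summary or rec.summary
            tgt.project_url = tgt.project_url or rec.project_url
            tgt.organisms |= rec.organisms
            tgt.sources |= rec.sources
            for src, payload in rec.full_metadata.items():
                tgt.full_metadata.setdefault(src, payload)
    return [merged[acc] for acc in sorted(merged)]


def _sanitize(text: str) -> str:
    # TSV dialect: tabs/newlines inside text fields become single spaces
    return re.sub(r"[\t\r\n]", " ", text)


def _tsv_row(row: ReportRow) -> dict:
    return {
        "accession": row.record.accession,
        "sources": ";".join(sorted(row.evidence.sources | row.record.sources)),
        "matched_by": row.evidence.matched_by,
        "matched_peptides": ";".join(sorted(row.evidence.matched_peptides)),
        "usi_count": row.evidence.usi_count,
        "title": _sanitize(row.record.title),
        "summary": _sanitize(row.record.summary),
        "project_url": _sanitize(row.record.project_url),
    }


def _report_to_json_obj(report: SearchReport) -> dict:
    return {
        "target_accession": report.target_accession,
        "target_taxon": report.target_taxon,
        "n_unique_peptides": report.n_unique_peptides,
        "filtered_out": report.filtered_out,
        "timestamp": report.timestamp,
        "config": report.config_echo,
        "datasets": [
            {
                "accession": row.record.accession,
                "title": row.record.title,
                "summary": row.record.summary,
                "project_url": row.record.project_url,
                "organisms": sorted(
                    (o.to_dict() for o in row.record.organisms),
                    key=lambda d: (str(d["name"]), str(d["taxon_id"])),
                ),
                "sources": sorted(row.record.sources),
                "evidence": {
                    "matched_by": row.evidence.matched_by,
                    "matched_peptides": sorted(row.evidence.matched_peptides),
                    "usi_count": row.evidence.usi_count,
                    "sources": sorted(row.evidence.sources),
                },
                "full_metadata": row.record.full_metadata,
            }
            for row in report.rows
        ],
    }


def export_report(report: SearchReport, output_dir: Union[str, Path]) -> tuple[Path, Path]:
    """Write ``report.json`` (complete) and ``report.tsv`` (standardized).

    Both payloads are serialized in full before anything touches disk, so an
    unwritable directory raises before any partial write.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(output_dir, os.W_OK):
        raise OSError(f"output directory is not writable: {output_dir}")

    json_text = json.dumps(_report_to_json_obj(report), indent=2, ensure_ascii=False) + "\n"
    tsv_lines = ["\t".join(_TSV_COLUMNS)]
    for row in report.rows:
        values = _tsv_row(row)
        tsv_lines.append("\t".join(str(values[c]) for c in _TSV_COLUMNS))
    tsv_text = "\n".join(tsv_lines) + "\n"

    json_path = output_dir / "report.json"
    tsv_path = output_dir / "report.tsv"
    json_path.write_text(json_text, encoding="utf-8")
    tsv_path.write_text(tsv_text, encoding="utf-8")
    return json_path, tsv_path


def load_report(json_path: Union[str, Path]) -> SearchReport:
    """Rebuild a :class:`SearchReport` from an exported JSON file."""
    obj = json.loads(Path(json_path).read_text(encoding="utf-8"))
    rows = []
    for d in obj["datasets"]:
        record = DatasetRecord(
            accession=d["accession"],
            title=d["title"],
            summary=d["summary"],
            project_url=d["project_url"],
            organisms={Organism.from_dict(o) for o in d["organisms"]},
            sources=set(d["sources"]),
            full_metadata=d.get("full_metadata", {}),
        )
        ev = d["evidence"]
        evidence = DatasetEvidence(
            accession=d["accession"],
            matched_peptides=set(ev["matched_peptides"]),
            usi_count=ev["usi_count"],
            sources=set(ev["sources"]),
            protein_level_hit=ev["matched_by"] in ("protein", "both"),
        )
        rows.append(ReportRow(record=record, evidence=evidence))
    return SearchReport(
        target_accession=obj["target_accession"],
        target_taxon=obj["target_taxon"],
        n_unique_peptides=obj["n_unique_peptides"],
        rows=rows,
        filtered_out=obj["filtered_out"],
        timestamp=obj["timestamp"],
        config_echo=obj.get("config", {}),
    )


def _resolve_metadata(
    evidence: EvidenceTable, retrievers: list[Retriever]
) -> list[DatasetRecord]:
    """Fetch dataset metadata from every retriever and merge, keeping bare
    records (evidence only, no metadata) for datasets no repository knows."""
    per_source: list[list[DatasetRecord]] = []
    for retriever in retrievers:
        records = []
        for acc in sorted(evidence):
            rec = retriever.fetch_dataset_metadata(acc)
            if rec is not None:
                records.append(rec)
        per_source.append(records)
    merged = merge_reports(per_source)
    known = {rec.accession for rec in merged}
    for acc in sorted(evidence):
        if acc not in known:
            merged.append(DatasetRecord(accession=acc, sources=set(evidence[acc].sources)))
    merged.sort(key=lambda r: r.accession)
    return merged


def search(config: SearchConfig) -> SearchReport:
    """Run the full pipeline and (if an output directory is set) export.

    Raises the underlying not-found / empty-library / search-failed errors;
    on error no output files are written.
    """
    library = read_fasta(config.proteome_path)
    target = get_protein(library, config.target_accession)
    index = build_peptide_index(library, config.digestion)
    uniq = unique_peptides(config.target_accession, index)

    evidence = run_2d_search(
        config.target_accession, uniq, config.retrievers, progress=config.progress
    )
    records = _resolve_metadata(evidence, config.retrievers)

    taxon = config.target_taxon
    if taxon is None:
        taxon = target.taxon_id if target.taxon_id is not None else target.organism_name
    if taxon is None:
        raise ValueError(
            "no target organism: set target_taxon or use a proteome with OS=/OX= headers"
        )
    retained, removed = filter_by_organism(records, taxon, config.keep_unannotated)

    rows = [ReportRow(record=rec, evidence=evidence[rec.accession]) for rec in retained]
    report = SearchReport(
        target_accession=config.target_accession,
        target_taxon=taxon,
        n_unique_peptides=len(uniq),
        rows=rows,
        filtered_out=removed,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        config_echo={
            "proteome": str(config.proteome_path),
            "protease": config.digestion.protease,
            "max_missed_cleavages": config.digestion.max_missed_cleavages,
            "min_length": config.digestion.min_length,
            "max_length": config.digestion.max_length,
            "exclude_nonstandard": config.digestion.exclude_nonstandard,
            "collapse_il": config.digestion.collapse_il,
            "retrievers": [r.name for r in config.retrievers],
            "keep_unannotated": config.keep_unannotated,
        },
    )
    if config.output_dir is not None:
        export_report(report, config.output_dir)
    return report


def load_config(path: Union[str, Path], **overrides) -> SearchConfig:
    """Build a :class:`SearchConfig` from a JSON config file.

    Expected keys: ``accession``, ``proteome``, ``retrievers`` (a list of
    retriever configurations for :func:`pepscout.retrieval.make_retriever`),
    optional ``taxon``, ``digestion`` (DigestionConfig fields),
    ``output_dir``, ``keep_unannotated``. Keyword overrides win.
    """
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    obj.update({k: v for k, v in overrides.items() if v is not None})
    digestion = DigestionConfig(**obj.get("digestion", {}))
    retrievers = [
        r if isinstance(r, Retriever) else make_retriever(r) for r in obj["retrievers"]
    ]
    return SearchConfig(
        target_accession=obj["accession"],
        proteome_path=obj["proteome"],
        retrievers=retrievers,
        digestion=digestion,
        target_taxon=obj.get("taxon"),
        output_dir=obj.get("output_dir"),
        keep_unannotated=bool(obj.get("keep_unannotated", False)),
    )
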