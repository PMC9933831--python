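"""Repository retrievers: the query contract and its backends.

A retriever answers three questions about one repository: which datasets
does it associate with a protein identifier (protein level), which spectra
— as USI strings — match a peptide sequence (peptide level), and what is the
metadata of a given dataset. Transport failures never raise: each query is
retried up to a budget and the outcome is encoded in the result's ``status``
(``ok`` / ``empty`` / ``failed``), because a federated search must survive
partial repository outages.

Two backends are provided: a deterministic fixture backend driven by a JSON
manifest (the tested path), and a thin live HTTP adapter for PRIDE-shaped
APIs whose endpoints are configuration values, not code constants.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

from pepscout.exceptions import PepscoutError

logger = logging.getLogger(__name__)


class TransportError(PepscoutError):
    """Internal marker for a failed exchange with a repository."""


@dataclass(frozen=True)
class Organism:
    """An organism descriptor: scientific name and/or NCBI taxon id."""

    name: Optional[str] = None
    taxon_id: Optional[int] = None

    def to_dict(self) -> dict:
        return {"name": self.name, "taxon_id": self.taxon_id}

    @classmethod
    def from_dict(cls, d: dict) -> "Organism":
        taxon = d.get("taxon_id")
        return cls(name=d.get("name"), taxon_id=int(taxon) if taxon is not None else None)


@dataclass
class RetrievalResult:
    """Outcome of one repository query.

    Protein-level results carry ``dataset_accessions``; peptide-level
    results carry ``usis``. ``status`` is ``ok`` (hits), ``empty`` (query
    succeeded, nothing found) or ``failed`` (transport gave out after
    ``attempts`` tries, both lists empty).
    """

    source: str
    level: str  # "protein" | "peptide"
    query_term: str
    usis: list[str] = field(default_factory=list)
    dataset_accessions: list[str] = field(default_factory=list)
    status: str = "empty"  # "ok" | "empty" | "failed"
    attempts: int = 1

    def __post_init__(self) -> None:
        if self.level not in ("protein", "peptide"):
            raise ValueError(f"level must be 'protein' or 'peptide', got {self.level!r}")
        if self.status == "failed" and (self.usis or self.dataset_accessions):
            raise ValueError("a failed result must carry no hits")


@dataclass
class DatasetRecord:
    """Standardized dataset metadata merged across repositories.

    Absent fields are empty strings/sets, never None. ``full_metadata`` maps
    each contributing repository name to its verbatim payload, so nothing a
    repository returned is lost by standardization.
    """

    accession: str
    title: str = ""
    summary: str = ""
    project_url: str = ""
    organisms: set[Organism] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)
    full_metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("dataset accession must be non-empty")


class Retriever:
    """Base retriever: retry loop, pacing, and the three query operations.

    Subclasses implement ``_request(kind, term)`` returning the raw hits and
    raising :class:`TransportError` on failure; this class turns that into
    the never-raising status contract.
    """

    name: str = "retriever"

    def __init__(
        self,
        max_attempts: int = 3,
        min_interval: float = 0.0,
        sleep: Callable[[float], None] = time.sleep,
    ):
        if max_attempts < 1:
            raise ValueError("max_attempts must be at least 1")
        self.max_attempts = max_attempts
        self.min_interval = min_interval
        self._sleep = sleep
        self._last_request: Optional[float] = None

    # -- subclass surface ---------------------------------------------------
    def _request(self, kind: str, term: str):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- retry/pacing machinery ---------------------------------------------
    def _paced_request(self, kind: str, term: str):
        if self.min_interval > 0 and self._last_request is not None:
            elapsed = time.monotonic() - self._last_request
            if elapsed < self.min_interval:
                self._sleep(self.min_interval - elapsed)
        self._last_request = time.monotonic()
        return self._request(kind, term)

    def _query(self, kind: str, term: str) -> tuple[Optional[list], int]:
        """Returns (hits or None on failure, attempts used)."""
        for attempt in range(1, self.max_attempts + 1):
            try:
                return self._paced_request(kind, term), attempt
            except TransportError as exc:
                logger.warning(
                    "query failed: source=%s kind=%s term=%s attempt=%d/%d error=%s",
                    self.name, kind, term, attempt, self.max_attempts, exc,
                )
        return None, self.max_attempts

    # -- public operations ----------------------------------------------------
    def query_protein_level(self, accession: str) -> RetrievalResult:
        """Datasets the repository associates with a protein identifier."""
        hits, attempts = self._query("protein", accession)
        if hits is None:
            return RetrievalResult(
                source=self.name, level="protein", query_term=accession,
                status="failed", attempts=attempts,
            )
        return RetrievalResult(
            source=self.name, level="protein", query_term=accession,
            dataset_accessions=list(hits), status="ok" if hits else "empty",
            attempts=attempts,
        )

    def query_peptide_level(self, peptide: str) -> RetrievalResult:
        """USI strings whose interpretation contains the queried peptide."""
        if not peptide:
            raise ValueError("peptide must be non-empty")
        hits, attempts = self._query("peptide", peptide)
        if hits is None:
            return RetrievalResult(
                source=self.name, level="peptide", query_term=peptide,
                status="failed", attempts=attempts,
            )
        return RetrievalResult(
            source=self.name, level="peptide", query_term=peptide,
            usis=list(hits), status="ok" if hits else "empty", attempts=attempts,
        )

    def fetch_dataset_metadata(self, accession: str) -> Optional[DatasetRecord]:
        """Dataset metadata, or None when the repository does not know it."""
        if not accession:
            raise ValueError("dataset accession must be non-empty")
        payload, _ = self._query("dataset", accession)
        if not payload:
            return None
        return self._payload_to_record(accession, payload)

    def _payload_to_record(self, accession: str, payload: dict) -> DatasetRecord:
        organisms = {Organism.from_dict(o) for o in payload.get("organisms", [])}
        return DatasetRecord(
            accession=accession,
            title=payload.get("title") or "",
            summary=payload.get("summary") or "",
            project_url=payload.get("project_url") or "",
            organisms=organisms,
            sources={self.name},
            full_metadata={self.name: payload},
        )


class FixtureRetriever(Retriever):
    """Deterministic retriever backed by a JSON manifest.

    The manifest holds, per repository: dataset metadata, planted
    protein→dataset associations, planted peptide→USI associations, and an
    optional failure script (``{"protein:ACC": n, ...}``) that makes the
    first *n* exchanges for that query raise a transport error — letting
    tests exercise the retry contract offline. Identical manifest + query
    always yields identical results.
    """

    def __init__(
        self,
        manifest: Union[str, Path, dict],
        repository: Optional[str] = None,
        max_attempts: int = 3,
        min_interval: float = 0.0,
        sleep: Callable[[float], None] = time.sleep,
    ):
        super().__init__(max_attempts=max_attempts, min_interval=min_interval, sleep=sleep)
        if isinstance(manifest, (str, Path)):
            manifest = json.loads(Path(manifest).read_text(encoding="utf-8"))
        repos = manifest.get("repositories", {})
        if not repos:
            raise ValueError("fixture manifest declares no repositories")
        if repository is None:
            if len(repos) > 1:
                raise ValueError(
                    f"manifest has several repositories ({sorted(repos)}); pick one"
                )
            repository = next(iter(repos))
        if repository not in repos:
            raise ValueError(f"repository {repository!r} not in manifest ({sorted(repos)})")
        self.name = repository
        data = repos[repository]
        self._datasets: dict[str, dict] = data.get("datasets", {})
        self._protein_index: dict[str, list[str]] = data.get("protein_index", {})
        self._peptide_index: dict[str, list[str]] = data.get("peptide_index", {})
        # remaining failure counts, decremented as queries are made
        self._failures: dict[str, int] = dict(data.get("failures", {}))

    def _request(self, kind: str, term: str):
        key = f"{kind}:{term}"
        remaining = self._failures.get(key, 0)
        if remaining > 0:
            self._failures[key] = remaining - 1
            raise TransportError(f"scripted failure for {key} ({remaining} left)")
        if kind == "protein":
            return list(self._protein_index.get(term, []))
        if kind == "peptide":
            return list(self._peptide_index.get(term, []))
        if kind == "dataset":
            return self._datasets.get(term)
        raise ValueError(f"unknown query kind {kind!r}")

    @staticmethod
    def all_for_manifest(
        manifest: Union[str, Path, dict], **kwargs
    ) -> list["FixtureRetriever"]:
        """One retriever per repository in the manifest, in manifest order."""
        if isinstance(manifest, (str, Path)):
            manifest = json.loads(Path(manifest).read_text(encoding="utf-8"))
        return [
            FixtureRetriever(manifest, repository=name, **kwargs)
            for name in manifest.get("repositories", {})
        ]


class LiveRetriever(Retriever):
    """Thin adapter for a PRIDE/iProX-shaped HTTP API.

    Endpoint URL templates come from configuration (``{accession}`` /
    ``{peptide}`` placeholders) since repository APIs drift. The adapter is
    transport plumbing only and is exercised by smoke tests, not live calls.
    """

    def __init__(
        self,
        name: str,
        protein_url: str,
        peptide_url: str,
        dataset_url: str,
        timeout: float = 30.0,
        max_attempts: int = 3,
        min_interval: float = 0.5,
        sleep: Callable[[float], None] = time.sleep,
    ):
        super().__init__(max_attempts=max_attempts, min_interval=min_interval, sleep=sleep)
        self.name = name
        self.protein_url = protein_url
        self.peptide_url = peptide_url
        self.dataset_url = dataset_url
        self.timeout = timeout

    def _fetch_json(self, url: str):
        import urllib.error
        import urllib.request

        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, TimeoutError, json.JSONDecodeError, OSError) as exc:
            raise TransportError(f"{url}: {exc}") from exc

    def _request(self, kind: str, term: str):
        if kind == "protein":
            payload = self._fetch_json(self.protein_url.format(accession=term))
            return [d["accession"] for d in payload] if payload else []
        if kind == "peptide":
            payload = self._fetch_json(self.peptide_url.format(peptide=term))
            return [u if isinstance(u, str) else u.get("usi", "") for u in payload or []]
        if kind == "dataset":
            return self._fetch_json(self.dataset_url.format(accession=term))
        raise ValueError(f"unknown query kind {kind!r}")


def make_retriever(config: dict) -> Retriever:
    """Build a retriever from a configuration mapping.

    ``{"type": "fixture", "manifest": path, "repository": name}`` or
    ``{"type": "live", "name": ..., "protein_url": ..., "peptide_url": ...,
    "dataset_url": ...}``; optional keys ``max_attempts``, ``min_interval``.
    """
    kind = config.get("type", "fixture")
    common = {
        k: config[k] for k in ("max_attempts", "min_interval") if k in config
    }
    if kind == "fixture":
        return FixtureRetriever(
            config["manifest"], repository=config.get("repository"), **common
        )
    if kind == "live":
        return LiveRetriever(
            name=config["name"],
            protein_url=config["protein_url"],
            peptide_url=config["peptide_url"],
            dataset_url=config["dataset_url"],
            timeout=config.get("timeout", 30.0),
            **common,
        )
    raise ValueError(f"unknown retriever type {kind!r}")
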