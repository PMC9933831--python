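"""Seeded generator of synthetic search worlds for offline testing.

A "world" is a toy proteome FASTA plus a mock-repository manifest plus a
ground-truth answer key. The generator draws random protein sequences with
K/R frequency boosted to ~11% (so tryptic peptides in the 7-25 window are
plentiful, roughly mimicking real tryptic length statistics), verifies the
target's unique peptides with the digestion module, deliberately copies some
of them into a second protein (making them shared, hence non-unique), plants
chosen unique peptides as USIs across datasets with mixed organisms, and
writes exactly which datasets a correct search must retain.

Everything is driven by one seed: the same seed yields byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from pepscout.digestion import DigestionConfig, build_peptide_index, unique_peptides
from pepscout.exceptions import GenerationError
from pepscout.proteome_io import ProteinRecord, ProteomeLibrary, write_fasta
from pepscout.usi import parse_usi

TARGET_ORGANISM = {"name": "Homo sapiens", "taxon_id": 9606}
OFF_ORGANISM = {"name": "Mus musculus", "taxon_id": 10090}

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
# K and R each ~5.5% so cleavage sites appear at a realistic tryptic density
_WEIGHTS = [0.055 if r in "KR" else 0.89 / 18 for r in _RESIDUES]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic world.

    ``n_planted_unique`` peptides of the target are planted into repository
    datasets; ``n_shared`` peptides are copied verbatim into other proteins
    (non-unique by construction, so a correct search must never query them).
    ``organism_mix`` optionally fixes each dataset's organism annotations
    (list of organism-dict lists, one per dataset); by default roughly 60%
    of datasets are target-organism, 25% off-organism, the rest unannotated.
    ``failure_script`` may be a per-repository failure mapping, or ``"auto"``
    to inject a couple of transient failures below the retry budget.
    """

    seed: int
    n_proteins: int = 50
    target_index: int = 0
    n_planted_unique: int = 3
    n_shared: int = 2
    n_datasets: int = 8
    n_repositories: int = 2
    organism_mix: Optional[list] = None
    failure_script: Optional[Union[str, dict]] = None
    digestion: DigestionConfig = field(default_factory=DigestionConfig)

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("a world needs at least 2 proteins")
        if not (0 <= self.target_index < self.n_proteins):
            raise ValueError("target_index out of range")
        if self.n_shared > self.n_proteins - 1:
            raise ValueError("n_shared exceeds the number of recipient proteins")
        if self.organism_mix is not None and len(self.organism_mix) != self.n_datasets:
            raise ValueError("organism_mix must have one entry per dataset")


@dataclass(frozen=True)
class WorldPaths:
    fasta: Path
    manifest: Path
    answer_key: Path


def _random_protein(rng: random.Random, i: int) -> ProteinRecord:
    length = rng.randint(180, 320)
    seq = "".join(rng.choices(_RESIDUES, weights=_WEIGHTS, k=length))
    return ProteinRecord(
        accession=f"FXP{i:05d}",
        entry_name=f"SYN{i:03d}_HUMAN",
        description=f"Synthetic protein {i}",
        organism_name=TARGET_ORGANISM["name"],
        taxon_id=TARGET_ORGANISM["taxon_id"],
        sequence=seq,
    )


def _dataset_roles(rng: random.Random, n: int, mix: Optional[list]) -> list[list[dict]]:
    """Organism annotation per dataset (list of organism dicts, maybe empty)."""
    if mix is not None:
        return [list(entry) for entry in mix]
    n_target = max(1, round(0.6 * n))
    n_off = min(max(0, n - n_target), max(1, round(0.25 * n))) if n > 1 else 0
    roles = ["target"] * n_target + ["off"] * n_off + ["none"] * (n - n_target - n_off)
    rng.shuffle(roles)
    out = []
    for role in roles:
        if role == "target":
            orgs = [dict(TARGET_ORGANISM)]
            if rng.random() < 0.25:  # multi-organism datasets must still be retained
                orgs.append(dict(OFF_ORGANISM))
        elif role == "off":
            orgs = [dict(OFF_ORGANISM)]
        else:
            orgs = []
        out.append(orgs)
    return out


def _is_target_annotated(orgs: list[dict]) -> bool:
    return any(o.get("taxon_id") == TARGET_ORGANISM["taxon_id"] for o in orgs)


def _make_usi(rng: random.Random, dataset: str, peptide: str) -> str:
    run = f"run{rng.randint(1, 99):02d}"
    scan = rng.randint(100, 99999)
    charge = rng.choice([2, 3])
    return f"mzspec:{dataset}:{run}:scan:{scan}:{peptide}/{charge}"


def _try_build_world(spec: FixtureSpec, rng: random.Random):
    """One attempt at a satisfiable world; returns None when the draw fails."""
    records = [_random_protein(rng, i) for i in range(spec.n_proteins)]
    target = records[spec.target_index]
    library = ProteomeLibrary(records=records, source_label="fixture")
    uniq = unique_peptides(target.accession, build_peptide_index(library, spec.digestion))
    # shared peptides must survive digestion verbatim after insertion:
    # appended at a tryptic boundary, so the residue before them must be K/R
    # and their own first residue must not be P
    candidates = sorted(p for p in uniq if p[0] != "P")
    if len(candidates) < spec.n_shared or len(uniq) < spec.n_planted_unique + spec.n_shared:
        return None

    shared = rng.sample(candidates, spec.n_shared)
    recipient_idx = [i for i in range(spec.n_proteins) if i != spec.target_index]
    recipients = rng.sample(recipient_idx, spec.n_shared)
    new_records = list(records)
    for pep, idx in zip(shared, recipients):
        rec = new_records[idx]
        seq = rec.sequence
        if seq[-1] not in "KR":
            seq += "R"
        seq += pep
        new_records[idx] = ProteinRecord(
            accession=rec.accession,
            entry_name=rec.entry_name,
            description=rec.description,
            organism_name=rec.organism_name,
            taxon_id=rec.taxon_id,
            sequence=seq,
        )
    library = ProteomeLibrary(records=new_records, source_label="fixture")
    index = build_peptide_index(library, spec.digestion)
    uniq_final = unique_peptides(target.accession, index)

    for pep in shared:  # sharing must have destroyed uniqueness, nothing else
        if pep in uniq_final or len(index.parents(pep)) < 2:
            return None
    if len(uniq_final) < spec.n_planted_unique:
        return None
    planted = rng.sample(sorted(uniq_final), spec.n_planted_unique)
    return library, target, uniq_final, planted, shared


def generate_world(spec: FixtureSpec, out_dir: Union[str, Path], max_attempts: int = 25) -> WorldPaths:
    """Emit (FASTA, manifest JSON, answer-key JSON) into ``out_dir``.

    The answer key is recomputed from the written manifest by brute force
    (union of protein-level plantings and collections of accepted USIs,
    intersected with target-organism datasets), not copied from the
    generator's bookkeeping.

    Raises :class:`GenerationError` if no satisfiable world is found within
    ``max_attempts`` (e.g. shared-peptide insertion keeps destroying the
    required uniqueness); larger proteins or fewer plantings usually help.
    """
    rng = random.Random(spec.seed)
    built = None
    for _ in range(max_attempts):
        built = _try_build_world(spec, rng)
        if built is not None:
            break
    if built is None:
        raise GenerationError(
            f"could not satisfy the fixture spec in {max_attempts} attempts; "
            "try more/longer proteins or fewer planted/shared peptides"
        )
    library, target, uniq_final, planted, shared = built

    # --- datasets, organisms, repository assignment -------------------------
    datasets = [f"PXDT{i + 1:06d}" for i in range(spec.n_datasets)]
    organisms = _dataset_roles(rng, spec.n_datasets, spec.organism_mix)
    target_ds = [d for d, orgs in zip(datasets, organisms) if _is_target_annotated(orgs)]
    repo_names = [f"mockdb{i + 1}" for i in range(spec.n_repositories)]
    ds_repos = {
        d: (list(repo_names) if rng.random() < 0.5 or spec.n_repositories == 1
            else [rng.choice(repo_names)])
        for d in datasets
    }

    # --- peptide-level plantings --------------------------------------------
    pep_plantings: dict[str, list[str]] = {}
    for k, pep in enumerate(planted):
        n_ds = rng.randint(1, min(3, spec.n_datasets))
        chosen = rng.sample(datasets, n_ds)
        if k == 0 and target_ds and not set(chosen) & set(target_ds):
            chosen[0] = rng.choice(target_ds)  # guarantee at least one retained hit
        pep_plantings[pep] = sorted(set(chosen))

    peptide_covered = {d for ds in pep_plantings.values() for d in ds}

    # --- protein-level plantings --------------------------------------------
    prot_ds: set[str] = set()
    if peptide_covered:
        prot_ds.add(rng.choice(sorted(peptide_covered)))  # a "both" dataset
    uncovered_target = [d for d in target_ds if d not in peptide_covered]
    if uncovered_target and rng.random() < 0.8:
        prot_ds.add(rng.choice(uncovered_target))  # a protein-level-only dataset

    # --- manifest assembly ----------------------------------------------------
    repos: dict[str, dict] = {
        name: {"datasets": {}, "protein_index": {}, "peptide_index": {}, "failures": {}}
        for name in repo_names
    }
    for i, (d, orgs) in enumerate(zip(datasets, organisms)):
        meta = {
            "title": f"Synthetic proteomics study {i + 1}",
            "summary": f"Mock dataset {d} generated for offline search testing.",
            "project_url": f"https://repo.example.org/datasets/{d}",
            "organisms": orgs,
            "instrument": rng.choice(["Orbitrap Fusion", "Q Exactive HF", "timsTOF Pro"]),
        }
        for name in ds_repos[d]:
            repos[name]["datasets"][d] = meta
    for d in sorted(prot_ds):
        for name in ds_repos[d]:
            repos[name]["protein_index"].setdefault(target.accession, []).append(d)
    for pep, ds_list in pep_plantings.items():
        for d in ds_list:
            repo = rng.choice(ds_repos[d])
            usis = [_make_usi(rng, d, pep) for _ in range(rng.randint(1, 2))]
            repos[repo]["peptide_index"].setdefault(pep, []).extend(usis)
    # decoy plantings of shared (non-unique) peptides: a correct search never
    # queries these, so they must not create datasets in the answer key
    for pep in shared:
        d = rng.choice(datasets)
        repo = rng.choice(ds_repos[d])
        repos[repo]["peptide_index"].setdefault(pep, []).append(_make_usi(rng, d, pep))

    if spec.failure_script == "auto":
        # transient failures strictly below the default retry budget of 3
        repos[repo_names[0]]["failures"][f"protein:{target.accession}"] = rng.randint(1, 2)
        if planted:
            victim = rng.choice(planted)
            repos[repo_names[-1]]["failures"][f"peptide:{victim}"] = rng.randint(1, 2)
    elif isinstance(spec.failure_script, dict):
        for name, failures in spec.failure_script.items():
            repos[name]["failures"].update(failures)

    manifest = {
        "schema": "pepscout-fixture-manifest/1",
        "seed": spec.seed,
        "repositories": repos,
    }

    # --- answer key: brute-force recomputation from the manifest -------------
    evidence: dict[str, dict] = {}
    for name in repo_names:
        for d in repos[name]["protein_index"].get(target.accession, []):
            ev = evidence.setdefault(d, {"peptides": set(), "usi_count": 0, "protein": False})
            ev["protein"] = True
        for pep in sorted(uniq_final):
            for usi_text in repos[name]["peptide_index"].get(pep, []):
                rec = parse_usi(usi_text)
                if rec.peptide_sequence != pep:
                    continue
                ev = evidence.setdefault(
                    rec.collection, {"peptides": set(), "usi_count": 0, "protein": False}
                )
                ev["peptides"].add(pep)
                ev["usi_count"] += 1
    org_by_ds = dict(zip(datasets, organisms))
    retained = {}
    for d in sorted(evidence):
        if not _is_target_annotated(org_by_ds.get(d, [])):
            continue
        ev = evidence[d]
        matched_by = (
            "both" if ev["protein"] and ev["peptides"]
            else "protein" if ev["protein"] else "peptide"
        )
        retained[d] = {
            "matched_by": matched_by,
            "matched_peptides": sorted(ev["peptides"]),
            "usi_count": ev["usi_count"],
        }
    answer_key = {
        "target_accession": target.accession,
        "target_taxon": TARGET_ORGANISM["taxon_id"],
        "n_unique_peptides": len(uniq_final),
        "planted_unique": sorted(planted),
        "shared_peptides": sorted(shared),
        "mapped_total": len(evidence),
        "filtered_out": len(evidence) - len(retained),
        "retained": retained,
    }

    # --- write ---------------------------------------------------------------
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = write_fasta(library, out_dir / "proteome.fasta")
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    key_path = out_dir / "answer_key.json"
    key_path.write_text(
        json.dumps(answer_key, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return WorldPaths(fasta=fasta_path, manifest=manifest_path, answer_key=key_path)
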