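# pepscout

**Find public proteomics datasets that contain evidence for your protein of
interest.**

Bottom-up proteomics is peptide-centric: proteins are digested (usually with
trypsin), peptides are identified from mass spectra, and proteins are
inferred from the peptides. A *unique* (proteotypic) peptide — one whose
sequence occurs in the digest of exactly one protein in a given proteome
library — is therefore the strongest evidence that a protein is present in a
dataset. pepscout exploits this to search dataset repositories along two
axes at once (a "2D" search):

1. **Protein level** — query the repository with the protein identifier
   itself.
2. **Peptide level** — compute the protein's unique tryptic peptides against
   its proteome library and query each one. Hits come back as Universal
   Spectrum Identifiers (USIs), `mzspec:<collection>:<run>:<type>:<index>[:<interpretation>]`,
   whose second field (the Collection Component) is the dataset accession —
   so every spectral hit maps back to a dataset.

The peptide axis matters because repositories often index identifications
under whatever identifier namespace the original submitter's search database
used (an entry-name mnemonic such as `RENT2_HUMAN` rather than the accession
`Q9HAU5`), so a plain protein-identifier query can miss datasets that
contain the protein. Results from both levels and from multiple
repositories are merged per dataset, filtered by organism (a peptide hit in
a mouse dataset is not evidence for a human protein), and exported as JSON
(complete metadata) and TSV (standardized columns).

## The method in brief

Given a target accession $T$ in a proteome library $L$:

- digest every record of $L$ in silico with the trypsin rule (cleave
  C-terminal to K or R unless the next residue is P), enumerating peptides
  with up to $m$ missed cleavages (default $m=1$) and lengths in $[7, 25]$;
- build the peptide index $I : \text{peptide} \mapsto \{\text{parent accessions}\}$;
  the unique set is $U(T) = \{p : I(p) = \{T\}\}$;
- for each configured repository, query $T$ at the protein level and each
  $p \in U(T)$ at the peptide level; map each returned USI to its
  collection (dataset) if its interpretation's sequence equals the query;
- label each mapped dataset `protein`, `peptide`, or `both`; fetch its
  metadata from every repository; merge (first-configured source wins on
  conflicting scalars, everything kept verbatim in `full_metadata`);
  retain datasets whose organism annotation contains the target organism.

Because the correctness of such a tool lives in the orchestration rather
than in any remote payload, pepscout ships a deterministic **fixture
backend** (a JSON manifest of mock repositories; schema in
`docs/fixture_manifest.schema.json`) and a seeded **world generator** that
plants unique and shared peptides into synthetic proteomes and mock
datasets, together with a ground-truth answer key. Live HTTP adapters
implement the same retriever contract.

## Worked example

Generate a synthetic world and search it:

```bash
pepscout make-fixtures --seed 7 --out demo
pepscout search --accession FXP00000 --proteome demo/proteome.fasta \
    --retriever fixture:demo/manifest.json:mockdb1 \
    --retriever fixture:demo/manifest.json:mockdb2 \
    --out demo_out
```

which prints

```
search parameters: protease trypsin, missed cleavages: 1, length 7–25
FXP00000: 28 unique peptides; 5 dataset(s) retained, 1 filtered out; wrote demo_out/report.json and demo_out/report.tsv
```

meaning: the target protein has 28 tryptic peptides found in no other
library protein; querying two mock repositories at both levels mapped six
datasets, of which five carry the target organism (*Homo sapiens*, taxon
9606) and are retained — per dataset the TSV lists which peptides matched,
how many spectra (`usi_count`), and whether it was reached at the protein
level, the peptide level, or both. The same search is available from Python:

```python
from pepscout import SearchConfig, FixtureRetriever, search

report = search(SearchConfig(
    target_accession="FXP00000",
    proteome_path="demo/proteome.fasta",
    retrievers=FixtureRetriever.all_for_manifest("demo/manifest.json"),
))
print(report.summary())
report.to_dataframe()
```

`pepscout digest --accession ... --proteome ...` lists the unique peptides
standalone.

## Scope

pepscout performs no spectral rescoring, FDR assessment, modification
handling or peptide mass computation, and ships no result cache or
authentication. Live repository adapters are thin, configuration-driven and
smoke-tested only; all tested behaviour runs offline against fixtures.
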