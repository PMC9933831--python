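# Methods

## The procedure and its assumptions

pepscout treats dataset discovery as a mapping problem. A dataset contains
evidence for a protein if a repository associates the dataset with the
protein identifier (protein level) or if spectra in the dataset were
identified as one of the protein's *unique* peptides (peptide level). The
pipeline is: read the proteome library → resolve the target → digest every
library record in silico → index peptides by parent accession → take the
peptides whose parent set is exactly the target → query every configured
repository at both levels → map peptide-level USI hits to datasets through
the USI Collection Component → fetch and merge dataset metadata → filter by
organism → export.

Assumptions worth stating:

- **Uniqueness is relative to the library.** A peptide unique against one
  proteome snapshot may be shared in another (new isoforms, new entries).
  Unique-peptide counts are therefore properties of (protein, library,
  digestion parameters), not of the protein alone, and are expected to
  drift with library releases.
- **Uniqueness is evaluated at the accession level.** A peptide shared only
  between two isoform entries of one gene is *not* unique. This is the
  strictest reading; it errs toward fewer, stronger query terms.
- **Repository identifications are trusted as given.** No rescoring or FDR
  control is applied; the organism filter and the exact-interpretation check
  are the only relevance guards.

## Digestion

The trypsin rule is fixed as "cleave C-terminal to K or R, except when the
following residue is P" (the classical Keil rule; the dominant convention in
digestion tools). The rule table is extensible by name (`lys-c` and `arg-c`
are registered). A peptide with *j* missed cleavages spans *j*+1 consecutive
fully-cleaved fragments; enumeration is by fragment-run, which makes two
properties exact by construction and testable: the mc=0 fragments
concatenate to the input, and with *c* sites and no filters there are
*c*+1−*j* peptides with exactly *j* missed cleavages.

Parameter defaults (all overridable):

| parameter | default | why |
|---|---|---|
| protease | trypsin | standard bottom-up workhorse |
| max_missed_cleavages | 1 | common search-engine setting; balances coverage vs combinatorics |
| min_length / max_length | 7 / 25 | residues; the useful MS-identifiable range |
| exclude_nonstandard | true | peptides with B/J/O/U/X/Z cannot be meaningfully queried against repositories |
| collapse_il | false | I/L are isobaric and indistinguishable by mass; off by default so reported peptides are literal library sequences |

N-terminal methionine is **not** removed before digestion and no other
hidden sequence transformation is applied: reproducibility favors digesting
exactly what the FASTA says. Non-standard residues are retained at read time
(the library must faithfully represent its source) and handled only at
digestion/indexing. `*` stop characters are stripped with a warning since
they are translated-ORF artifacts, not residues. Coordinates are 1-based
inclusive, the common proteomics convention.

## USI handling

USIs are split on `:`; fields beyond the fifth separator are rejoined into
the interpretation, so interpretations containing `:` (e.g. UNIMOD
annotations) round-trip, while `:` inside an ms-run name is unsupported
(ambiguous under colon-splitting — dataset mapping only needs the collection
and index fields to be unambiguous). Collection validation is permissive by
default with an optional strict mode (`PXD|MSV|IPX|RPXD` shapes). A
peptide-level hit is counted only if the USI interpretation's sequence
portion (text before the final `/`) equals the queried peptide exactly;
charge is ignored; USIs without an interpretation cannot be disconfirmed and
are accepted.

## Retrieval and failure semantics

Queries never raise on transport failure: each is retried up to a budget
(default 3 attempts) and the outcome is encoded in the result status, so a
federated search degrades gracefully under partial outages.
`SearchFailedError` is raised only when every query against every repository
failed. Backoff/pacing delays are injectable (zero in tests). Query order is
deterministic — protein level first, then peptides lexicographically — for
reproducible logs.

## Merging and filtering

Merging is keyed by dataset accession: sources and organisms union; for
conflicting scalar metadata (title/summary/URL) the first-configured source
wins, but an empty scalar never beats a non-empty one, and every source's
verbatim payload is preserved under its own key in `full_metadata`. This
makes merging associative and order-insensitive up to the fixed source
precedence (property-tested).

The organism filter matches by taxon id when the target is numeric, else by
case-insensitive scientific name; multi-organism datasets containing the
target are retained. Datasets with no organism metadata are dropped by
default (the filter exists to guarantee evidence relevance) and counted in
the removed tally; `keep_unannotated` overrides. Retained + removed always
equals the mapped total.

## Export

TSV dialect: UTF-8, header plus one row per dataset, columns `accession,
sources, matched_by, matched_peptides, usi_count, title, summary,
project_url`; multi-valued fields are `;`-joined and sorted; tabs/newlines
inside text fields become single spaces so the column count is constant on
every row. JSON carries the complete records including `full_metadata` and
evidence, and re-exporting a reloaded JSON is byte-identical. Timestamps are
ISO-8601 UTC and excluded from determinism comparisons.

## The synthetic world generator

The generator emulates the parts of the real ecosystem the orchestration
depends on: a proteome library in which the target provably has unique
peptides, peptides deliberately duplicated into other proteins (non-unique
by construction — a correct search must never query them; decoy plantings of
these in the mock repositories must never surface), repositories that plant
chosen unique peptides as USIs across datasets with mixed organism
annotations (~60% target organism, ~25% off-organism, the rest unannotated,
with occasional multi-organism datasets), protein-level plantings including
a protein-level-only dataset when possible, and scripted transient failures
below the retry budget.

Protein sequences are random draws over the 20 canonical residues with K and
R boosted to ~5.5% each (~11% combined) so tryptic peptides in the 7–25
window are plentiful, mimicking real tryptic length statistics well enough
for testing. Shared peptides are inserted at tryptic boundaries (preceded by
K/R, first residue not P, or appended at the terminus) so they survive
digestion verbatim. The answer key is recomputed from the written manifest
by brute force rather than copied from generator bookkeeping. Default scale
— 50 proteins of 180–320 residues, 2 repositories, 8 datasets, 3 planted
unique and 2 shared peptides — keeps a full world generation + search round
under a second while exercising every code path.

What the generator does **not** emulate: real repository payload schemas
beyond the fields the standardized record consumes, identification noise
(every planted USI is a correct identification), repository-side
identifications made with *non-unique* peptides, result pagination, and
rate-limit behaviour of live APIs. Passing tests therefore demonstrate that
the orchestration — digestion, uniqueness, mapping, merging, filtering,
export — is correct, not that any live repository's content or API contract
matches the fixtures.

## Numerical and degenerate-input choices

No floating-point computation is involved; determinism is exact. Degenerate
inputs are explicit: empty FASTA → format error; duplicate accession →
duplicate-record error naming the accession; empty library → empty-input
error at indexing; a target absent from the library or index → not-found
error with case-insensitive suggestions; an empty unique set still runs the
protein-level search; unparseable USIs are skipped and tallied, never fatal.

## Known limitations

- Live adapters are smoke-tested plumbing; endpoint drift is handled by
  configuration, not code, and no MassIVE adapter ships yet (the retriever
  contract supports adding one).
- Isoform-aware uniqueness (gene-level grouping) is out of scope; the
  accession-level rule may under-report unique peptides for genes with many
  isoform entries in the library.
- Repository-side identifications made with peptides outside the unique set
  are invisible to the search by design; reconciling them is a separate
  problem.
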