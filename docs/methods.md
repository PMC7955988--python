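# Methods

## Data model

A `PubmedArticleSet` document is a sequence of `PubmedArticle` elements
plus, in post-baseline files, a `DeleteCitation` element listing removed
PMIDs. One article yields rows in up to fifteen versioned tables (see
`medlinedb/registry.py` for the full registry and element paths); every
row carries `(pmid, version)`. The registry is data — adding a column or
table does not touch pipeline code, which iterates over it.

Conventions chosen where the source format leaves room:

- **Version default.** A `PMID` element without a `Version` attribute is
  version 1, the document type's declared default.
- **Dates.** History dates with a missing day (or month) are stored padded
  with 1 and flagged in a `date_precision` column (`day`/`month`/`year`),
  keeping one sortable date column without inventing precision. Invalid
  dates (e.g. month 0) are stored null with a warning.
- **ORCID normalization.** Identifier values with `Source="ORCID"` are
  canonicalized to the 19-character dashed form — URL prefix stripped,
  check character uppercased — so identifier joins have one key;
  unparseable values pass through verbatim.
- **Abstracts** are one row per article; labelled paragraphs are
  concatenated with their labels kept as `LABEL: ` prefixes.
- **Duplicate PMID within one file**: the last occurrence in document
  order wins, consistent with the pipelines' most-recent rule.
- **Author rows** keep the author-list position (`author_pos`, 1-based);
  exactly one of `last_name` / `collective_name` is set. An author entry
  with neither is dropped with a warning rather than stored with null
  keys.

## Merge rules

**Baseline.** Files are appended in sequence order, one transaction per
file (rows + ledger entry), then each versioned table is reduced to the
per-PMID maximal version with a single set-based anti-join per table.
If the same `(pmid, version)` appears in two baseline files, the later
file's rows replace the earlier's at append time, so ties resolve to the
most recently processed file. The ledger makes the build resumable after
a crash; replaying a file is harmless because its `(pmid, version)` pairs
are replaced, not duplicated.

**Update.** Unprocessed files (ledger-filtered, sequence-ordered) are
staged into `tmp_`-prefixed twins with a `source_file` tag; deletion
notices go to `tmp_deletion`. Resolution picks per PMID the maximal
staged version, ties to the later file; the PMID is tombstoned instead if
its last staged event in file order is a deletion (a notice in the same
file outranks that file's article data, since `DeleteCitation` closes the
document). Application is one transaction of whole-PMID delete-and-append
— the format revises whole records, so no field-level diffing exists.
Staging twins are real tables dropped only on success, leaving a crashed
run inspectable and retryable. Deleting a never-seen PMID is a logged
no-op.

A consequence worth knowing: when batches are applied one file at a time,
each batch resolves independently, so an (unrealistic) version regression
across batches ends at the later file's lower version, whereas a combined
batch ends at the maximal version. Real update streams never decrease a
PMID's version, and for version-monotone inputs batch splitting is
state-equivalent (tested).

**Citations.** The edge list loads into a shadow table swapped in on
success; a failed load cannot disturb the previous table. Lines that are
not two positive integers are skipped and counted; self-citations load
but are flagged. "Newer release" means "different label" — semantic
ordering of upstream labels is not this package's contract. Deletion
notices do not purge citation edges; the table is replaced wholesale on
refresh anyway.

## Backends and memory

The embedded backend is stdlib SQLite — first-class, used by every test,
and recommended for small-scale work. A PostgreSQL dialect sits behind
the same `Database` wrapper (paramstyle and type mapping differ; the
password comes from `MEDLINEDB_PASSWORD`, never a URL). Timestamps are
stored UTC.

Parsing is streaming: `iterparse` with immediate element cleanup, so peak
memory is set by the largest single article. The single-worker pipelines
append in chunks of 2 000 articles, keeping memory flat for arbitrarily
long files; with several workers, whole files are parsed concurrently in
subprocesses and appended serially in file order (bounded by a file — the
price of parallel parsing). The suite verifies the bound by streaming a
generated 50 000-article file (~90 MB of XML) in a subprocess: it stays
under 256 MiB where a whole-document parse of the same file exceeds it.

## Synthetic corpus and oracle

The generator renders event scripts (create/update/delete per file) into
gzip XML with fixed gzip mtime, so a seed yields byte-identical files.
Article content is a pure function of `(seed, pmid, version, payload
sizes)`: names, journals, MeSH terms and keywords from small seeded
vocabularies, ORCIDs with valid ISO 7064 MOD 11-2 check characters,
history events always including an `entrez` entry date, and deliberate
presentation noise (ORCID URL/dash variants, omitted `Version="1"`
attributes, day-less dates) that the parser must normalize away.

Default random-script mixes model the corpus the pipelines face: most
PMIDs single-version, ~10 % gaining a second version, ~40 % updated, ~10 %
eventually deleted, ~15 % first appearing in update files. Scripts keep
versions non-decreasing — as in the real stream — and place deletions
only in update files.

The replay oracle computes the expected end state by replaying events in
order (last event per PMID wins) and shares no code with the pipelines;
it is itself cross-checked in the suite against a second, naive
nested-loop implementation. What fixture-scale passing shows: the merge,
versioning, deletion, idempotency and ordering logic is correct for the
structural features emulated. What it does not show: behaviour on MEDLINE
elements outside the registry, real-world encoding pathology, server-
backend concurrency, or full-corpus performance.

## Problem sizes and defaults

Suite and acceptance-script sizes were chosen to exercise every rule with
comfortable randomization while staying desk-sized: the headline
equivalence check runs 100 random scripts of up to 200 PMIDs over up to 5
files; the version-rule property covers 1 000 random cases; the
acceptance script sweeps 30 corpora and builds a 400-PMID demonstration
corpus. The query layer defaults to grouping time by the `entrez` history
status (the database-entry stamp, present on essentially every record);
the status is a parameter because registration conventions vary by study.
Quartiles use linear interpolation; periods with no publications are
omitted rather than zero-filled.

## Known limitations

- Only the registry's data types are parsed; book documents and full-text
  (PMC) content are out of scope and skipped with a warning.
- The PostgreSQL dialect is interface-complete but exercised only through
  the SQLite twin; server-specific bulk-load tuning (COPY) is not
  implemented.
- `parse_file` materializes a whole file's rows by design (its contract
  is a per-file batch); memory-bounded consumers use `parse_events`.
- Downloading from NLM or the citation-collection publisher is outside
  the package; callers supply local files and release labels.
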