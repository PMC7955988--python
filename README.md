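# medlinedb

Build and incrementally maintain a **relational database of PubMed/MEDLINE**
article metadata from the XML files NLM distributes in bulk, plus the NIH
Open Citation Collection edge list.

PubMed's E-utilities API suits small, specific queries; large-scale
bibliometric and meta-research analyses ("how many authors per paper over
time?", "which articles cite a given trial?") need the whole corpus in a
form that supports joins. NLM ships that corpus as an annual **baseline**
of deeply nested XML files and **daily update files** carrying new, revised
and deleted records. `medlinedb` turns these into flat tables — one per
data type (`pub`, `author`, `author_identifier`, `pub_history`,
`mesh_term`, `journal`, …) — linked by PMID, and keeps the database current
as update files arrive.

## The method

**Schema.** Each data type extracted from a `PubmedArticleSet` document is
its own table whose rows begin with `(pmid, version)`; the `Version`
attribute of a PMID distinguishes revisions of the same record (most PMIDs
only ever have version 1). A `xml_processed` ledger records every source
file and when it was processed.

**Baseline build.** Every baseline file is stream-parsed
(`lxml.etree.iterparse`, elements freed as consumed, so memory is bounded
by one article rather than the file), appended and logged in one
transaction per file, in file-sequence order. Afterwards every versioned
table is reduced so that only each PMID's **latest version** remains. The
ledger makes interrupted builds resumable.

**Incremental update.** Update files are parsed into staging twins of the
main tables, each row tagged with its source file. Per PMID the pipeline
resolves the *most recent* data — maximal version, ties broken by file
order — then, in one transaction, deletes the PMID's old rows from every
table and appends exactly the winning rows. A PMID whose last event is a
`DeleteCitation` notice is tombstoned: all rows removed, nothing appended.
Re-running on processed files is a no-op.

**Citations.** The open-citation CSV (citing PMID → cited PMID) loads into
a shadow table swapped in atomically, and is refreshed whenever the
upstream release label changes.

Because the real corpus (tens of millions of PMIDs) cannot be rebuilt at
desk scale, correctness rests on a synthetic corpus generator plus an
independent **replay oracle**: random scripts of create/update/delete
events are rendered to schema-valid XML, pushed through the pipelines, and
the resulting database state must equal the oracle's straightforward
per-event replay — table by table, row multiset by row multiset.

## Worked example

```sh
# generate a synthetic corpus: 2 baseline + 3 update files, 40 PMIDs
medlinedb simulate --out corpus --seed 3 --pmids 40

medlinedb create --dir corpus/baseline --db pm.db
# files processed: 2
# rows removed by version reduction: 0
# ...
# author	85
# pub	33
# pub_history	81

medlinedb update --dir corpus/updatefiles --db pm.db
# updated: 17 pmid(s)
# deleted: 8 pmid(s)
# rows deleted: 261
# pub	+17
# ...
```

After the update the database holds each surviving PMID's most recent
revision only; the eight deleted PMIDs have no rows anywhere. The example
analyses then run as plain queries:

```sh
medlinedb query authors-by-year --db pm.db --start 1950 --end 2024
# year	n_pubs	mean	median	q1	q3
# 1950	1	4.0	4.0	4.0	4.0
# 1951	1	4.0	4.0	4.0	4.0
# 1952	1	1.0	1.0	1.0	1.0
# ...
```

one row per year of database entry: how many publications, and the mean,
median and quartiles of authors per publication, and

```sh
medlinedb query orcid-by-month --db pm.db --start 1950-01 --end 2024-12
# month	n_author_names	n_with_orcid	percent
# 1950-05	4	3	75.0
# 1951-05	4	3	75.0
# ...
```

the percentage of author names carrying an ORCID identifier per month
(joining `pub_history`, `author` and `author_identifier` on
`(pmid, author_pos)`). On real data, note that records created 1984–1995
kept at most 10 authors and 1996–1999 at most 25, which biases the mean —
not the median or IQR — in those years.

The same operations are available as library functions
(`medlinedb.build_baseline`, `medlinedb.update_database`,
`medlinedb.load_citations`, `medlinedb.authors_per_pub_by_year`, …).

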