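"""medlinedb: build and incrementally maintain a relational database of
PubMed/MEDLINE article metadata.

The pipeline stream-parses ``PubmedArticleSet`` XML files into per-data-type
tables linked by PMID, reduces each PMID to its latest version, applies
daily update files through staged delete-and-append merges with tombstone
deletion, and loads the open-citation edge list alongside.
"""

from .build import BuildReport, build_baseline, keep_latest
from .citations import (
    CitationLoadReport,
    SourceVersionTag,
    load_citations,
    needs_refresh,
)
from .db import Database, FileLogEntry, database_state, init_tables, unprocessed
from .ingest import RecordBatch, parse_deletions, parse_file
from .registry import REGISTRY, TableSpec, VERSIONED_TABLES
from .update import ChangeReport, UpdatePlan, resolve_plan, update_database

__version__ = "0.1.0"


def __getattr__(name):
    # deferred: the query layer pulls in pandas, which the parse and build
    # paths never need
    if name in ("authors_per_pub_by_year", "orcid_fraction_by_month"):
        from . import queries

        return getattr(queries, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")

__all__ = [
    "BuildReport",
    "ChangeReport",
    "CitationLoadReport",
    "Database",
    "FileLogEntry",
    "REGISTRY",
    "RecordBatch",
    "SourceVersionTag",
    "TableSpec",
    "UpdatePlan",
    "VERSIONED_TABLES",
    "authors_per_pub_by_year",
    "build_baseline",
    "database_state",
    "init_tables",
    "keep_latest",
    "load_citations",
    "needs_refresh",
    "orcid_fraction_by_month",
    "parse_deletions",
    "parse_file",
    "resolve_plan",
    "unprocessed",
    "update_database",
]
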