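"""Load the open-citation edge list (citing PMID → cited PMID) into the DB.

The NIH Open Citation Collection ships as a two-column CSV with a header
row; each release carries a version label.  The table is replaced
wholesale whenever the label changes: rows land in a shadow table that is
swapped in only on success, so a failed load leaves the previous edges
untouched and readers never see a half-loaded table.
"""

from __future__ import annotations

import csv
import datetime as _dt
import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path

from .db import Database

logger = logging.getLogger(__name__)

_SHADOW = "citation_shadow"
_CHUNK = 50_000


@dataclass(frozen=True)
class SourceVersionTag:
    """Release label of the loaded citation collection and when it was fetched."""

    version_label: str
    retrieved_at: _dt.datetime

    def __post_init__(self) -> None:
        if not self.version_label:
            raise ValueError("version_label must be non-empty")


@dataclass
class CitationLoadReport:
    edges_loaded: int = 0
    lines_skipped: int = 0
    self_citations: int = 0


def needs_refresh(
    current: SourceVersionTag | None, candidate: SourceVersionTag
) -> bool:
    """True iff nothing is loaded yet or the release label changed.

    Labels are compared for inequality only; ordering upstream releases is
    the publisher's business, not ours.
    """
    return current is None or current.version_label != candidate.version_label


def current_tag(db: Database) -> SourceVersionTag | None:
    if not db.has_table("citation_version"):
        return None
    row = db.fetchone("SELECT version_label, retrieved_at FROM citation_version")
    if row is None:
        return None
    return SourceVersionTag(row[0], _dt.datetime.fromisoformat(row[1]))


def _open_text(csv_source):
    if isinstance(csv_source, (str, Path)):
        stream = open(csv_source, "rb")
    else:
        stream = csv_source
    if hasattr(stream, "read") and not hasattr(stream, "peek"):
        try:
            stream = io.BufferedReader(stream)
        except Exception:
            pass
    if hasattr(stream, "peek") and stream.peek(2)[:2] == b"\x1f\x8b":
        stream = gzip.GzipFile(fileobj=stream)
    if isinstance(stream, io.TextIOBase):
        return stream
    return io.TextIOWrapper(stream, encoding="utf-8")


def load_citations(
    csv_source, db: Database, tag: SourceVersionTag
) -> CitationLoadReport:
    """Replace the ``citation`` table with the edges in ``csv_source``.

    The source is a comma-delimited file (optionally gzip) whose header row
    is skipped.  Lines that do not hold two positive integers are skipped
    and counted, never fatal; self-citations load normally but are flagged
    in the report.  The whole load is atomic: prior contents survive any
    failure.
    """
    text = _open_text(csv_source)
    report = CitationLoadReport()
    with db.transaction():
        db.drop_table(_SHADOW)
        types = db.column_types()
        db.execute(
            f"CREATE TABLE {_SHADOW} "
            f"(citing_pmid {types['integer']}, cited_pmid {types['integer']})"
        )
        reader = csv.reader(text)
        next(reader, None)  # header
        chunk: list[tuple[int, int]] = []

        def flush() -> None:
            if chunk:
                db.executemany(
                    f"INSERT INTO {_SHADOW} (citing_pmid, cited_pmid) VALUES (?, ?)",
                    chunk,
                )
                chunk.clear()

        for line in reader:
            fields = [f.strip() for f in line if f.strip() != ""]
            if len(fields) != 2 or not all(f.isdigit() for f in fields):
                report.lines_skipped += 1
                continue
            citing, cited = int(fields[0]), int(fields[1])
            if citing < 1 or cited < 1:
                report.lines_skipped += 1
                continue
            if citing == cited:
                report.self_citations += 1
            chunk.append((citing, cited))
            report.edges_loaded += 1
            if len(chunk) >= _CHUNK:
                flush()
        flush()
        db.drop_table("citation")
        db.rename_table(_SHADOW, "citation")
        db.execute("DELETE FROM citation_version")
        ts = tag.retrieved_at
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=_dt.timezone.utc)
        db.execute(
            "INSERT INTO citation_version (version_label, retrieved_at) VALUES (?, ?)",
            (tag.version_label, ts.isoformat()),
        )
    if report.self_citations:
        logger.info("flagged %d self-citation edge(s)", report.self_citations)
    return report


def refresh_citations(
    csv_source, db: Database, candidate: SourceVersionTag
) -> CitationLoadReport | None:
    """Load only if the candidate release differs from what is stored."""
    if not needs_refresh(current_tag(db), candidate):
        logger.info("citation collection %s already loaded", candidate.version_label)
        return None
    return load_citations(csv_source, db, candidate)
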