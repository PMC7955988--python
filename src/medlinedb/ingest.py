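"""Streaming parse of PubMed/MEDLINE XML into per-data-type row sets.

A baseline or post-baseline file is one ``PubmedArticleSet`` document, and
can hold tens of thousands of ``PubmedArticle`` elements plus (in
post-baseline files) a ``DeleteCitation`` element listing removed PMIDs.
:func:`parse_file` walks the document with :func:`lxml.etree.iterparse`,
freeing each article element as soon as its rows are extracted, so peak
memory is bounded by the largest single article rather than the file.

This module emits :class:`RecordBatch` values only; it never touches the
database.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterator

from lxml import etree

from .registry import VERSIONED_TABLES

logger = logging.getLogger(__name__)


class ParseError(RuntimeError):
    """The document is not well-formed XML."""


class RecordError(RuntimeError):
    """One article record is structurally unusable (e.g. no PMID)."""


@dataclass
class RecordBatch:
    """Parsed content of one source file.

    ``rows_by_table`` maps every versioned registry table to its rows (an
    empty list when the file holds none); each row is a flat column→value
    dict carrying ``pmid`` and ``version``.  ``deleted_pmids`` lists the
    PMIDs under the file's ``DeleteCitation`` element, in document order.
    """

    source_file: str
    rows_by_table: dict[str, list[dict]] = field(default_factory=dict)
    deleted_pmids: list[int] = field(default_factory=list)

    def row_count(self, table: str) -> int:
        return len(self.rows_by_table.get(table, ()))


# -- small field normalizers ----------------------------------------------

_ORCID_URL_RE = re.compile(r"^\s*https?://(?:www\.)?orcid\.org/", re.IGNORECASE)
_ORCID_RE = re.compile(r"^(\d{4})-?(\d{4})-?(\d{4})-?(\d{3}[0-9Xx])$")

_MONTH_NAMES = {
    name: i
    for i, name in enumerate(
        "jan feb mar apr may jun jul aug sep oct nov dec".split(), start=1
    )
}


def normalize_orcid(raw: str) -> str:
    """Canonical 19-character dashed ORCID; unparseable values pass through.

    Strips any ``https://orcid.org/`` prefix and uppercases the final check
    character (which may be ``X``).  Values that do not look like a 16-digit
    ORCID are returned verbatim so nothing is lost.
    """
    s = _ORCID_URL_RE.sub("", raw).strip()
    m = _ORCID_RE.match(s)
    if not m:
        return raw.strip()
    a, b, c, d = m.groups()
    return f"{a}-{b}-{c}-{d.upper()}"


def _parse_history_date(el: etree._Element, pmid: int) -> tuple[str | None, str | None]:
    """(ISO date, precision) from a Year/Month/Day element triple.

    Missing day (or month) is padded with 1 and flagged via the precision
    column (``day`` / ``month`` / ``year``) so the date stays sortable
    without inventing precision.  Invalid dates yield (None, None) with a
    warning.
    """
    year = _child_text(el, "Year")
    month = _child_text(el, "Month")
    day = _child_text(el, "Day")
    if year is None:
        logger.warning("pmid %d: history date without Year; stored null", pmid)
        return None, None
    try:
        y = int(year)
        if month is None:
            m, d, precision = 1, 1, "year"
        else:
            m = _MONTH_NAMES.get(month[:3].lower(), None)
            if m is None:
                m = int(month)
            if day is None:
                d, precision = 1, "month"
            else:
                d, precision = int(day), "day"
        import datetime

        iso = datetime.date(y, m, d).isoformat()
    except ValueError:
        logger.warning(
            "pmid %d: invalid history date (%r, %r, %r); stored null",
            pmid,
            year,
            month,
            day,
        )
        return None, None
    return iso, precision


def _child_text(el: etree._Element, tag: str) -> str | None:
    child = el.find(tag)
    if child is None:
        return None
    text = "".join(child.itertext()).strip()
    return text or None


def _element_text(el: etree._Element | None) -> str | None:
    if el is None:
        return None
    text = "".join(el.itertext()).strip()
    return text or None


# -- per-article extraction ------------------------------------------------


def extract_article_tables(article: etree._Element) -> dict[str, list[dict]]:
    """Rows for one ``PubmedArticle`` element, keyed by table name.

    Only data types present in the article appear in the result; every row
    shares the article's (pmid, version).  A row whose mandatory
    sub-elements are missing is dropped with a warning rather than emitted
    with null key columns.
    """
    citation = article.find("MedlineCitation")
    pmid_el = citation.find("PMID") if citation is not None else None
    if pmid_el is None or not (pmid_el.text or "").strip():
        raise RecordError("article has no readable PMID element")
    pmid = int(pmid_el.text.strip())
    version = int(pmid_el.get("Version", "1"))
    base = {"pmid": pmid, "version": version}

    out: dict[str, list[dict]] = {}

    def add(table: str, **cols) -> None:
        out.setdefault(table, []).append({**base, **cols})

    art = citation.find("Article")

    # pub: one row per article, unconditionally
    add(
        "pub",
        title=_element_text(art.find("ArticleTitle")) if art is not None else None,
        language=_child_text(art, "Language") if art is not None else None,
    )

    if art is not None:
        journal = art.find("Journal")
        if journal is not None:
            issue = journal.find("JournalIssue")
            add(
                "journal",
                journal_name=_child_text(journal, "Title"),
                issn=_child_text(journal, "ISSN"),
                volume=_child_text(issue, "Volume") if issue is not None else None,
                issue=_child_text(issue, "Issue") if issue is not None else None,
            )

        author_list = art.find("AuthorList")
        if author_list is not None:
            pos = 0
            for author in author_list.iterfind("Author"):
                last = _child_text(author, "LastName")
                collective = _child_text(author, "CollectiveName")
                if last is None and collective is None:
                    logger.warning(
                        "pmid %d: author without LastName or CollectiveName "
                        "dropped",
                        pmid,
                    )
                    continue
                pos += 1
                add(
                    "author",
                    author_pos=pos,
                    last_name=last,
                    fore_name=_child_text(author, "ForeName") if last else None,
                    initials=_child_text(author, "Initials") if last else None,
                    suffix=_child_text(author, "Suffix") if last else None,
                    collective_name=collective if last is None else None,
                )
                for ident in author.iterfind("Identifier"):
                    value = _element_text(ident)
                    if value is None:
                        continue
                    source = ident.get("Source", "")
                    add(
                        "author_identifier",
                        author_pos=pos,
                        identifier_source=source,
                        identifier=normalize_orcid(value)
                        if source.upper() == "ORCID"
                        else value,
                    )

        abstract = art.find("Abstract")
        if abstract is not None:
            parts = []
            for para in abstract.iterfind("AbstractText"):
                text = _element_text(para)
                if text is None:
                    continue
                label = para.get("Label")
                parts.append(f"{label}: {text}" if label else text)
            if parts:
                add("abstract", text=" ".join(parts))

        grants = art.find("GrantList")
        if grants is not None:
            for g in grants.iterfind("Grant"):
                add(
                    "grant_item",
                    grant_id=_child_text(g, "GrantID"),
                    agency=_child_text(g, "Agency"),
                    country=_child_text(g, "Country"),
                )

        ptl = art.find("PublicationTypeList")
        if ptl is not None:
            for pt in ptl.iterfind("PublicationType"):
                name = _element_text(pt)
                if name is None:
                    continue
                add("pub_type", type_name=name, ui=pt.get("UI"))

        dbl = art.find("DataBankList")
        if dbl is not None:
            for bank in dbl.iterfind("DataBank"):
                bank_name = _child_text(bank, "DataBankName")
                accs = bank.find("AccessionNumberList")
                numbers = (
                    [_element_text(a) for a in accs.iterfind("AccessionNumber")]
                    if accs is not None
                    else []
                )
                numbers = [n for n in numbers if n] or [None]
                for n in numbers:
                    add("data_bank", data_bank_name=bank_name, accession_number=n)

    mesh_list = citation.find("MeshHeadingList")
    if mesh_list is not None:
        for heading in mesh_list.iterfind("MeshHeading"):
            desc = heading.find("DescriptorName")
            term = _element_text(desc)
            if term is None:
                logger.warning("pmid %d: MeshHeading without descriptor dropped", pmid)
                continue
            add(
                "mesh_term",
                term=term,
                ui=desc.get("UI"),
                major_topic=desc.get("MajorTopicYN") == "Y",
            )

    for kw_list in citation.iterfind("KeywordList"):
        for kw in kw_list.iterfind("Keyword"):
            text = _element_text(kw)
            if text is not None:
                add("keyword", keyword=text)

    chem_list = citation.find("ChemicalList")
    if chem_list is not None:
        for chem in chem_list.iterfind("Chemical"):
            substance = chem.find("NameOfSubstance")
            add(
                "chemical",
                registry_number=_child_text(chem, "RegistryNumber"),
                substance=_element_text(substance),
                ui=substance.get("UI") if substance is not None else None,
            )

    inv_list = citation.find("InvestigatorList")
    if inv_list is not None:
        for pos, inv in enumerate(inv_list.iterfind("Investigator"), start=1):
            add(
                "investigator",
                investigator_pos=pos,
                last_name=_child_text(inv, "LastName"),
                fore_name=_child_text(inv, "ForeName"),
                initials=_child_text(inv, "Initials"),
            )

    cc_list = citation.find("CommentsCorrectionsList")
    if cc_list is not None:
        for cc in cc_list.iterfind("CommentsCorrections"):
            ref = _child_text(cc, "PMID")
            add(
                "comment_correction",
                ref_type=cc.get("RefType"),
                ref_pmid=int(ref) if ref else None,
            )

    pubmed_data = article.find("PubmedData")
    if pubmed_data is not None:
        history = pubmed_data.find("History")
        if history is not None:
            for event in history.iterfind("PubMedPubDate"):
                status = event.get("PubStatus")
                if not status:
                    logger.warning("pmid %d: history event without PubStatus dropped", pmid)
                    continue
                date, precision = _parse_history_date(event, pmid)
                add(
                    "pub_history",
                    pub_status=status,
                    event_date=date,
                    date_precision=precision,
                )
        id_list = pubmed_data.find("ArticleIdList")
        if id_list is not None:
            for aid in id_list.iterfind("ArticleId"):
                value = _element_text(aid)
                if value is None:
                    continue
                add("article_id", id_type=aid.get("IdType"), id_value=value)

    return out


# -- whole-file streaming parse -------------------------------------------


def _open_source(xml_source) -> BinaryIO:
    """Binary stream over ``xml_source`` (path or file object), gzip-sniffed."""
    if isinstance(xml_source, (str, Path)):
        stream: BinaryIO = open(xml_source, "rb")
    else:
        stream = xml_source
    if not isinstance(stream, io.BufferedReader) and not hasattr(stream, "peek"):
        stream = io.BufferedReader(stream)  # type: ignore[arg-type]
    if stream.peek(2)[:2] == b"\x1f\x8b":
        return gzip.GzipFile(fileobj=stream)  # type: ignore[return-value]
    return stream


def _iter_top_level(stream: BinaryIO, file_name: str) -> Iterator[etree._Element]:
    """Yield each direct child of the article-set root, then free it."""
    context = etree.iterparse(stream, events=("end",), recover=False)
    try:
        for _, elem in context:
            parent = elem.getparent()
            if parent is None or parent.getparent() is not None:
                continue
            yield elem
            # free the subtree and any exhausted preceding siblings
            elem.clear()
            while elem.getprevious() is not None:
                del parent[0]
    except etree.XMLSyntaxError as exc:
        line, col = exc.position
        raise ParseError(
            f"{file_name}: malformed XML at line {line}, column {col}: {exc.msg}"
        ) from exc


def _default_name(xml_source, file_name: str | None) -> str:
    if file_name is not None:
        return file_name
    return Path(xml_source).name if isinstance(xml_source, (str, Path)) else "<stream>"


def parse_events(
    xml_source, file_name: str | None = None
) -> Iterator[tuple[str, object]]:
    """Streaming event feed over one file: the primitive the pipelines consume.

    Yields ``("article", tables)`` for each ``PubmedArticle`` in document
    order (``tables`` as from :func:`extract_article_tables`) and
    ``("delete", pmids)`` for each ``DeleteCitation`` element.  Elements are
    freed as soon as they are consumed, so memory stays bounded by the
    largest single article no matter how long the file is.  Unknown
    top-level elements are skipped with a warning; an article without a
    readable PMID raises :class:`RecordError` naming its index.
    """
    file_name = _default_name(xml_source, file_name)
    stream = _open_source(xml_source)
    n_articles = 0
    for elem in _iter_top_level(stream, file_name):
        tag = elem.tag
        if tag == "PubmedArticle":
            n_articles += 1
            try:
                tables = extract_article_tables(elem)
            except RecordError as exc:
                raise RecordError(
                    f"{file_name}: article #{n_articles}: {exc}"
                ) from None
            yield "article", tables
        elif tag == "DeleteCitation":
            pmids = []
            for pmid_el in elem.iterfind("PMID"):
                text = (pmid_el.text or "").strip()
                if text:
                    pmids.append(int(text))
            yield "delete", pmids
        else:
            logger.warning(
                "%s: skipping unknown top-level element <%s>", file_name, tag
            )


def iter_article_tables(
    xml_source, file_name: str | None = None
) -> Iterator[dict[str, list[dict]]]:
    """Per-article table→rows maps in document order (deletions skipped)."""
    for kind, payload in parse_events(xml_source, file_name):
        if kind == "article":
            yield payload  # type: ignore[misc]


def parse_file(xml_source, file_name: str | None = None) -> RecordBatch:
    """Parse one baseline or post-baseline file into a :class:`RecordBatch`.

    ``xml_source`` is a path or a readable binary stream; gzip input is
    detected by magic bytes.  If one PMID occurs more than once in the file,
    its last occurrence in document order wins (matching the pipelines'
    most-recent rule).  This materializes every row of the file; pipelines
    that must stay within a memory budget consume :func:`parse_events` in
    chunks instead.
    """
    file_name = _default_name(xml_source, file_name)
    per_pmid: dict[int, dict[str, list[dict]]] = {}
    deleted: list[int] = []
    for kind, payload in parse_events(xml_source, file_name):
        if kind == "article":
            pmid = payload["pub"][0]["pmid"]  # type: ignore[index]
            per_pmid[pmid] = payload  # type: ignore[assignment]
        else:
            deleted.extend(payload)  # type: ignore[arg-type]

    rows_by_table: dict[str, list[dict]] = {t: [] for t in VERSIONED_TABLES}
    for tables in per_pmid.values():
        for table, rows in tables.items():
            rows_by_table[table].extend(rows)
    return RecordBatch(
        source_file=file_name, rows_by_table=rows_by_table, deleted_pmids=deleted
    )


def parse_deletions(xml_source, file_name: str | None = None) -> list[int]:
    """PMIDs under the file's ``DeleteCitation`` element, in document order."""
    deleted: list[int] = []
    for kind, payload in parse_events(xml_source, file_name):
        if kind == "delete":
            deleted.extend(payload)  # type: ignore[arg-type]
    return deleted
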