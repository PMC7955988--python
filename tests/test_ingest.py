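"""Streaming XML parse: row extraction, normalization, error handling."""

import gzip
import io
import logging
import re
import xml.etree.ElementTree as stdlib_etree

import pytest
from hypothesis import given
from hypothesis import strategies as st

from medlinedb import fixtures as fx
from medlinedb.ingest import (
    ParseError,
    RecordError,
    extract_article_tables,
    normalize_orcid,
    parse_deletions,
    parse_file,
)
from medlinedb.registry import VERSIONED_TABLES

from lxml import etree


def article_xml(body: str, pmid: int = 1, version: str | None = None) -> bytes:
    vattr = f' Version="{version}"' if version is not None else ""
    return (
        "<PubmedArticleSet><PubmedArticle><MedlineCitation>"
        f"<PMID{vattr}>{pmid}</PMID>{body}"
        "</MedlineCitation></PubmedArticle></PubmedArticleSet>"
    ).encode()


def test_empty_article_set(tmp_path):
    path = tmp_path / "pubmed26n0001.xml.gz"
    fx.write_file(path, [], [])
    batch = parse_file(path)
    assert set(batch.rows_by_table) == set(VERSIONED_TABLES)
    assert all(rows == [] for rows in batch.rows_by_table.values())
    assert batch.deleted_pmids == []


def test_author_rows_counted_by_independent_path_walk(tmp_path):
    """Fixture with 2 articles x 3 authors: row counts match a stdlib walk."""
    sizes = fx.PayloadSizes(authors=3, orcids=0)
    path = tmp_path / "pubmed26n0001.xml.gz"
    fx.write_file(path, [(11, 1, sizes), (22, 1, sizes)], seed=3)
    batch = parse_file(path)

    # independent oracle: element counting with the stdlib parser
    tree = stdlib_etree.parse(gzip.open(path))
    oracle_authors = len(tree.findall(".//AuthorList/Author"))
    assert oracle_authors == 6
    assert len(batch.rows_by_table["author"]) == oracle_authors
    for pmid in (11, 22):
        positions = {
            r["author_pos"]
            for r in batch.rows_by_table["author"]
            if r["pmid"] == pmid
        }
        assert positions == {1, 2, 3}


@pytest.mark.parametrize(
    "version_attr, expected",
    [(None, 1), ("1", 1), ("2", 2)],
)
def test_pmid_version_attribute_default(version_attr, expected):
    # the document type declares Version's default as "1"
    batch = parse_file(io.BytesIO(article_xml("", pmid=9, version=version_attr)))
    assert batch.rows_by_table["pub"][0]["version"] == expected


def test_duplicate_pmid_last_occurrence_wins(tmp_path):
    first = fx.PayloadSizes(authors=4, orcids=0)
    second = fx.PayloadSizes(authors=1, orcids=0)
    path = tmp_path / "pubmed26n0001.xml.gz"
    fx.write_file(path, [(5, 1, first), (5, 1, second)], seed=0)
    batch = parse_file(path)
    assert len(batch.rows_by_table["pub"]) == 1
    assert len(batch.rows_by_table["author"]) == 1


def test_collective_author_name():
    body = (
        "<Article><AuthorList><Author>"
        "<CollectiveName>Trial Group</CollectiveName>"
        "</Author></AuthorList></Article>"
    )
    batch = parse_file(io.BytesIO(article_xml(body)))
    (row,) = batch.rows_by_table["author"]
    assert row["collective_name"] == "Trial Group"
    assert row["last_name"] is None


def test_article_without_author_list_has_no_author_table():
    root = etree.fromstring(article_xml("<Article/>"))
    tables = extract_article_tables(root.find("PubmedArticle"))
    assert "author" not in tables
    assert len(tables["pub"]) == 1


def test_one_author_one_orcid_positions_match():
    body = (
        "<Article><AuthorList><Author><LastName>Park</LastName>"
        "<Identifier Source=\"ORCID\">0000-0002-1825-0097</Identifier>"
        "</Author></AuthorList></Article>"
    )
    batch = parse_file(io.BytesIO(article_xml(body)))
    (author,) = batch.rows_by_table["author"]
    (ident,) = batch.rows_by_table["author_identifier"]
    assert ident["author_pos"] == author["author_pos"] == 1
    assert ident["identifier"] == "0000-0002-1825-0097"


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("https://orcid.org/0000-0002-1825-0097", "0000-0002-1825-0097"),
        ("http://www.orcid.org/0000-0002-1825-0097", "0000-0002-1825-0097"),
        ("0000000218250097", "0000-0002-1825-0097"),
        ("0000-0001-5109-372x", "0000-0001-5109-372X"),
        ("not-an-orcid", "not-an-orcid"),  # unparseable: kept verbatim
    ],
)
def test_orcid_normalization(raw, expected):
    assert normalize_orcid(raw) == expected


def test_history_date_missing_day_padded_and_flagged():
    body = ""
    xml = (
        "<PubmedArticleSet><PubmedArticle><MedlineCitation><PMID>4</PMID>"
        "</MedlineCitation><PubmedData><History>"
        "<PubMedPubDate PubStatus=\"entrez\"><Year>2019</Year><Month>7</Month>"
        "</PubMedPubDate></History></PubmedData></PubmedArticle>"
        "</PubmedArticleSet>"
    ).encode()
    batch = parse_file(io.BytesIO(xml))
    (row,) = batch.rows_by_table["pub_history"]
    assert row["event_date"] == "2019-07-01"
    assert row["date_precision"] == "month"


def test_invalid_history_date_stored_null_with_warning(caplog):
    xml = (
        "<PubmedArticleSet><PubmedArticle><MedlineCitation><PMID>4</PMID>"
        "</MedlineCitation><PubmedData><History>"
        "<PubMedPubDate PubStatus=\"entrez\"><Year>2019</Year><Month>0</Month>"
        "<Day>5</Day></PubMedPubDate></History></PubmedData></PubmedArticle>"
        "</PubmedArticleSet>"
    ).encode()
    with caplog.at_level(logging.WARNING, logger="medlinedb"):
        batch = parse_file(io.BytesIO(xml))
    (row,) = batch.rows_by_table["pub_history"]
    assert row["event_date"] is None and row["date_precision"] is None
    assert any("invalid history date" in r.message for r in caplog.records)


def test_missing_pmid_is_record_error_with_index():
    xml = (
        "<PubmedArticleSet>"
        "<PubmedArticle><MedlineCitation><PMID>1</PMID></MedlineCitation>"
        "</PubmedArticle>"
        "<PubmedArticle><MedlineCitation></MedlineCitation></PubmedArticle>"
        "</PubmedArticleSet>"
    ).encode()
    with pytest.raises(RecordError, match=r"article #2"):
        parse_file(io.BytesIO(xml), "f.xml")


def test_malformed_xml_names_file_and_position():
    xml = b"<PubmedArticleSet><PubmedArticle></PubmedArticleSet>"
    with pytest.raises(ParseError, match=r"broken\.xml.*line \d+"):
        parse_file(io.BytesIO(xml), "broken.xml")


def test_unknown_top_level_element_skipped_with_warning(caplog):
    xml = (
        "<PubmedArticleSet><BookDocument><PMID>7</PMID></BookDocument>"
        "<PubmedArticle><MedlineCitation><PMID>1</PMID></MedlineCitation>"
        "</PubmedArticle></PubmedArticleSet>"
    ).encode()
    with caplog.at_level(logging.WARNING, logger="medlinedb"):
        batch = parse_file(io.BytesIO(xml))
    assert [r["pmid"] for r in batch.rows_by_table["pub"]] == [1]
    assert any("BookDocument" in r.message for r in caplog.records)


def test_gzip_detected_by_magic_bytes(tmp_path):
    xml = article_xml("", pmid=3)
    plain = parse_file(io.BytesIO(xml))
    gz = parse_file(io.BytesIO(gzip.compress(xml)))
    assert plain.rows_by_table == gz.rows_by_table


def test_parse_deletions(tmp_path):
    path = tmp_path / "pubmed26n0002.xml.gz"
    fx.write_file(path, [(1, 1, fx.PayloadSizes())], deletions=[11, 12], seed=1)
    assert parse_deletions(path) == [11, 12]
    # independent oracle: regex over the raw text of the deletion element
    text = gzip.open(path).read().decode()
    block = re.search(r"<DeleteCitation>(.*?)</DeleteCitation>", text, re.S).group(1)
    assert [int(m) for m in re.findall(r"<PMID[^>]*>(\d+)</PMID>", block)] == [11, 12]

    baseline = tmp_path / "pubmed26n0001.xml.gz"
    fx.write_file(baseline, [(1, 1, fx.PayloadSizes())], seed=1)
    assert parse_deletions(baseline) == []


def test_parse_is_deterministic(tmp_path):
    script = fx.random_script(12, n_pmids=15)
    (path, *_) = fx.generate(script, tmp_path)
    a = parse_file(path)
    b = parse_file(path)
    assert a.rows_by_table == b.rows_by_table
    assert a.deleted_pmids == b.deleted_pmids


def test_author_identifier_referential_closure(tmp_path):
    script = fx.random_script(21, n_pmids=30)
    for path in fx.generate(script, tmp_path):
        batch = parse_file(path)
        authors = {
            (r["pmid"], r["version"], r["author_pos"])
            for r in batch.rows_by_table["author"]
        }
        for r in batch.rows_by_table["author_identifier"]:
            assert (r["pmid"], r["version"], r["author_pos"]) in authors


@st.composite
def payload_sizes(draw):
    authors = draw(st.integers(1, 5))
    return fx.PayloadSizes(
        authors=authors,
        orcids=draw(st.integers(0, authors)),
        history=draw(st.integers(1, 5)),
        mesh=draw(st.integers(0, 4)),
        keywords=draw(st.integers(0, 3)),
        grants=draw(st.integers(0, 2)),
        collective=draw(st.booleans()),
    )


@given(
    pmid=st.integers(1, 10**7),
    version=st.integers(1, 4),
    seed=st.integers(0, 100),
    sizes=payload_sizes(),
)
def test_round_trip_article_render_then_parse(pmid, version, seed, sizes):
    """Parsing a rendered article reproduces the declared rows exactly."""
    element = fx.build_article_element(seed, pmid, version, sizes)
    doc = b"<PubmedArticleSet>" + etree.tostring(element) + b"</PubmedArticleSet>"
    batch = parse_file(io.BytesIO(doc))
    expected, _ = fx.article_payload(seed, pmid, version, sizes)
    for table, rows in expected.items():
        assert batch.rows_by_table[table] == rows, table
    for table in set(VERSIONED_TABLES) - set(expected):
        assert batch.rows_by_table[table] == []
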