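"""Reading and writing the extended-BibTeX dialect used for article records.

Metasearch exports carry abbreviated article records as ``@article`` entries
whose values may be wrapped in straight quotes (``"..."``), typographic quotes
(``“...”``) or braces (``{...}``), extended with the identifier
fields ``PMID``, ``DOI``, ``ISSN`` and ``EISSN`` on top of the usual
Author/Title/Journal/Year/Volume/Number/Pages set.  Parsing is deliberately
forgiving: a malformed entry is skipped with a logged warning (losing a
record silently would hurt retrieval recall), and unknown fields are kept in
an opaque ``extras`` map so that parse/write round-trips are lossless.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Source databases a record can be tagged with.
SOURCES = ("pubmed", "embase", "cinahl", "psycinfo", "cochrane", "other")

_KNOWN_FIELDS = {
    "author", "title", "journal", "year", "volume", "number", "issue",
    "pages", "pmid", "doi", "issn", "eissn", "source",
}

# value delimiters: opener -> closer
_DELIMS = {'"': '"', "“": "”", "{": "}"}

_PUBMED_KEY = re.compile(r"^PUBMED(\d+)$", re.IGNORECASE)


@dataclass
class BibRecord:
    """One parsed article record tagged with its source database."""

    record_id: str
    source: str = "other"
    pmid: str | None = None
    doi: str | None = None
    issn: str | None = None
    eissn: str | None = None
    journal: str | None = None
    title: str | None = None
    authors: list[str] | None = None
    year: int | None = None
    volume: str | None = None
    issue: str | None = None
    pages: str | None = None
    extras: dict[str, str] = field(default_factory=dict)


class _Scanner:
    """Minimal cursor over the raw text, tracking offsets for diagnostics."""

    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0

    def eof(self) -> bool:
        return self.pos >= len(self.text)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while not self.eof() and self.text[self.pos].isspace():
            self.pos += 1

    def read_word(self) -> str:
        start = self.pos
        while not self.eof() and (self.text[self.pos].isalnum()
                                  or self.text[self.pos] in "_-:."):
            self.pos += 1
        return self.text[start:self.pos]

    def read_value(self) -> str:
        """Read one field value: delimited (quotes/braces) or bare."""
        ch = self.peek()
        if ch in _DELIMS:
            closer = _DELIMS[ch]
            self.pos += 1
            start = self.pos
            depth = 1
            while not self.eof():
                c = self.text[self.pos]
                if ch == "{":
                    if c == "{":
                        depth += 1
                    elif c == "}":
                        depth -= 1
                        if depth == 0:
                            break
                elif c == closer:
                    break
                self.pos += 1
            if self.eof():
                raise ValueError("unterminated value")
            value = self.text[start:self.pos]
            self.pos += 1  # consume closer
            return value
        # bare value: up to comma or closing brace
        start = self.pos
        while not self.eof() and self.text[self.pos] not in ",}":
            self.pos += 1
        return self.text[start:self.pos].strip()


def _strip_outer_braces(value: str) -> str:
    v = value.strip()
    if len(v) >= 2 and v[0] == "{" and v[-1] == "}":
        return v[1:-1].strip()
    return v


def _clean(value: str) -> str | None:
    v = value.strip()
    return v or None


def _build_record(key: str, fields: dict[str, str], source: str) -> BibRecord:
    rec = BibRecord(record_id=key, source=source)
    for name, raw in fields.items():
        lname = name.lower()
        value = _clean(raw)
        if lname not in _KNOWN_FIELDS:
            if value is not None:
                rec.extras[name] = value
            continue
        if value is None:
            continue
        if lname == "author":
            authors = [a.strip() for a in value.split(" and ")]
            authors = [a for a in authors if a]
            rec.authors = authors or None
        elif lname == "title":
            rec.title = _clean(_strip_outer_braces(value))
        elif lname == "journal":
            rec.journal = value
        elif lname == "year":
            try:
                year = int(value)
            except ValueError:
                year = -1
            if 1000 <= year <= 9999:
                rec.year = year
            else:
                logger.warning("record %s: unparseable Year %r", key, value)
                rec.extras[name] = value
        elif lname == "volume":
            rec.volume = value
        elif lname in ("number", "issue"):
            rec.issue = value
        elif lname == "pages":
            rec.pages = value
        elif lname == "pmid":
            rec.pmid = value
        elif lname == "doi":
            rec.doi = value
        elif lname == "issn":
            rec.issn = value
        elif lname == "eissn":
            rec.eissn = value
        elif lname == "source":
            v = value.lower()
            rec.source = v if v in SOURCES else "other"
    return rec


def parse_bibtex(text: str, source: str = "other") -> list[BibRecord]:
    """Parse zero or more ``@article`` entries into :class:`BibRecord` objects.

    Parameters
    ----------
    text:
        Raw extended-BibTeX text.
    source:
        Default source-database tag for every entry; a per-entry ``Source``
        field overrides it.

    Malformed entries are skipped with a logged warning naming the byte
    offset; the rest of the batch is still parsed (a lost record is a lost
    article, so parsing never aborts).
    """
    records: list[BibRecord] = []
    sc = _Scanner(text)
    while True:
        at = sc.text.find("@", sc.pos)
        if at == -1:
            break
        sc.pos = at + 1
        try:
            entry_type = sc.read_word()
            sc.skip_ws()
            if entry_type.lower() != "article" or sc.peek() != "{":
                raise ValueError(f"unsupported entry type {entry_type!r}")
            sc.pos += 1
            sc.skip_ws()
            key = sc.read_word().strip()
            if not key:
                raise ValueError("empty entry key")
            sc.skip_ws()
            if sc.peek() == ",":
                sc.pos += 1
            fields: dict[str, str] = {}
            while True:
                sc.skip_ws()
                if sc.eof():
                    raise ValueError("unterminated entry")
                if sc.peek() == "}":
                    sc.pos += 1
                    break
                if sc.peek() == ",":
                    sc.pos += 1
                    continue
                name = sc.read_word()
                if not name:
                    raise ValueError(f"expected field name near offset {sc.pos}")
                sc.skip_ws()
                if sc.peek() != "=":
                    raise ValueError(f"expected '=' after field {name!r}")
                sc.pos += 1
                sc.skip_ws()
                fields[name] = sc.read_value()
            records.append(_build_record(key, fields, source))
        except ValueError as exc:
            logger.warning("skipping malformed entry at offset %d: %s", at, exc)
            # resync at the next entry marker
            nxt = sc.text.find("@", at + 1)
            sc.pos = len(sc.text) if nxt == -1 else nxt
    return records


def write_bibtex(records: list[BibRecord]) -> str:
    """Serialize records so that ``parse_bibtex`` reproduces all non-null fields."""
    blocks = []
    for r in records:
        lines = [f"@article{{{r.record_id},"]

        def emit(name: str, value: str) -> None:
            lines.append(f'  {name} = "{value}",')

        if r.authors:
            emit("Author", " and ".join(r.authors))
        if r.title is not None:
            emit("Title", "{" + r.title + "}")
        if r.journal is not None:
            emit("Journal", r.journal)
        if r.year is not None:
            emit("Year", str(r.year))
        if r.volume is not None:
            emit("Volume", r.volume)
        if r.issue is not None:
            emit("Number", r.issue)
        if r.pages is not None:
            emit("Pages", r.pages)
        if r.pmid is not None:
            emit("PMID", r.pmid)
        if r.doi is not None:
            emit("DOI", r.doi)
        if r.issn is not None:
            emit("ISSN", r.issn)
        if r.eissn is not None:
            emit("EISSN", r.eissn)
        emit("Source", r.source)
        for name, value in r.extras.items():
            emit(name, value)
        lines.append("}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def extract_pmid(record: BibRecord) -> str | None:
    """PubMed identifier of a record: the explicit PMID field if present,
    else the digits of a ``PUBMED<digits>`` record key, else ``None``."""
    if record.pmid is not None:
        return record.pmid
    m = _PUBMED_KEY.match(record.record_id)
    if m:
        return m.group(1)
    return None
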