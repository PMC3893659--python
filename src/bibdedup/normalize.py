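"""Field canonicalization so that record comparison compares like with like.

The databases behind a metasearch disagree on surface form even when they
index the same article: journal names are abbreviated differently
(``Journal of psychosomatic research`` vs ``J-Psychosom-Res``), page ranges
are truncated (``112–8`` vs ``112–118``), author names flip order and lose
middle initials, and encodings differ.  This module derives, once per
record, the canonical forms every matching rule works on: stop-word-free
lowercase token sequences, expanded page ranges, canonical identifiers and
``[surname, initial]`` author tokens.

Diacritics are intentionally *not* folded: the approximate string matcher
compares literal characters, and an accented character simply costs one
mismatch there.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .records_io import BibRecord, extract_pmid

#: Default stop words removed from journal/title token sequences.  English
#: connectives dominate journal-title noise; a handful of Romance particles
#: cover common journal names.  Overridable via MatchConfig / CLI.
DEFAULT_STOP_WORDS = frozenset(
    {"of", "the", "and", "a", "an", "in", "on", "for", "to", "with",
     "de", "la", "le"}
)

# word = maximal run of letters/digits; splits on whitespace, hyphens,
# periods, commas and all other punctuation
_WORD = re.compile(r"[^\W_]+", re.UNICODE)
_ALPHA = re.compile(r"[^\W\d_]+", re.UNICODE)
_DASH_SPLIT = re.compile(r"\s*[-–—]+\s*")
_DOI_PREFIX = re.compile(r"^(?:doi:\s*|https?://(?:dx\.)?doi\.org/)", re.IGNORECASE)


def tokenize(text: str | None, stop_words: frozenset[str] = DEFAULT_STOP_WORDS) -> list[str]:
    """Lowercased word tokens of *text*, in order, with stop words dropped."""
    if not text:
        return []
    # lowercase before splitting: case-folding can introduce combining
    # marks, which are not word characters
    return [t for t in _WORD.findall(text.lower()) if t not in stop_words]


def normalize_pages(pages: str | None) -> tuple[str | None, str | None]:
    """Canonical ``(page_start, page_end)`` of a free-text page field.

    An abbreviated end page is expanded with the leading digits of the start
    page (``112–8`` → ``("112", "118")``).  A single numeric page is both
    start and end; non-numeric paging (article numbers like ``e100044``) is
    kept verbatim as the start with no end.  Idempotent on its own output.
    """
    if pages is None or not pages.strip():
        return (None, None)
    text = pages.strip()
    parts = [p for p in _DASH_SPLIT.split(text) if p]
    if len(parts) == 1:
        p = parts[0].strip()
        if p.isdigit():
            return (p, p)
        return (text, None)
    if len(parts) == 2:
        start, end = parts[0].strip(), parts[1].strip()
        if start.isdigit() and end.isdigit():
            if len(end) < len(start):
                end = start[: len(start) - len(end)] + end
            return (start, end)
    return (text, None)


def normalize_identifier(value: str | None, kind: str) -> str | None:
    """Canonical form of an identifier: ``pmid`` → digits only, ``doi`` →
    lowercase with any ``doi:``/resolver prefix stripped, ``issn`` → digits
    and ``X`` with hyphens removed."""
    if value is None:
        return None
    if kind == "pmid":
        digits = "".join(c for c in value if c.isdigit())
        return digits or None
    if kind == "doi":
        v = _DOI_PREFIX.sub("", value.strip()).lower()
        return v or None
    if kind == "issn":
        v = "".join(c.upper() for c in value if c.isdigit() or c in "xX")
        return v or None
    raise ValueError(f"unknown identifier kind {kind!r}")


def normalize_author(name: str | None) -> list[str]:
    """``[surname, first-initial]`` tokens of one free-text author name.

    Handles both ``Smalheiser, NR.`` and ``Smalheiser N.R.`` orderings by
    taking the longest alphabetic token as the surname (tie: first token)
    and the first letter of the remaining tokens as the initial; middle
    initials are dropped since databases omit them inconsistently.
    """
    if not name:
        return []
    words = _ALPHA.findall(name)
    if not words:
        return []
    surname = max(words, key=len)  # max() keeps the first on ties
    rest = list(words)
    rest.remove(surname)
    out = [surname.lower()]
    if rest:
        out.append(rest[0][0].lower())
    return out


@dataclass
class NormalizedRecord:
    """A parsed record plus its cached canonical fields."""

    base: BibRecord
    pmid_c: str | None
    doi_c: str | None
    issn_c: str | None
    eissn_c: str | None
    journal_tokens: list[str]
    title_tokens: list[str]
    author_tokens: list[str] = field(default_factory=list)
    page_start: str | None = None
    page_end: str | None = None
    volume_c: str | None = None
    issue_c: str | None = None
    year_c: int | None = None

    @property
    def record_id(self) -> str:
        return self.base.record_id

    @property
    def source(self) -> str:
        return self.base.source


def normalize_record(rec: BibRecord,
                     stop_words: frozenset[str] = DEFAULT_STOP_WORDS) -> NormalizedRecord:
    """Derive every canonical field of *rec* once, for use by all rules."""
    page_start, page_end = normalize_pages(rec.pages)
    author_tokens: list[str] = []
    for name in rec.authors or []:
        author_tokens.extend(normalize_author(name))
    return NormalizedRecord(
        base=rec,
        pmid_c=normalize_identifier(extract_pmid(rec), "pmid"),
        doi_c=normalize_identifier(rec.doi, "doi"),
        issn_c=normalize_identifier(rec.issn, "issn"),
        eissn_c=normalize_identifier(rec.eissn, "issn"),
        journal_tokens=tokenize(rec.journal, stop_words),
        title_tokens=tokenize(rec.title, stop_words),
        author_tokens=author_tokens,
        page_start=page_start,
        page_end=page_end,
        volume_c=rec.volume.strip() if rec.volume and rec.volume.strip() else None,
        issue_c=rec.issue.strip() if rec.issue and rec.issue.strip() else None,
        year_c=rec.year,
    )


def normalize_lists(lists: dict[str, list[BibRecord]],
                    stop_words: frozenset[str] = DEFAULT_STOP_WORDS
                    ) -> dict[str, list[NormalizedRecord]]:
    """Normalize every record of every source list."""
    return {src: [normalize_record(r, stop_words) for r in recs]
            for src, recs in lists.items()}
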