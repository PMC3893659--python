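"""Synthetic multi-database corpora with known duplicate ground truth.

Real metasearch result sets cannot be redistributed, so tests and
benchmarks run on generated ones.  The generator builds base articles
(pronounceable random journal/title/author words, years in a narrow band so
that year blocks actually fill up, plausible volume/page numbers and
consistent PMID/DOI/ISSN identifiers) and indexes a fraction of them in a
second database, emitting a perturbed variant there and recording the pair
as ground truth.

The perturbations model the variation actually observed across databases:

* journal names abbreviated per-token by prefix truncation
  (``Journal of Pakemi`` → ``J-Pake``);
* page ranges truncated (``112–118`` → ``112–8``);
* author initials re-punctuated (``Surname, NR.`` → ``Surname N.R.``) and
  trailing authors dropped;
* a diacritic introduced into one title word;
* identifiers missing from one side;
* rarely, a missing or outright wrong publication year (wrong-year
  duplicates are the algorithm's documented blind spot).

Overlapping articles are indexed in exactly two databases, so every ground
truth pair is independently discoverable and precision/recall are crisp.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .engine import DedupReport
from .records_io import BibRecord

_CONSONANTS = "bcdfghklmnprstv"
_VOWELS = "aeiou"
_ACCENTS = {"a": "á", "e": "é", "i": "í", "o": "ó", "u": "ú"}


@dataclass(frozen=True)
class PerturbationProfile:
    """Per-variant perturbation probabilities and the corpus seed.

    ``p_missing_year`` defaults to 0.001: roughly one record per thousand
    lacks a year in real exports.  ``p_wrong_year`` is kept equally rare;
    such pairs are by design not found.  The remaining defaults are chosen
    to make each variation class common enough to be exercised in a corpus
    of a few hundred articles.
    """

    p_journal_abbrev: float = 0.3
    p_page_truncate: float = 0.3
    p_author_initial_variant: float = 0.3
    p_author_drop: float = 0.05
    p_missing_pmid: float = 0.2
    p_missing_doi: float = 0.3
    p_missing_year: float = 0.001
    p_diacritic_variant: float = 0.1
    p_wrong_year: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if name.startswith("p_") and not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


def clean_profile(seed: int = 0) -> PerturbationProfile:
    """All perturbation probabilities zero: every variant is field-identical."""
    return PerturbationProfile(
        p_journal_abbrev=0, p_page_truncate=0, p_author_initial_variant=0,
        p_author_drop=0, p_missing_pmid=0, p_missing_doi=0,
        p_missing_year=0, p_diacritic_variant=0, p_wrong_year=0, seed=seed)


def modeled_profile(seed: int = 0) -> PerturbationProfile:
    """Default perturbations restricted to the variation classes the
    matcher is designed to absorb (no wrong-year entries)."""
    return replace(PerturbationProfile(seed=seed), p_wrong_year=0.0)


@dataclass
class SyntheticCorpus:
    """Generated per-source record lists plus ground-truth duplicate pairs
    (unordered, stored as sorted id tuples)."""

    lists: dict[str, list[BibRecord]]
    truth_pairs: set[tuple[str, str]] = field(default_factory=set)

    def year_of(self) -> dict[str, int | None]:
        return {r.record_id: r.year for recs in self.lists.values() for r in recs}

    def same_year_truth_pairs(self) -> set[tuple[str, str]]:
        """Truth pairs whose two records agree on a non-null year — the
        subset the year-blocked algorithm can find at all."""
        years = self.year_of()
        return {p for p in self.truth_pairs
                if years[p[0]] is not None and years[p[0]] == years[p[1]]}


@dataclass
class _Article:
    idx: int
    journal_tokens: list[str]
    issn: str
    eissn: str
    title_words: list[str]
    authors: list[tuple[str, str]]  # (surname, initials)
    year: int
    volume: str
    issue: str
    page_start: int
    page_end: int
    pmid: str
    doi: str


def _word(rng: random.Random, syllables: int) -> str:
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
                   for _ in range(syllables))


def _make_journal(rng: random.Random, idx: int) -> tuple[list[str], str, str]:
    words = [_word(rng, rng.randint(3, 5)).capitalize()
             for _ in range(rng.randint(2, 3))]
    if rng.random() < 0.5:
        tokens = ["Journal", "of"] + words
    else:
        tokens = words
    issn = f"{1000 + idx:04d}-{rng.randint(1000, 9999):04d}"
    eissn = f"{5000 + idx:04d}-{rng.randint(1000, 9999):04d}"
    return tokens, issn, eissn


def _make_article(rng: random.Random, idx: int,
                  journals: list[tuple[list[str], str, str]]) -> _Article:
    jtokens, issn, eissn = journals[rng.randrange(len(journals))]
    title = [_word(rng, rng.randint(3, 5)) for _ in range(rng.randint(6, 10))]
    n_authors = rng.randint(1, 5)
    authors = []
    for _ in range(n_authors):
        surname = _word(rng, rng.randint(3, 5)).capitalize()
        initials = "".join(rng.choice("ABCDEFGHJKLMNPRSTV")
                           for _ in range(rng.randint(1, 2)))
        authors.append((surname, initials))
    start = rng.randint(1, 1800)
    return _Article(
        idx=idx,
        journal_tokens=list(jtokens),
        issn=issn,
        eissn=eissn,
        title_words=title,
        authors=authors,
        year=rng.randint(2006, 2010),
        volume=str(rng.randint(1, 120)),
        issue=str(rng.randint(1, 12)),
        page_start=start,
        page_end=start + rng.randint(1, 19),
        pmid=str(10000000 + idx),
        doi=f"10.1{idx:04d}/{_word(rng, 3)}{idx}",
    )


def _abbreviate_journal(rng: random.Random, tokens: list[str]) -> str:
    out = []
    for i, tok in enumerate(tokens):
        if tok.lower() in ("of", "the"):
            continue  # abbreviated styles drop connectives
        cut = 1 if i == 0 and tok.lower() == "journal" else rng.randint(2, max(2, len(tok) - 2))
        out.append(tok[:cut])
    return "-".join(out)


def _truncate_pages(start: int, end: int) -> str:
    s, e = str(start), str(end)
    if s == e:
        return s
    common = 0
    while common < len(s) and common < len(e) and s[common] == e[common]:
        common += 1
    if len(s) == len(e) and common > 0:
        return f"{s}–{e[common:]}"
    return f"{s}–{e}"


def _accent_title(rng: random.Random, words: list[str]) -> list[str]:
    eligible = [i for i, w in enumerate(words) if len(w) >= 5]
    if not eligible:
        return words
    i = rng.choice(eligible)
    w = words[i]
    for pos, ch in enumerate(w):
        if ch in _ACCENTS:
            words = list(words)
            words[i] = w[:pos] + _ACCENTS[ch] + w[pos + 1:]
            break
    return words


def _render(art: _Article, source: str, seq_id: int, rng: random.Random,
            profile: PerturbationProfile, perturbed: bool) -> BibRecord:
    journal = " ".join(art.journal_tokens)
    title_words = list(art.title_words)
    authors = list(art.authors)
    pages = f"{art.page_start}–{art.page_end}"
    author_style = "comma"  # "Surname, NR."
    year: int | None = art.year

    if perturbed:
        if rng.random() < profile.p_journal_abbrev:
            journal = _abbreviate_journal(rng, art.journal_tokens)
        if rng.random() < profile.p_page_truncate:
            pages = _truncate_pages(art.page_start, art.page_end)
        if rng.random() < profile.p_author_initial_variant:
            author_style = "dotted"  # "Surname N.R."
        if rng.random() < profile.p_author_drop and len(authors) >= 2:
            authors = authors[:-1]
        if rng.random() < profile.p_diacritic_variant:
            title_words = _accent_title(rng, title_words)
        if rng.random() < profile.p_wrong_year:
            year = art.year + rng.choice((-1, 1))

    if rng.random() < profile.p_missing_year:
        year = None

    if author_style == "comma":
        author_strs = [f"{s}, {ini}." for s, ini in authors]
    else:
        author_strs = [f"{s} {'.'.join(ini)}." for s, ini in authors]

    if source == "pubmed":
        record_id = f"PUBMED{art.pmid}"
        pmid: str | None = art.pmid
    else:
        record_id = f"{source.upper()}:{300000 + seq_id}"
        pmid = None if rng.random() < profile.p_missing_pmid else art.pmid
    doi = None if rng.random() < profile.p_missing_doi else art.doi

    title = " ".join(title_words).capitalize()
    return BibRecord(
        record_id=record_id, source=source, pmid=pmid, doi=doi,
        issn=art.issn, eissn=art.eissn, journal=journal, title=title,
        authors=author_strs, year=year, volume=art.volume, issue=art.issue,
        pages=pages,
    )


def generate(n_articles: int,
             sources: tuple[str, ...] = ("pubmed", "embase", "cinahl"),
             overlap_rate: float = 0.4,
             profile: PerturbationProfile | None = None) -> SyntheticCorpus:
    """Generate a corpus of *n_articles* base articles across *sources*.

    With probability *overlap_rate* an article is indexed in a second
    database (preferring a PubMed pairing, the dominant case in practice):
    the reference copy goes to the first database, a perturbed variant to
    the second, and the id pair is recorded as ground truth.  Fully
    reproducible from ``profile.seed``.
    """
    if n_articles < 1:
        raise ValueError("n_articles must be >= 1")
    if not sources:
        raise ValueError("at least one source is required")
    if not (0.0 <= overlap_rate <= 1.0):
        raise ValueError(f"overlap_rate must be in [0, 1], got {overlap_rate}")
    profile = profile or PerturbationProfile()
    rng = random.Random(profile.seed)

    journals = [_make_journal(rng, j)
                for j in range(max(3, n_articles // 8))]
    lists: dict[str, list[BibRecord]] = {src: [] for src in sources}
    truth: set[tuple[str, str]] = set()

    for i in range(n_articles):
        art = _make_article(rng, i, journals)
        if len(sources) >= 2 and rng.random() < overlap_rate:
            others = [s for s in sources if s != "pubmed"]
            if "pubmed" in sources:
                first, second = "pubmed", rng.choice(others)
            else:
                first, second = rng.sample(list(sources), 2)
            rec_a = _render(art, first, i, rng, profile, perturbed=False)
            rec_b = _render(art, second, i, rng, profile, perturbed=True)
            lists[first].append(rec_a)
            lists[second].append(rec_b)
            truth.add(tuple(sorted((rec_a.record_id, rec_b.record_id))))
        else:
            home = sources[rng.randrange(len(sources))]
            lists[home].append(_render(art, home, i, rng, profile,
                                       perturbed=False))

    return SyntheticCorpus(lists=lists, truth_pairs=truth)


def found_pairs(report: DedupReport) -> set[tuple[str, str]]:
    """Unordered id pairs found by a deduplication run."""
    return {tuple(sorted((p.a_id, p.b_id))) for p in report.pairs}


def score(report: DedupReport, truth: SyntheticCorpus) -> tuple[float, float]:
    """(precision, recall) of a run against ground truth; an empty found
    set has precision 1, an empty truth set recall 1."""
    found = found_pairs(report)
    hits = found & truth.truth_pairs
    precision = 1.0 if not found else len(hits) / len(found)
    recall = 1.0 if not truth.truth_pairs else len(hits) / len(truth.truth_pairs)
    return precision, recall
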