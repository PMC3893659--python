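"""The seven-rule pairwise decision procedure.

Rules run in a fixed order on a pair of normalized records:

1–3. *Denial* rules — both records carry a PMID / DOI / (E)ISSN and the
     values disagree: they are different articles, stop immediately.  These
     are cheap string comparisons and fire for the overwhelming majority of
     pairs, which is what makes them worth running first.
4–5. Identifier *match* rules — shared PMID or DOI proves identity.
6.   Journal name matches and the paging group (volume + issue + start
     page) matches: the paging group has high selectivity inside a journal.
7.   Journal, title and author list all match and the pages do not
     conflict: the fallback for records whose paging data is incomplete.

A matching rule never fires on two missing values, and a denial rule never
fires unless both sides are present — missing data neither confirms nor
denies.  When no rule fires the pair is left unmerged: the design goal is
never to merge two distinct articles, at the price of missing some true
duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .normalize import NormalizedRecord
from .text_match import MatchConfig, sequences_equal


@dataclass
class MatchCounters:
    """Instrumentation: how many record pairs were examined and how many
    text-field (sequence) comparisons were actually evaluated."""

    record_comparisons: int = 0
    similarity_calls: int = 0


@dataclass(frozen=True)
class RuleVerdict:
    """Outcome of one pairwise comparison: whether the pair is a duplicate,
    which rule decided (1–7), and whether that was a denial rule."""

    is_duplicate: bool
    rule_id: int | None
    denial: bool


NO_MATCH = RuleVerdict(is_duplicate=False, rule_id=None, denial=False)


def _seq_eq(a: list[str], b: list[str], cfg: MatchConfig,
            counters: MatchCounters | None) -> bool:
    if counters is not None and a and b:
        counters.similarity_calls += 1
    return sequences_equal(a, b, cfg)


def journal_equals(a: NormalizedRecord, b: NormalizedRecord, cfg: MatchConfig,
                   counters: MatchCounters | None = None) -> bool:
    """Journal-name token sequences match; false when either is missing."""
    return _seq_eq(a.journal_tokens, b.journal_tokens, cfg, counters)


def title_equals(a: NormalizedRecord, b: NormalizedRecord, cfg: MatchConfig,
                 counters: MatchCounters | None = None) -> bool:
    """Title token sequences match; false when either is missing."""
    return _seq_eq(a.title_tokens, b.title_tokens, cfg, counters)


def author_equals(a: NormalizedRecord, b: NormalizedRecord, cfg: MatchConfig,
                  counters: MatchCounters | None = None) -> bool:
    """Flattened [surname, initial] author sequences match.

    Because sequence similarity divides by the shorter sequence, a database
    that lists only the first authors still matches the full list.
    """
    return _seq_eq(a.author_tokens, b.author_tokens, cfg, counters)


def page_equals(a: NormalizedRecord, b: NormalizedRecord) -> bool:
    """Strong paging-group test (rule 6): volume and start page both present
    and equal, issue equal or missing on at least one side."""
    if a.volume_c is None or b.volume_c is None or a.volume_c != b.volume_c:
        return False
    if a.page_start is None or b.page_start is None or a.page_start != b.page_start:
        return False
    if a.issue_c is not None and b.issue_c is not None and a.issue_c != b.issue_c:
        return False
    return True


def page_compatible(a: NormalizedRecord, b: NormalizedRecord) -> bool:
    """Weak page test (rule 7): start pages equal, or missing on either
    side; two conflicting non-null start pages reject the pair."""
    if a.page_start is None or b.page_start is None:
        return True
    return a.page_start == b.page_start


def records_are_duplicate(a: NormalizedRecord, b: NormalizedRecord,
                          cfg: MatchConfig,
                          counters: MatchCounters | None = None) -> RuleVerdict:
    """Apply the seven rules in order and report the verdict.

    Denial rules (1–3) run only when ``cfg.denial_enabled``; text rules
    (6–7) honour ``cfg.approx_enabled`` through ``sequences_equal``.
    Symmetric in its arguments.
    """
    if counters is not None:
        counters.record_comparisons += 1

    if cfg.denial_enabled:
        if a.pmid_c is not None and b.pmid_c is not None and a.pmid_c != b.pmid_c:
            return RuleVerdict(False, 1, True)
        if a.doi_c is not None and b.doi_c is not None and a.doi_c != b.doi_c:
            return RuleVerdict(False, 2, True)
        # print and electronic serial numbers are distinct identifiers for
        # the same journal, so ISSN is never compared against EISSN
        if ((a.issn_c is not None and b.issn_c is not None
             and a.issn_c != b.issn_c)
                or (a.eissn_c is not None and b.eissn_c is not None
                    and a.eissn_c != b.eissn_c)):
            return RuleVerdict(False, 3, True)

    if a.pmid_c is not None and b.pmid_c is not None and a.pmid_c == b.pmid_c:
        return RuleVerdict(True, 4, False)
    if a.doi_c is not None and b.doi_c is not None and a.doi_c == b.doi_c:
        return RuleVerdict(True, 5, False)
    if journal_equals(a, b, cfg, counters) and page_equals(a, b):
        return RuleVerdict(True, 6, False)
    if (journal_equals(a, b, cfg, counters)
            and title_equals(a, b, cfg, counters)
            and author_equals(a, b, cfg, counters)
            and page_compatible(a, b)):
        return RuleVerdict(True, 7, False)
    return NO_MATCH
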