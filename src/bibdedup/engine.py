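"""YEAR-blocked hash-join deduplication over per-database result lists.

Two records can only be the same article if their publication years agree
(the rare wrong-year entry is a deliberately accepted miss), so records are
first hashed into per-year blocks and only same-year records are ever
compared — turning an all-pairs join over every list into small per-block
joins.  Within a block, an accumulator is seeded with the PubMed records
(the reference list) and the remaining sources are folded in one at a time:
each incoming record is compared against every accumulated record, emitting
a duplicate pair per match, and only records that matched nothing join the
accumulator.  Records with no year are compared against the whole
accumulated pool at the end; in practice they are ~0.1% of records.

Source order is fixed (pubmed, embase, cinahl, psycinfo, cochrane, other)
so that identical input always yields identical output.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .normalize import DEFAULT_STOP_WORDS, NormalizedRecord
from .records_io import SOURCES
from .rules import MatchCounters, records_are_duplicate
from .text_match import MatchConfig

#: The four operating modes: approximate text matching and identifier
#: denial rules, each independently on or off.
MODES = ("plain", "denial", "approx", "approx_denial")


def mode_config(mode: str, threshold: float = 0.8,
                stop_words: frozenset[str] = DEFAULT_STOP_WORDS) -> MatchConfig:
    """MatchConfig for a named mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    return MatchConfig(
        threshold=threshold,
        approx_enabled=mode in ("approx", "approx_denial"),
        denial_enabled=mode in ("denial", "approx_denial"),
        stop_words=stop_words,
    )


def mode_name(cfg: MatchConfig) -> str:
    return ("approx" if cfg.approx_enabled else "plain") if not cfg.denial_enabled \
        else ("approx_denial" if cfg.approx_enabled else "denial")


@dataclass
class YearBlocks:
    """Records partitioned by publication year, keyed source-wise inside
    each block, plus the records whose year is missing."""

    by_year: dict[int, dict[str, list[NormalizedRecord]]] = field(default_factory=dict)
    missing_year: list[NormalizedRecord] = field(default_factory=list)

    @property
    def records_in(self) -> int:
        return sum(len(recs) for srcs in self.by_year.values()
                   for recs in srcs.values()) + len(self.missing_year)


@dataclass(frozen=True)
class DuplicatePair:
    """One matched pair: ``a`` is the incoming record, ``b`` the retained
    (accumulated, PubMed-preferred) copy, with the rule that decided."""

    a_id: str
    b_id: str
    rule_id: int
    a_source: str
    b_source: str


@dataclass
class DedupReport:
    """Result of one deduplication run plus instrumentation."""

    pairs: list[DuplicatePair]
    comparisons_made: int
    similarity_calls: int
    records_in: int
    mode: str
    elapsed: float


def block_by_year(lists: dict[str, list[NormalizedRecord]]) -> YearBlocks:
    """Partition records into per-year blocks; null-year records go to
    ``missing_year``.  Every input record lands in exactly one place."""
    blocks = YearBlocks()
    for src, recs in lists.items():
        for rec in recs:
            if rec.year_c is None:
                blocks.missing_year.append(rec)
            else:
                blocks.by_year.setdefault(rec.year_c, {}).setdefault(src, []).append(rec)
    return blocks


def _source_order(sources) -> list[str]:
    known = [s for s in SOURCES if s in sources]
    extra = sorted(s for s in sources if s not in SOURCES)
    return known + extra


def deduplicate(blocks: YearBlocks, cfg: MatchConfig) -> DedupReport:
    """Run the blocked join and return all duplicate pairs found.

    One incoming record may match several accumulated records (e.g. an
    article indexed twice in one database, both copies matching the same
    PubMed record): every match is emitted as its own pair.
    """
    t0 = time.perf_counter()
    counters = MatchCounters()
    pairs: list[DuplicatePair] = []
    all_records: list[NormalizedRecord] = []

    def fold(incoming: NormalizedRecord, pool: list[NormalizedRecord]) -> None:
        matched = False
        for kept in pool:
            verdict = records_are_duplicate(incoming, kept, cfg, counters)
            if verdict.is_duplicate:
                matched = True
                pairs.append(DuplicatePair(
                    a_id=incoming.record_id, b_id=kept.record_id,
                    rule_id=verdict.rule_id,
                    a_source=incoming.source, b_source=kept.source))
        if not matched:
            pool.append(incoming)

    for year in sorted(blocks.by_year):
        src_map = blocks.by_year[year]
        accumulated = list(src_map.get("pubmed", []))
        for src in _source_order(src_map):
            if src == "pubmed":
                continue
            for rec in src_map[src]:
                fold(rec, accumulated)
        all_records.extend(accumulated)

    for rec in blocks.missing_year:
        fold(rec, all_records)

    pairs.sort(key=lambda p: (p.a_id, p.b_id))
    return DedupReport(
        pairs=pairs,
        comparisons_made=counters.record_comparisons,
        similarity_calls=counters.similarity_calls,
        records_in=blocks.records_in,
        mode=mode_name(cfg),
        elapsed=time.perf_counter() - t0,
    )


def run_modes(lists: dict[str, list[NormalizedRecord]],
              modes: tuple[str, ...] = MODES,
              threshold: float = 0.8,
              stop_words: frozenset[str] = DEFAULT_STOP_WORDS
              ) -> dict[str, DedupReport]:
    """Deduplicate the same input under several modes."""
    blocks = block_by_year(lists)
    return {mode: deduplicate(blocks, mode_config(mode, threshold, stop_words))
            for mode in modes}
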