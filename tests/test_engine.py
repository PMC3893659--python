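"""Year-blocked join engine: blocking, accumulator semantics, modes,
instrumentation, and equivalence with a naive all-pairs oracle."""

import itertools

import pytest

import bibdedup as bd


def nrec(record_id, source="other", **fields):
    return bd.normalize_record(bd.BibRecord(record_id=record_id,
                                            source=source, **fields))


def brute_force_pairs(lists, cfg):
    """Naive oracle: evaluate the rules on every cross-source same-year
    pair, and on every pair involving a missing-year record."""
    recs = [r for rl in lists.values() for r in rl]
    out = set()
    for a, b in itertools.combinations(recs, 2):
        same_year = (a.year_c is not None and a.year_c == b.year_c
                     and a.source != b.source)
        missing = a.year_c is None or b.year_c is None
        if not (same_year or missing):
            continue
        if bd.records_are_duplicate(a, b, cfg).is_duplicate:
            out.add(tuple(sorted((a.record_id, b.record_id))))
    return out


class TestBlocking:
    def test_partition_and_conservation(self):
        lists = {
            "pubmed": [nrec("P1", "pubmed", year=2008),
                       nrec("P2", "pubmed", year=2009)],
            "embase": [nrec("E1", "embase", year=2008),
                       nrec("E2", "embase")],  # no year
        }
        blocks = bd.block_by_year(lists)
        assert sorted(blocks.by_year) == [2008, 2009]
        assert [r.record_id for r in blocks.by_year[2008]["pubmed"]] == ["P1"]
        assert [r.record_id for r in blocks.missing_year] == ["E2"]
        assert blocks.records_in == 4

    def test_empty_input(self):
        blocks = bd.block_by_year({})
        assert blocks.by_year == {} and blocks.missing_year == []
        report = bd.deduplicate(blocks, bd.MatchConfig())
        assert report.pairs == [] and report.comparisons_made == 0

    def test_distinct_years_are_never_compared(self):
        lists = {"pubmed": [nrec(f"P{y}", "pubmed", year=y, journal="J",
                                 volume="1", pages="10-20")
                            for y in range(2000, 2010)]}
        report = bd.deduplicate(bd.block_by_year(lists), bd.MatchConfig())
        assert report.pairs == [] and report.comparisons_made == 0


class TestDeduplicate:
    def test_fixture_pair_found_once_via_rule_6(self, pubmed_record,
                                                embase_record):
        lists = bd.normalize_lists({"pubmed": [pubmed_record],
                                    "embase": [embase_record]})
        report = bd.deduplicate(bd.block_by_year(lists), bd.MatchConfig())
        assert len(report.pairs) == 1
        (pair,) = report.pairs
        assert pair.rule_id == 6
        assert {pair.a_id, pair.b_id} == {"PUBMED18812194", "EMBASE:2008527667"}
        assert pair.b_source == "pubmed"  # the retained copy

    def test_wrong_year_duplicates_are_missed_by_design(self):
        art = dict(journal="Neuroscience research", volume="62",
                   pages="236–9", pmid="18812194")
        lists = {"pubmed": [nrec("P", "pubmed", year=2008, **art)],
                 "embase": [nrec("E", "embase", year=2009, **art)]}
        report = bd.deduplicate(bd.block_by_year(lists), bd.MatchConfig())
        assert report.pairs == []

    def test_missing_year_record_checked_against_all(self):
        art = dict(journal="Neuroscience research", volume="62", pages="236–9")
        lists = {"pubmed": [nrec("P", "pubmed", year=2008, **art)],
                 "embase": [nrec("E", "embase", year=None, **art)]}
        report = bd.deduplicate(bd.block_by_year(lists), bd.MatchConfig())
        assert [(p.a_id, p.b_id) for p in report.pairs] == [("E", "P")]

    def test_one_record_may_match_several_accumulated(self):
        """An article indexed twice within one database: both copies flag
        against the same retained PubMed record."""
        art = dict(journal="Neuroscience research", volume="62",
                   pages="236–9", year=2008, pmid="18812194")
        lists = {"pubmed": [nrec("P", "pubmed", **art)],
                 "embase": [nrec("E1", "embase", **art),
                            nrec("E2", "embase", **art)]}
        report = bd.deduplicate(bd.block_by_year(lists), bd.MatchConfig())
        assert {(p.a_id, p.b_id) for p in report.pairs} == \
            {("E1", "P"), ("E2", "P")}

    def test_matched_record_not_added_to_accumulator(self):
        # after E matches P, a later CINAHL copy still matches the retained
        # PubMed copy, not the EMBASE one
        art = dict(journal="Neuroscience research", volume="62",
                   pages="236–9", year=2008)
        lists = {"pubmed": [nrec("P", "pubmed", **art)],
                 "embase": [nrec("E", "embase", **art)],
                 "cinahl": [nrec("C", "cinahl", **art)]}
        report = bd.deduplicate(bd.block_by_year(lists), bd.MatchConfig())
        assert {(p.a_id, p.b_id) for p in report.pairs} == \
            {("E", "P"), ("C", "P")}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 2])
    @pytest.mark.parametrize("mode", ["approx_denial", "plain"])
    def test_blocked_join_equals_all_pairs_oracle(self, seed, mode):
        corpus = bd.generate(160, ("pubmed", "embase", "cinahl"), 0.45,
                             bd.PerturbationProfile(seed=seed))
        lists = bd.normalize_lists(corpus.lists)
        cfg = bd.mode_config(mode)
        report = bd.deduplicate(bd.block_by_year(lists), cfg)
        assert bd.found_pairs(report) == brute_force_pairs(lists, cfg)


@pytest.fixture(scope="module")
def reports():
    corpus = bd.generate(200, ("pubmed", "embase", "cinahl"), 0.4,
                         bd.modeled_profile(seed=5))
    return corpus, bd.run_modes(bd.normalize_lists(corpus.lists))


class TestModesAndInstrumentation:

    def test_denial_rules_change_cost_not_outcome(self, reports):
        _, reps = reports
        assert bd.found_pairs(reps["plain"]) == bd.found_pairs(reps["denial"])
        assert bd.found_pairs(reps["approx"]) == \
            bd.found_pairs(reps["approx_denial"])

    def test_approx_finds_a_superset_of_plain(self, reports):
        _, reps = reports
        assert bd.found_pairs(reps["plain"]) <= bd.found_pairs(reps["approx"])

    def test_denial_cuts_similarity_computations(self, reports):
        _, reps = reports
        assert reps["denial"].similarity_calls < reps["plain"].similarity_calls
        assert reps["approx_denial"].similarity_calls < \
            reps["approx"].similarity_calls

    def test_blocking_beats_naive_comparison_count(self, reports):
        _, reps = reports
        for rep in reps.values():
            naive = rep.records_in * (rep.records_in - 1) // 2
            assert rep.comparisons_made < naive

    def test_determinism(self):
        corpus = bd.generate(60, ("pubmed", "embase"), 0.5,
                             bd.PerturbationProfile(seed=3))
        lists = bd.normalize_lists(corpus.lists)
        r1 = bd.deduplicate(bd.block_by_year(lists), bd.MatchConfig())
        r2 = bd.deduplicate(bd.block_by_year(lists), bd.MatchConfig())
        assert r1.pairs == r2.pairs
        assert r1.pairs == sorted(r1.pairs, key=lambda p: (p.a_id, p.b_id))

    def test_pairs_are_unique_and_irreflexive(self, reports):
        _, reps = reports
        for rep in reps.values():
            keys = [(p.a_id, p.b_id) for p in rep.pairs]
            assert len(keys) == len(set(keys))
            assert all(p.a_id != p.b_id for p in rep.pairs)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            bd.mode_config("fuzzy")
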