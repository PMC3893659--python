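"""Shared fixtures: the published PubMed/EMBASE record pair for one article
(the canonical worked example of cross-database variation) and default
matching configuration."""

import pytest
from hypothesis import settings

import bibdedup as bd

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")

# The same 2008 Neuroscience Research article as exported by PubMed and by
# EMBASE: note the author-initial punctuation, journal capitalization and
# page-range truncation differences, and the mixed quote styles.
PUBMED_ENTRY = """@article{PUBMED18812194,
Author="Smalheiser, NR. and Lugli, G. and Torvik, VI. and Mise, N. and Ikeda, R. and Abe, K.",
Title="{Natural antisense transcripts are co-expressed with sense mRNAs in synaptoneurosomes of adult mouse forebrain.}",
Journal="Neuroscience research",
Year="2008",
Volume="62",
Number="4",
Pages="236–9"
}"""

EMBASE_ENTRY = """@article{EMBASE:2008527667,
Author=“Smalheiser N.R. and Lugli G. and Torvik V.I. and Mise N. and Ikeda R. and Abe K.”,
Title=“{Natural antisense transcripts are co-expressed with sense mRNAs in synaptoneurosomes of adult mouse forebrain}”,
Journal=“Neuroscience Research”,
Year=“2008”,
Volume=“62”,
Number=“4”,
Pages=“236–239”
}"""


@pytest.fixture(scope="session")
def pubmed_record():
    (rec,) = bd.parse_bibtex(PUBMED_ENTRY, source="pubmed")
    return rec


@pytest.fixture(scope="session")
def embase_record():
    (rec,) = bd.parse_bibtex(EMBASE_ENTRY, source="embase")
    return rec


@pytest.fixture(scope="session")
def cross_db_pair(pubmed_record, embase_record):
    """The two records normalized, ready for rule evaluation."""
    return bd.normalize_record(pubmed_record), bd.normalize_record(embase_record)


@pytest.fixture(scope="session")
def cfg():
    """Default production configuration: approx + denial, threshold 0.8."""
    return bd.MatchConfig()
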