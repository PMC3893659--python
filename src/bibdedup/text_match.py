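"""Approximate matching of words and word sequences via longest common
subsequence (LCS).

Two layers share one similarity definition, ``LCS(A, B) / MIN_LEN(A, B)``:

* character level — how alike are two words?  Literal characters are
  compared (no diacritic folding), so ``Hello`` vs ``Hḗllo`` scores 4/5.
* token level — how alike are two token sequences?  Token equality is the
  abbreviation-aware :func:`token_match` (prefix match, or character-level
  similarity above threshold), so ``[j, psychosom, res]`` fully matches
  ``[journal, psychosomatic, research]``.

Dividing by the *shorter* length makes a truncated list (fewer authors,
abbreviated journal) score high against its full counterpart — deliberate,
given that missing parts are common across databases.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass

from .normalize import DEFAULT_STOP_WORDS


@dataclass(frozen=True)
class MatchConfig:
    """Matching behaviour: similarity threshold, mode flags, stop words.

    ``threshold`` (default 0.8) applies at both the character and the token
    level.  ``approx_enabled`` switches between approximate and exact field
    comparison; ``denial_enabled`` switches the quick identifier denial
    rules on or off.
    """

    threshold: float = 0.8
    approx_enabled: bool = True
    denial_enabled: bool = True
    stop_words: frozenset[str] = DEFAULT_STOP_WORDS

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")


def _lcs_length(a: Sequence, b: Sequence, eq: Callable) -> int:
    """Length of the longest common subsequence under equality predicate
    *eq*, by the standard O(|a|·|b|) dynamic program (two-row)."""
    n = len(b)
    prev = [0] * (n + 1)
    for x in a:
        cur = [0] * (n + 1)
        for j, y in enumerate(b):
            if eq(x, y):
                cur[j + 1] = prev[j] + 1
            else:
                cur[j + 1] = max(prev[j + 1], cur[j])
        prev = cur
    return prev[n]


def char_lcs_similarity(w1: str, w2: str) -> float:
    """Character-level LCS length divided by the shorter word length.

    Symmetric, in [0, 1]; characters are compared literally (codepoint
    equality), so accented variants cost exactly their mismatches.
    """
    if not w1 or not w2:
        raise ValueError("char_lcs_similarity requires non-empty words")
    lcs = _lcs_length(w1, w2, lambda x, y: x == y)
    return lcs / min(len(w1), len(w2))


def token_match(t1: str, t2: str, cfg: MatchConfig) -> bool:
    """Whether two normalized tokens stand for the same word.

    True when either token is a prefix of the other (abbreviations:
    ``j`` ~ ``journal``, ``psychosom`` ~ ``psychosomatic``) or when their
    character-level similarity clears ``cfg.threshold`` (encoding variants:
    ``hello`` ~ ``hḗllo``).
    """
    if t1.startswith(t2) or t2.startswith(t1):
        return True
    return char_lcs_similarity(t1, t2) >= cfg.threshold


def token_lcs_length(a: Sequence[str], b: Sequence[str], cfg: MatchConfig) -> int:
    """Token-level LCS length where token equality is :func:`token_match`."""
    return _lcs_length(a, b, lambda x, y: token_match(x, y, cfg))


def sequence_similarity(a: Sequence[str], b: Sequence[str], cfg: MatchConfig) -> float:
    """Token-level LCS length divided by the shorter sequence length."""
    if not a or not b:
        raise ValueError("sequence_similarity requires non-empty sequences; "
                         "treat an empty field as missing")
    return token_lcs_length(a, b, cfg) / min(len(a), len(b))


def sequences_equal(a: Sequence[str], b: Sequence[str], cfg: MatchConfig) -> bool:
    """Decide whether two token sequences denote the same field value.

    An empty sequence never matches anything: missing data must not confirm
    a duplicate.  With approximate matching enabled the sequences match when
    their similarity reaches ``cfg.threshold``; otherwise only exact
    token-list equality counts.
    """
    if not a or not b:
        return False
    if cfg.approx_enabled:
        return sequence_similarity(a, b, cfg) >= cfg.threshold
    return list(a) == list(b)
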