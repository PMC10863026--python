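"""Token-level keyword and phrase matching for clinical note text.

Matching semantics used throughout the labeling functions and feature
extraction:

* text is lowercased and split into word tokens (``[a-z0-9']+``);
* a single-token term matches whole tokens only (``alert`` does not match
  ``alertness``);
* a multi-word term matches a consecutive token subsequence
  (``no response`` matches the tokens ``no``, ``response`` in order);
* two matches are "within *w* tokens of each other" when the smallest
  token-index distance between any token of one span and any token of the
  other is at most *w*.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Sequence, Tuple

_TOKEN_RE = re.compile(r"[a-z0-9']+")

#: a matched occurrence: (start token index, span length in tokens)
Span = Tuple[int, int]


def tokenize(text: str) -> List[str]:
    return _TOKEN_RE.findall(text.lower())


def compile_terms(terms: Iterable[str]) -> List[Tuple[str, ...]]:
    """Tokenize each term once; drop terms that tokenize to nothing."""
    out = []
    for t in terms:
        tok = tuple(tokenize(t))
        if tok:
            out.append(tok)
    return out


class LexiconIndex:
    """First-token index over several named term lists for one-pass scans."""

    def __init__(self, lexicons: Dict[str, Iterable[str]]):
        self.names = list(lexicons)
        # first token -> list of (name, token tuple)
        self._by_first: Dict[str, List[Tuple[str, Tuple[str, ...]]]] = {}
        for name, terms in lexicons.items():
            for tok in compile_terms(terms):
                self._by_first.setdefault(tok[0], []).append((name, tok))

    def scan(self, tokens: Sequence[str]) -> Dict[str, List[Span]]:
        """Return, per lexicon name, the occurrence spans in ``tokens``."""
        hits: Dict[str, List[Span]] = {}
        by_first = self._by_first
        for i, tok in enumerate(tokens):
            cands = by_first.get(tok)
            if not cands:
                continue
            for name, term in cands:
                k = len(term)
                if k == 1 or tuple(tokens[i : i + k]) == term:
                    hits.setdefault(name, []).append((i, k))
        return hits


def find_occurrences(tokens: Sequence[str], terms: Iterable[str]) -> List[Span]:
    return LexiconIndex({"_": terms}).scan(tokens).get("_", [])


def span_distance(a: Span, b: Span) -> int:
    """Smallest token-index distance between any token of span a and of b."""
    a_lo, a_hi = a[0], a[0] + a[1] - 1
    b_lo, b_hi = b[0], b[0] + b[1] - 1
    if a_hi < b_lo:
        return b_lo - a_hi
    if b_hi < a_lo:
        return a_lo - b_hi
    return 0  # overlapping spans


def spans_within(spans_a: Sequence[Span], spans_b: Sequence[Span], window: int) -> bool:
    for a in spans_a:
        for b in spans_b:
            if span_distance(a, b) <= window:
                return True
    return False


def proximity_match(text: str, lex_a: Iterable[str], lex_b: Iterable[str], window: int) -> bool:
    """True iff a term of ``lex_a`` occurs within ``window`` tokens of a term
    of ``lex_b`` in ``text``.  Empty text never matches."""
    if window < 1:
        raise ValueError("window must be >= 1")
    tokens = tokenize(text)
    if not tokens:
        return False
    a = find_occurrences(tokens, lex_a)
    if not a:
        return False
    b = find_occurrences(tokens, lex_b)
    return spans_within(a, b, window)
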