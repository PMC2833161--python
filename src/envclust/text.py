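"""Tokenization shared by the literature-coherence and annotation stages.

Text is lowercased and split on whitespace and punctuation; a hyphen
between word characters is the one piece of punctuation preserved, so
"zinc-binding" survives as a single token.  Stop words come from the
packaged list (data/stopwords.txt).
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


@lru_cache(maxsize=1)
def stop_words() -> frozenset[str]:
    text = resources.files("envclust").joinpath("data/stopwords.txt").read_text()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace/punctuation (intra-word hyphens kept),
    drop stop words; surviving tokens returned in order."""
    sw = stop_words()
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in sw]


def ngrams(tokens) -> tuple[set[str], set[str]]:
    """Distinct unigrams and distinct consecutive bigrams (space-joined)
    of an already-filtered token sequence."""
    tokens = list(tokens)
    unigrams = set(tokens)
    bigrams = {f"{a} {b}" for a, b in zip(tokens, tokens[1:])}
    return unigrams, bigrams
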