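"""Shared text normalization.

Every text-matching component (eligibility search terms, disease-category
lookup) must agree on tokenization, so the normalizer lives in one place.
Normalization is deliberately blunt: lower-case, any non-word character
becomes whitespace (digits are kept), tokens are whitespace-delimited.
Matching is then *token-level*, never raw substring: "art" does not match
inside "heart".
"""

from __future__ import annotations

import re

_PUNCT = re.compile(r"[^\w\s]|_", flags=re.UNICODE)


def normalize_tokens(text: str | None) -> tuple[str, ...]:
    """Lower-case, strip punctuation, split into tokens.

    Returns an empty tuple for ``None`` or whitespace-only input.
    """
    if not text:
        return ()
    return tuple(_PUNCT.sub(" ", text.lower()).split())


def ngrams(tokens: tuple[str, ...], max_n: int) -> set[tuple[str, ...]]:
    """All contiguous token n-grams with 1 <= n <= max_n."""
    out: set[tuple[str, ...]] = set()
    L = len(tokens)
    for n in range(1, min(max_n, L) + 1):
        for i in range(L - n + 1):
            out.add(tokens[i : i + n])
    return out
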