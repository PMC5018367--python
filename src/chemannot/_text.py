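"""Low-level string utilities shared by the reference space and the matcher."""

from __future__ import annotations

import re
import unicodedata

_WS_RUN = re.compile(r"\s+")

#: 14 uppercase letters, hyphen, 10 uppercase letters, hyphen, 1 uppercase letter.
INCHIKEY_PATTERN = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


def normalize_name(raw: str) -> str:
    """Normalize a chemical name for dictionary lookup.

    Applies Unicode compatibility (NFKC) normalization, case folding, strips
    leading/trailing whitespace and collapses internal whitespace runs to a
    single space.  Hyphens, digits, commas and parentheses are chemically
    meaningful and are preserved.
    """
    s = unicodedata.normalize("NFKC", raw).casefold().strip()
    return _WS_RUN.sub(" ", s)


def aggressive_key(name: str) -> str:
    """Collapse a normalized name to alphanumerics only.

    Too lossy for exact matching (it would merge e.g. "2,4-d" and "24d"),
    but useful as an extra candidate-generation key for approximate search.
    """
    return "".join(c for c in name if c.isalnum())


def ngrams(s: str, n: int, pad: str = "#") -> frozenset[str]:
    """Character n-grams of ``s`` padded with one ``pad`` character per side."""
    padded = pad + s + pad
    if len(padded) < n:
        return frozenset((padded,))
    return frozenset(padded[i : i + n] for i in range(len(padded) - n + 1))


def is_inchikey_shaped(s: str) -> bool:
    return bool(INCHIKEY_PATTERN.match(s))
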