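"""Canonical unordered protein pairs.

Every table in the pipeline is keyed by an *unordered* pair of protein
identifiers.  The canonical form sorts the two identifiers
lexicographically, so ``(B, A)`` and ``(A, B)`` collapse to the same key.
Self-pairs are rejected: none of the evidence or scoring rules are defined
for a protein interacting with itself.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Tuple

Pair = Tuple[str, str]


class SelfPairError(ValueError):
    """Raised when the two members of a pair are the same identifier."""


def canonical_pair(a: str, b: str) -> Pair:
    """Return the canonical (lexicographically sorted) form of a pair.

    Raises
    ------
    ValueError
        If either identifier is empty.
    SelfPairError
        If the two identifiers are equal after stripping whitespace.
    """
    a = str(a).strip()
    b = str(b).strip()
    if not a or not b:
        raise ValueError(f"empty protein identifier in pair ({a!r}, {b!r})")
    if a == b:
        raise SelfPairError(f"self-pair ({a}, {a}) is not allowed")
    return (a, b) if a < b else (b, a)


def iter_canonical(pairs: Iterable[Tuple[str, str]], *, drop_self: bool = True) -> Iterator[Pair]:
    """Canonicalize a stream of pairs, silently dropping self-pairs if asked."""
    for a, b in pairs:
        try:
            yield canonical_pair(a, b)
        except SelfPairError:
            if not drop_self:
                raise


def canonical_set(pairs: Iterable[Tuple[str, str]]) -> set:
    """Canonicalize into a set (self-pairs dropped, duplicates merged)."""
    return set(iter_canonical(pairs))
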