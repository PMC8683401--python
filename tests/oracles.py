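"""Independent reference implementations used only as test oracles.

The pattern-matching oracle enumerates every per-element repeat expansion via
a reachable-position set (breadth-first over element expansions), touching
none of the production scanning code paths; letter matching is re-derived
from the element fields rather than reusing the production matcher.
"""

from __future__ import annotations

import random

from famscreen.pattern_engine import (
    ElementKind,
    MotifPattern,
    PatternElement,
)

STANDARD = "ACDEFGHIKLMNPQRSTVWY"


def _letter_ok(el: PatternElement, ch: str) -> bool:
    if el.kind is ElementKind.WILDCARD:
        return True
    if ch not in STANDARD:
        return False
    if el.kind is ElementKind.EXCLUDED:
        return ch not in el.residues
    return ch in el.residues


def oracle_match_ends(pattern: MotifPattern, seq: str, start: int) -> set[int]:
    """All end positions of complete matches anchored at ``start``."""
    reachable = {start}
    for el in pattern.elements:
        nxt: set[int] = set()
        for pos in reachable:
            hi = min(el.max_repeat, len(seq) - pos)
            for r in range(el.min_repeat, hi + 1):
                if all(_letter_ok(el, seq[pos + k]) for k in range(r)):
                    nxt.add(pos + r)
        reachable = nxt
        if not reachable:
            return set()
    if pattern.anchored_end:
        reachable &= {len(seq)}
    return reachable


def oracle_count(pattern: MotifPattern, seq: str) -> int:
    seq = seq.upper()
    starts = [0] if pattern.anchored_start else range(len(seq) + 1)
    return sum(bool(oracle_match_ends(pattern, seq, s)) for s in starts)


def random_pattern(rng: random.Random, max_elements: int = 8) -> MotifPattern:
    """A random small pattern covering all element kinds and repeat shapes."""
    n = rng.randint(1, max_elements)
    elements = []
    for _ in range(n):
        kind = rng.choice(
            [ElementKind.FIXED, ElementKind.CLASS, ElementKind.EXCLUDED,
             ElementKind.WILDCARD, ElementKind.WILDCARD]
        )
        if kind is ElementKind.WILDCARD:
            lo = rng.randint(0, 2)
            hi = lo + rng.randint(0, 3)
            elements.append(PatternElement(kind, frozenset(), lo, hi))
            continue
        k = 1 if kind is ElementKind.FIXED else rng.randint(1, 4)
        residues = frozenset(rng.sample(STANDARD, k))
        lo = rng.randint(1, 2)
        hi = lo + rng.randint(0, 2)
        elements.append(PatternElement(kind, residues, lo, hi))
    try:
        return MotifPattern(tuple(elements), name="random")
    except Exception:
        # all-zero-span pattern: retry
        return random_pattern(rng, max_elements)


def random_sequence(rng: random.Random, max_len: int = 60) -> str:
    alphabet = STANDARD + "XBZU"
    weights = [10] * 20 + [1, 1, 1, 1]
    n = rng.randint(0, max_len)
    return "".join(rng.choices(alphabet, weights=weights, k=n))
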