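"""Naive reference deduplicators used as ground truth in tests.

These reimplement the duplicate semantics literally and independently — a
plain built-in sort followed by an in-memory scan, with their own comparator
code — sharing nothing with the streaming engine beyond the domain types.
Agreement between the two paths is therefore evidence, not tautology.
Quadratic-ish and memory-unbounded by intent; test scale only.
"""

from __future__ import annotations

from typing import Sequence

from .modes import ComparatorSpec
from .records import DedupUnit


def _seqs(unit: DedupUnit) -> list[str]:
    out = [unit.left.sequence.upper()]
    if unit.right is not None:
        out.append(unit.right.sequence.upper())
    return out


def _key(unit: DedupUnit) -> tuple[bytes, int]:
    seqs = _seqs(unit)
    return (b"\x00".join(s.encode("ascii") for s in seqs), unit.index)


def _equal(a: str, b: str) -> bool:
    return a == b


def _prefix_match(a: str, b: str) -> bool:
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    return longer.startswith(shorter)


def _hamming_within(a: str, b: str, k: int) -> bool:
    if len(a) != len(b):
        return False
    return sum(1 for x, y in zip(a, b) if x != y) <= k


def _is_dup(candidate: DedupUnit, reference: DedupUnit, spec: ComparatorSpec) -> bool:
    for s_cand, s_ref in zip(_seqs(candidate), _seqs(reference)):
        if spec.mode == "tight":
            ok = _equal(s_cand, s_ref)
        elif spec.mode == "loose":
            ok = _prefix_match(s_cand, s_ref)
        else:
            ok = _hamming_within(s_cand, s_ref, spec.hamming_max)
        if not ok:
            return False
    return True


def oracle_seqbased(units: Sequence[DedupUnit], spec: ComparatorSpec) -> list[str]:
    """Kept read IDs of the sequence-based engine, computed the slow way.

    Sorts in memory by (sequence key, input index), then scans: tight/loose
    against the current group representative, tail_hamming against the
    immediate predecessor in sorted order.
    """
    ordered = sorted(units, key=_key)
    kept: list[str] = []
    reference: DedupUnit | None = None
    for unit in ordered:
        if reference is not None and _is_dup(unit, reference, spec):
            if spec.mode == "tail_hamming":
                reference = unit
            continue
        kept.append(unit.left.id)
        reference = unit
    return kept


def oracle_exact(units: Sequence[DedupUnit]) -> list[str]:
    """First occurrence of each distinct sequence (pair), input order, text keys."""
    seen: set[tuple[str, ...]] = set()
    kept: list[str] = []
    for unit in units:
        key = tuple(_seqs(unit))
        if key in seen:
            continue
        seen.add(key)
        kept.append(unit.left.id)
    return kept
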