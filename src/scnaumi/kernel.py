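"""Bitwise barcode kernel: 2-bit DNA encoding, single-edit enumeration and
edit-distance-bounded search of a candidate barcode set.

Cell barcodes (16 nt) and UMIs (10 or 12 nt) are packed two bits per base
into a single Python integer (A=00, G=01, T=10, C=11), so that testing
whether an error-mutated read window equals a known barcode is one integer
comparison / one hash lookup.  Sequencing errors are explored by generating
all single-edit descendants of the extracted read window: for a core of
length ``L`` with a trailing extension buffer there are ``3L`` substitutions,
``4L`` insertions and ``L`` deletions, i.e. ``8L`` descendants per round
(128 for the 16-nt cell barcode).  Deletions pull the next extension base
into the core and insertions push the last core base out, so every
descendant stays directly comparable, as one integer, with the candidate
barcodes.

:func:`find_match` offers two equivalent search strategies: breadth-first
enumeration of the edit descendants (efficient when the candidate set is
large, because each level is a batch of O(1) set-membership tests) and a
per-candidate banded prefix alignment (efficient for the small per-gene /
per-window candidate sets produced by the guide index).  The two are tested
against each other and against a brute-force Levenshtein oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import edlib

__all__ = [
    "EncodedSeq",
    "SearchWindow",
    "MatchResult",
    "encode",
    "decode",
    "enumerate_edits",
    "count_permutations",
    "find_match",
]

#: base -> 2-bit code
_BASE_BITS = {"A": 0b00, "G": 0b01, "T": 0b10, "C": 0b11}
#: 2-bit code -> base (index = code)
_BITS_BASE = "AGTC"

#: sentinel base used to pad a truncated extension buffer
PAD_BASE = "A"

MAX_LEN = 31


class EncodingError(ValueError):
    """Raised for sequences that cannot be packed (non-ACGT, bad length)."""


@dataclass(frozen=True)
class EncodedSeq:
    """A fixed-length DNA word packed 2 bits/base into one integer.

    Base at position ``i`` (0-based, 5'->3') occupies bits ``[2i, 2i+1]``
    with position 0 in the two least-significant bits; this makes appending
    or popping bases at either end shift-only operations.
    """

    value: int
    length: int

    def __post_init__(self) -> None:
        if not (1 <= self.length <= MAX_LEN):
            raise EncodingError(f"length must be in 1..{MAX_LEN}, got {self.length}")
        if self.value < 0 or self.value >> (2 * self.length):
            raise EncodingError("value has bits outside 2*length")

    def decode(self) -> str:
        return decode(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.decode()


def encode(seq: str) -> EncodedSeq:
    """Pack an ACGT string (length 1..31) into an :class:`EncodedSeq`.

    Raises :class:`EncodingError` on any non-ACGT character (including N);
    callers are expected to pre-filter such windows.
    """
    if not (1 <= len(seq) <= MAX_LEN):
        raise EncodingError(f"sequence length must be 1..{MAX_LEN}, got {len(seq)}")
    value = 0
    try:
        for i, base in enumerate(seq):
            value |= _BASE_BITS[base] << (2 * i)
    except KeyError as exc:
        raise EncodingError(f"non-ACGT base {exc.args[0]!r} in {seq!r}") from None
    return EncodedSeq(value=value, length=len(seq))


def decode(e: EncodedSeq) -> str:
    """Inverse of :func:`encode`."""
    return "".join(_BITS_BASE[(e.value >> (2 * i)) & 0b11] for i in range(e.length))


@dataclass(frozen=True)
class SearchWindow:
    """An extracted read window: a barcode-length core plus up to 4 trailing
    extension bases that deletions may pull into the core.

    When the read ends before 4 extension bases are available the window is
    ``truncated``; edits that have to consume padded (sentinel) extension
    bases are demoted by one pseudo-edit.
    """

    core: str
    extension: str = ""

    def __post_init__(self) -> None:
        if len(self.extension) > 4:
            raise ValueError("extension buffer is at most 4 bases")

    @property
    def core_length(self) -> int:
        return len(self.core)

    @property
    def truncated(self) -> bool:
        return len(self.extension) < 4


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one read window against a candidate set.

    ``ambiguous`` is set when two or more distinct candidates tie at the
    best edit distance; such reads are not assigned (``matched is None``)
    but the tie multiplicity is reported in ``n_candidates_at_best``.
    """

    matched: Optional[EncodedSeq]
    ed: Optional[int]
    second_best_ed: Optional[int] = None
    ambiguous: bool = False
    n_candidates_at_best: int = 0
    #: number of window bases consumed by the best match (core length
    #: plus net deletions minus insertions); None when unmatched/ambiguous.
    consumed: Optional[int] = None


# ---------------------------------------------------------------------------
# single-edit enumeration
# ---------------------------------------------------------------------------

# internal mutable search state: (core_value, ext_value, ext_len, pad_used)
# core_value/ext_value use the same 2-bit little-endian packing as EncodedSeq.


def _state_from_window(w: SearchWindow) -> tuple[int, int, int, bool]:
    core = encode(w.core).value
    ext = encode(w.extension).value if w.extension else 0
    return core, ext, len(w.extension), False


def _state_children(
    core: int, ext: int, ext_len: int, pad: bool, L: int
) -> Iterator[tuple[int, int, int, bool]]:
    """All 8L single-edit descendants of a state (3L sub, 4L ins, L del)."""
    full_mask = (1 << (2 * L)) - 1
    top_shift = 2 * (L - 1)
    # substitutions: flip position i to each of the 3 other codes
    for i in range(L):
        shift = 2 * i
        cur = (core >> shift) & 0b11
        base_cleared = core & ~(0b11 << shift)
        for code in range(4):
            if code != cur:
                yield base_cleared | (code << shift), ext, ext_len, pad
    # insertions: insert code before position i; last core base is pushed
    # out of the core and prepended to the extension (read continuation).
    for i in range(L):
        shift = 2 * i
        low = core & ((1 << shift) - 1)
        high = core >> shift
        pushed = (core >> top_shift) & 0b11
        new_ext = (pushed | (ext << 2)) & ((1 << (2 * 4)) - 1)
        new_ext_len = min(ext_len + 1, 4)
        for code in range(4):
            new_core = (low | (code << shift) | (high << (shift + 2))) & full_mask
            yield new_core, new_ext, new_ext_len, pad
    # deletions: drop position i, pull the first extension base into the
    # core; an exhausted extension pulls the sentinel (pad) base instead.
    for i in range(L):
        shift = 2 * i
        low = core & ((1 << shift) - 1)
        high = core >> (shift + 2)
        if ext_len > 0:
            pulled = ext & 0b11
            new_ext, new_ext_len, new_pad = ext >> 2, ext_len - 1, pad
        else:
            pulled = _BASE_BITS[PAD_BASE]
            new_ext, new_ext_len, new_pad = 0, 0, True
        yield low | (high << shift) | (pulled << top_shift), new_ext, new_ext_len, new_pad


def enumerate_edits(w: SearchWindow) -> Iterator[SearchWindow]:
    """Yield the 8L single-edit descendants of a window (128 for L=16).

    Descendants keep the core length; their extensions reflect the pushed /
    pulled bases so that further rounds of editing remain consistent with
    the underlying read sequence.
    """
    L = w.core_length
    for core, ext, ext_len, _pad in _state_children(*_state_from_window(w), L):
        yield SearchWindow(
            core=decode(EncodedSeq(core, L)),
            extension=decode(EncodedSeq(ext, ext_len)) if ext_len else "",
        )


def count_permutations(core_length: int, max_ed: int, mode: str = "full") -> int:
    """Number of edited candidate sequences generated by the branching
    process for edit budgets ``1..max_ed`` (the unedited sequence excluded).

    ``mode='full'`` counts substitutions, insertions and deletions
    (branching factor 8L, i.e. 128 for L=16); ``mode='substitutions_only'``
    counts 3L.  Sequences reachable via several edit paths are counted once
    per path — this is the generated-permutation accounting, not a count of
    distinct sequences.
    """
    if max_ed < 0:
        raise ValueError("max_ed must be >= 0")
    if mode == "full":
        branch = 8 * core_length
    elif mode == "substitutions_only":
        branch = 3 * core_length
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return sum(branch**i for i in range(1, max_ed + 1))


# ---------------------------------------------------------------------------
# bounded search
# ---------------------------------------------------------------------------


def _finalize(
    costs: dict[int, tuple[int, int]], length: int, max_ed: int
) -> MatchResult:
    """Build a MatchResult from candidate-value -> (cost, consumed)."""
    if not costs:
        return MatchResult(None, None, None, False, 0)
    best = min(c for c, _ in costs.values())
    best_set = [v for v, (c, _) in costs.items() if c == best]
    others = [c for v, (c, _) in costs.items() if c > best]
    second = min(others) if others else None
    if len(best_set) >= 2:
        return MatchResult(None, None, second, True, len(best_set))
    v = best_set[0]
    return MatchResult(
        EncodedSeq(v, length), best, second, False, 1, consumed=costs[v][1]
    )


def _find_match_enum(
    w: SearchWindow, cand_values: dict[int, None], L: int, max_ed: int
) -> MatchResult:
    """Breadth-first enumeration over edit levels with state de-duplication.

    A state's cost is its edit depth plus one pseudo-edit if any of its
    edits consumed a padded extension base; matches above ``max_ed`` after
    demotion are rejected.
    """
    costs: dict[int, tuple[int, int]] = {}

    def register(core: int, cost: int, consumed: int) -> None:
        if cost <= max_ed and core in cand_values:
            prev = costs.get(core)
            if prev is None or cost < prev[0]:
                costs[core] = (cost, consumed)

    start = _state_from_window(w)
    start_ext_len = start[2]
    register(start[0], 0, L)
    frontier = {start}
    seen = {start}
    for depth in range(1, max_ed + 1):
        nxt = set()
        for state in frontier:
            for child in _state_children(*state, L):
                if child in seen:
                    continue
                seen.add(child)
                nxt.add(child)
                core, _ext, ext_len, pad = child
                # consumed = L + (#deletions - #insertions); recover the net
                # shift from how much extension remains vs. the start.
                consumed = L + (start_ext_len - ext_len) if not pad else L + 4
                register(core, depth + (1 if pad else 0), consumed)
        frontier = nxt
        if not frontier:
            break
    return _finalize(costs, L, max_ed)


def _find_match_direct(
    w: SearchWindow, cand_values: dict[int, None], L: int, max_ed: int
) -> MatchResult:
    """Per-candidate prefix alignment, equivalent to the enumeration.

    The cost of a candidate is the minimum over window prefixes ``m`` of
    ``Levenshtein(candidate, (core+extension+pad)[:m])`` plus one
    pseudo-edit for prefixes reaching into padded extension positions —
    exactly the demotion rule the enumeration applies.
    """
    target = w.core + w.extension
    avail = len(target)
    padded = target + PAD_BASE * (L + 4 - avail) if w.truncated else target
    costs: dict[int, tuple[int, int]] = {}
    for value in cand_values:
        cand = decode(EncodedSeq(value, L))
        if not w.truncated:
            # one semi-global call: min edit distance to any prefix of target
            res = edlib.align(cand, target, mode="SHW", k=max_ed)
            d = res["editDistance"]
            if d < 0 or d > max_ed:
                continue
            consumed = res["locations"][0][1] + 1
            costs[value] = (d, consumed)
        else:
            best: Optional[tuple[int, int]] = None
            for m in range(max(1, L - max_ed), min(len(padded), L + max_ed) + 1):
                d = edlib.align(cand, padded[:m], mode="NW")["editDistance"]
                cost = d + (1 if m > avail else 0)
                if cost <= max_ed and (best is None or cost < best[0]):
                    best = (cost, m)
            if best is not None:
                costs[value] = best
    return _finalize(costs, L, max_ed)


#: candidate-set size above which the enumeration strategy is preferred
ENUM_THRESHOLD = 64


def find_match(
    w: SearchWindow,
    candidates: Iterable[EncodedSeq],
    max_ed: int,
    strategy: str = "auto",
) -> MatchResult:
    """Match a read window against a candidate barcode set within ``max_ed``.

    Searches edit levels 0,1,...,max_ed; reports the best edit distance,
    the tie multiplicity at that level (ambiguous reads are not assigned)
    and the next level at which a *different* candidate is hit
    (``second_best_ed``), scanned up to ``max_ed``.  Candidates reachable
    via multiple edit paths are counted once.

    ``strategy``: 'enum' (bitwise breadth-first enumeration), 'direct'
    (per-candidate prefix alignment) or 'auto' (direct for small sets,
    enumeration for large ones).  The two strategies return identical
    results; see the property tests.
    """
    if not (0 <= max_ed <= 4):
        raise ValueError("max_ed must be in 0..4")
    cands = list(candidates)
    if not cands:
        return MatchResult(None, None, None, False, 0)
    L = w.core_length
    for c in cands:
        if c.length != L:
            raise ValueError("candidate length differs from window core length")
    cand_values = dict.fromkeys(c.value for c in cands)
    if strategy == "auto":
        # the enumeration wins for large candidate sets (each level is a
        # batch of set-membership tests) but its state space grows ~128**ed,
        # so deep searches over small sets go through per-candidate alignment
        strategy = (
            "enum" if len(cand_values) > ENUM_THRESHOLD and max_ed <= 3 else "direct"
        )
    if strategy == "enum":
        return _find_match_enum(w, cand_values, L, max_ed)
    if strategy == "direct":
        return _find_match_direct(w, cand_values, L, max_ed)
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# calibration support: distinct-neighbour counting
# ---------------------------------------------------------------------------


def count_distinct_cores(w: SearchWindow, max_depth: int) -> list[int]:
    """Distinct core sequences reachable within 0..max_depth edits.

    Returns cumulative counts per depth (index 0 = just the unedited core).
    Used by the edit-distance-policy calibration to estimate the collision
    volume of the search around a random window.
    """
    L = w.core_length
    start = _state_from_window(w)
    seen_states = {start}
    cores = {start[0]}
    out = [1]
    frontier = {start}
    for _ in range(max_depth):
        nxt = set()
        for state in frontier:
            for child in _state_children(*state, L):
                if child not in seen_states:
                    seen_states.add(child)
                    nxt.add(child)
                    cores.add(child[0])
        frontier = nxt
        out.append(len(cores))
    return out
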