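"""Barcode kernel: 2-bit encoding, edit enumeration, bounded search.

The brute-force oracle used throughout is an independent dynamic-programming
Levenshtein implementation (no shared code with the kernel, which uses
bitwise enumeration and edlib prefix alignment).
"""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scnaumi.kernel import (
    EncodedSeq,
    EncodingError,
    SearchWindow,
    count_permutations,
    decode,
    encode,
    enumerate_edits,
    find_match,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=31)


def levenshtein(a: str, b: str) -> int:
    """Textbook DP edit distance (the oracle; deliberately naive)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def oracle_best(window: SearchWindow, candidates: list[str], max_ed: int):
    """Minimal end-gap-free distance of each candidate to a prefix of
    core+extension (prefix lengths L-max_ed .. L+|extension|)."""
    target = window.core + window.extension
    L = len(window.core)
    per_cand = {}
    for cand in candidates:
        best = None
        for m in range(max(0, L - max_ed), min(len(target), L + max_ed) + 1):
            d = levenshtein(cand, target[:m])
            if d <= max_ed and (best is None or d < best):
                best = d
        if best is not None:
            per_cand[cand] = best
    return per_cand


class TestEncoding:
    def test_bit_code_assignments(self):
        assert encode("A").value == 0b00
        assert encode("G").value == 0b01
        assert encode("T").value == 0b10
        assert encode("C").value == 0b11

    def test_packing_convention_position0_least_significant(self):
        # "AC": A in bits [0,1], C in bits [2,3]
        assert encode("AC").value == 0b1100
        assert decode(EncodedSeq(0b1100, 2)) == "AC"

    @given(dna)
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, s):
        e = encode(s)
        assert decode(e) == s
        assert e.length == len(s)

    def test_equality_iff_same_string(self):
        assert encode("ACGT") == encode("ACGT")
        assert encode("ACGT") != encode("ACGA")
        # same value, different length: distinct sequences
        assert encode("A") != encode("AA")

    @pytest.mark.parametrize("bad", ["ACGN", "acgt", "", "A" * 32])
    def test_rejects_invalid(self, bad):
        with pytest.raises(EncodingError):
            encode(bad)


class TestEnumeration:
    @pytest.mark.parametrize("L,expected", [(16, 128), (10, 80)])
    def test_branching_count(self, L, expected):
        rng = random.Random(L)
        w = SearchWindow(
            core="".join(rng.choice("ACGT") for _ in range(L)),
            extension="".join(rng.choice("ACGT") for _ in range(4)),
        )
        children = list(enumerate_edits(w))
        assert len(children) == expected
        assert all(len(c.core) == L for c in children)

    def test_all_descendants_within_one_edit_of_parent_prefixes(self):
        rng = random.Random(7)
        w = SearchWindow(
            core="".join(rng.choice("ACGT") for _ in range(16)),
            extension="".join(rng.choice("ACGT") for _ in range(4)),
        )
        target = w.core + w.extension
        for child in enumerate_edits(w):
            best = min(
                levenshtein(child.core, target[:m]) for m in range(15, 21)
            )
            assert best <= 1

    def test_deletion_pulls_extension_base(self):
        w = SearchWindow(core="AAAA" * 4, extension="CGTA")
        cores = {c.core for c in enumerate_edits(w)}
        # deleting any core position pulls the C into the last position
        assert "A" * 15 + "C" in cores


class TestCountPermutations:
    def test_substitutions_only_ed1(self):
        assert count_permutations(16, 1, "substitutions_only") == 48

    def test_full_ed3(self):
        assert count_permutations(16, 3, "full") == 2_113_664

    def test_zero_budget(self):
        assert count_permutations(16, 0, "full") == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            count_permutations(16, -1, "full")


class TestFindMatch:
    def _win(self, rng, L=16):
        return SearchWindow(
            core="".join(rng.choice("ACGT") for _ in range(L)),
            extension="".join(rng.choice("ACGT") for _ in range(4)),
        )

    def test_exact_match(self):
        rng = random.Random(0)
        w = self._win(rng)
        res = find_match(w, [encode(w.core)], 2)
        assert res.ed == 0 and not res.ambiguous and res.matched.decode() == w.core

    def test_single_substitution(self):
        w = SearchWindow(core="ACGTACGTACGTACGT", extension="AAAA")
        cand = "ACGTACGTACGTACGA"
        res = find_match(w, [encode(cand)], 2)
        assert res.ed == 1 == levenshtein(w.core, cand)

    def test_constructed_tie_is_ambiguous(self):
        w = SearchWindow(core="A" * 16, extension="CCCC")
        cands = [encode("A" * 15 + "G"), encode("A" * 15 + "T")]
        res = find_match(w, cands, 2)
        assert res.ambiguous and res.matched is None and res.ed is None
        assert res.n_candidates_at_best == 2

    def test_empty_candidates(self):
        w = SearchWindow(core="A" * 16, extension="AAAA")
        res = find_match(w, [], 3)
        assert res.matched is None and res.ed is None

    def test_second_best_recorded(self):
        w = SearchWindow(core="ACGTACGTACGTACGT", extension="AAAA")
        cands = [encode("ACGTACGTACGTACGT"), encode("ACGTACGTACGTACAA")]
        res = find_match(w, cands, 3)
        assert res.ed == 0
        assert res.second_best_ed is not None and res.second_best_ed >= 1

    @pytest.mark.parametrize("seed", range(3))
    def test_strategies_agree(self, seed):
        rng = random.Random(seed)
        for _ in range(30):
            L = rng.choice([10, 16])
            w = self._win(rng, L)
            cands = []
            for _ in range(rng.randint(1, 20)):
                base = list(w.core)
                for _ in range(rng.randint(0, 3)):
                    base[rng.randrange(L)] = rng.choice("ACGT")
                cands.append(encode("".join(base)))
            max_ed = rng.randint(0, 2)
            a = find_match(w, cands, max_ed, strategy="enum")
            b = find_match(w, cands, max_ed, strategy="direct")
            assert (a.matched, a.ed, a.ambiguous, a.n_candidates_at_best) == (
                b.matched,
                b.ed,
                b.ambiguous,
                b.n_candidates_at_best,
            )

    def test_determinism(self):
        rng = random.Random(5)
        w = self._win(rng)
        cands = [encode("".join(rng.choice("ACGT") for _ in range(16))) for _ in range(8)]
        assert find_match(w, cands, 3) == find_match(w, cands, 3)


class TestOracleEquivalence:
    """find_match against the brute-force Levenshtein oracle (1000 random
    instances: window, candidate set <= 32, max_ed <= 3)."""

    def test_thousand_instances(self):
        rng = random.Random(20240917)
        for _ in range(1000):
            L = 16
            core = "".join(rng.choice("ACGT") for _ in range(L))
            ext = "".join(rng.choice("ACGT") for _ in range(4))
            w = SearchWindow(core=core, extension=ext)
            n_cands = rng.randint(1, 32)
            cands = []
            for _ in range(n_cands):
                if rng.random() < 0.5:
                    # near-miss candidate: mutate the core a little
                    base = list(core)
                    for _ in range(rng.randint(0, 4)):
                        op = rng.random()
                        pos = rng.randrange(len(base))
                        if op < 0.6:
                            base[pos] = rng.choice("ACGT")
                        elif op < 0.8 and len(base) > 1:
                            del base[pos]
                        else:
                            base.insert(pos, rng.choice("ACGT"))
                    cand = ("".join(base) + ext + "AAAA")[:L]
                else:
                    cand = "".join(rng.choice("ACGT") for _ in range(L))
                cands.append(cand)
            cands = sorted(set(cands))
            max_ed = rng.randint(0, 3)
            res = find_match(w, [encode(c) for c in cands], max_ed)
            expected = oracle_best(w, cands, max_ed)
            if not expected:
                assert res.matched is None and not res.ambiguous
                continue
            best = min(expected.values())
            winners = [c for c, d in expected.items() if d == best]
            if len(winners) > 1:
                assert res.ambiguous and res.n_candidates_at_best == len(winners)
            else:
                assert res.matched is not None, (w, cands, max_ed)
                assert res.ed == best
                assert res.matched.decode() == winners[0]
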