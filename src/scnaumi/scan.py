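"""Structural parse of long cDNA reads.

A 10x-style long read carries, on the barcode strand,

    adapter(3' PCR priming site) - cellBC(16) - UMI(10/12) - poly(T) - cDNA(rc) - TSO(rc)

so the barcode windows sit between the adapter and the poly(T).  The scan
locates a terminal poly(A)/poly(T) (>=20 nt at >=85% composition within
100 nt of a read end), canonicalizes orientation (poly(T) at the 5' end),
finds the adapter by sliding alignment of its terminal 10 nt (<=3
substitutions+indels), flags chimeric concatemers (an internal adapter next
to an A/T-rich tract), and emits the barcode/UMI extraction windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib

from .kernel import SearchWindow

__all__ = [
    "ADAPTER",
    "TSO",
    "PolyAResult",
    "ReadScan",
    "find_polyA",
    "find_adapter",
    "flag_internal_adapter",
    "scan_read",
    "revcomp",
]

#: 10x Genomics 3' PCR priming site (partial read-1 sequence)
ADAPTER = "CTACACGACGCTCTTCCGATCT"
#: template-switch oligo
TSO = "AAGCAGTGGTATCAACGCAGAGTACAT"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _at_runs(seq: str, base: str, min_len: int, min_frac: float) -> list[tuple[int, int]]:
    """Maximal runs of >=min_len windows with >=min_frac `base` content.

    A position belongs to a run if it is covered by at least one qualifying
    sliding window of length ``min_len``; overlapping qualifying windows are
    merged, then each run is trimmed to its outermost matching base so the
    reported boundaries land on actual A/T positions.  N never counts as
    A/T.
    """
    n = len(seq)
    if n < min_len:
        return []
    need = min_frac * min_len
    hits = [1 if c == base else 0 for c in seq]
    count = sum(hits[:min_len])
    runs: list[tuple[int, int]] = []
    cur: Optional[list[int]] = None
    for s in range(0, n - min_len + 1):
        if s > 0:
            count += hits[s + min_len - 1] - hits[s - 1]
        if count >= need:
            if cur is not None and s <= cur[1]:
                cur[1] = s + min_len
            else:
                if cur is not None:
                    runs.append(tuple(cur))
                cur = [s, s + min_len]
    if cur is not None:
        runs.append(tuple(cur))
    trimmed = []
    for s, e in runs:
        # tighten both boundaries: the terminal base must be the target
        # base and the terminal min_len window must itself satisfy the
        # composition rule, so the run cannot bleed into adjacent sequence
        min_core = int(min_len * min_frac + 0.999)  # e.g. 17 of a 20-mer
        # boundary refinement: prefer boundaries on a clean 3-base
        # homopolymer stretch whose terminal window holds the composition
        # (stops the run bleeding into adjacent T/A-containing sequence);
        # fall back to single-base boundaries when that erases the run,
        # so a 17-of-20 tail with mismatches at its edges is still called.
        for anchor in (3, 1):
            s2, e2 = s, e
            while e2 - s2 >= min_core:
                if seq[e2 - anchor : e2] != base * anchor:
                    e2 -= 1
                    continue
                w = seq[max(s2, e2 - min_len) : e2]
                if w.count(base) < min_frac * len(w):
                    e2 -= 1
                    continue
                break
            while e2 - s2 >= min_core:
                if seq[s2 : s2 + anchor] != base * anchor:
                    s2 += 1
                    continue
                w = seq[s2 : min(e2, s2 + min_len)]
                if w.count(base) < min_frac * len(w):
                    s2 += 1
                    continue
                break
            if e2 - s2 >= min_core:
                trimmed.append((s2, e2))
                break
    return trimmed


@dataclass(frozen=True)
class PolyAResult:
    """Terminal poly(A)/poly(T) call: kind in {none, at_5prime, at_3prime, both}."""

    kind: str
    polyt: Optional[tuple[int, int]] = None  # [start, end) of 5' poly(T)
    polya: Optional[tuple[int, int]] = None  # [start, end) of 3' poly(A)


def find_polyA(
    seq: str,
    min_len: int = 20,
    min_frac: float = 0.85,
    end_window: int = 100,
) -> PolyAResult:
    """Search for a 5' poly(T) and a 3' poly(A) within the terminal windows.

    The default rule (>=20 nt at >=85% A or T, within 100 nt of the read
    end) is equivalent, at the minimum length, to requiring at least 17 As
    in a 20-mer.  Reads qualifying at both ends are chimera suspects and
    are reported as ``both``.
    """
    head = seq[: min(end_window, len(seq))]
    t_runs = []
    for s, e in _at_runs(head, "T", min_len, min_frac):
        # a run may continue past the terminal search window: the rule only
        # requires it to start within 100 nt of the end
        while e < len(seq) and seq[e] == "T":
            e += 1
        t_runs.append((s, e))
    tail_off = max(0, len(seq) - end_window)
    a_runs = []
    for s, e in _at_runs(seq[tail_off:], "A", min_len, min_frac):
        s, e = s + tail_off, e + tail_off
        while s > 0 and seq[s - 1] == "A":
            s -= 1
        a_runs.append((s, e))
    polyt = t_runs[0] if t_runs else None  # first qualifying run from the 5' end
    polya = a_runs[-1] if a_runs else None  # last qualifying run at the 3' end
    if polyt and polya:
        return PolyAResult("both", polyt, polya)
    if polyt:
        return PolyAResult("at_5prime", polyt=polyt)
    if polya:
        return PolyAResult("at_3prime", polya=polya)
    return PolyAResult("none")


def find_adapter(
    seq: str,
    polyt_pos: int,
    probe: str = ADAPTER[-10:],
    max_mismatch: int = 3,
) -> Optional[tuple[int, int]]:
    """Locate the adapter probe between the read 5' extremity and the poly(T).

    Sliding global alignment of the probe (substitutions and indels all
    cost 1); the position with the least total cost wins, ties going to the
    position closest to the read extremity.  Returns ``(adapter_end,
    mismatches)`` with ``adapter_end`` the 0-based exclusive end of the
    match, or None if the best cost exceeds ``max_mismatch``.
    """
    region = seq[:polyt_pos]
    if not region:
        return None
    res = edlib.align(probe, region, mode="HW", task="locations", k=max_mismatch)
    if res["editDistance"] < 0:
        return None
    end = min(loc[1] for loc in res["locations"])
    return end + 1, res["editDistance"]


def flag_internal_adapter(
    seq: str,
    probe: str = ADAPTER[-10:],
    at_rich_window: int = 50,
    max_mismatch: int = 3,
    min_len: int = 20,
    min_frac: float = 0.85,
    exclude_terminal: int = 150,
) -> bool:
    """True iff an adapter match sits within ``at_rich_window`` nt of an
    internal A- or T-rich run — the signature of a chimeric concatemer.

    The terminal ``exclude_terminal`` nt at each end, already claimed by the
    legitimate adapter/poly(A), are excluded from the scan.
    """
    lo, hi = exclude_terminal, len(seq) - exclude_terminal
    if hi - lo < min_len:
        return False
    interior = seq[lo:hi]
    runs = _at_runs(interior, "A", min_len, min_frac) + _at_runs(
        interior, "T", min_len, min_frac
    )
    pad = at_rich_window + len(probe) + max_mismatch
    for s, e in runs:
        a = max(0, s - pad)
        b = min(len(interior), e + pad)
        res = edlib.align(probe, interior[a:b], mode="HW", k=max_mismatch)
        if res["editDistance"] >= 0:
            return True
    return False


@dataclass
class ReadScan:
    """Per-read structural parse in canonical (barcode-first) orientation.

    ``canon`` is the read sequence oriented adapter->BC->UMI->poly(T)->
    cDNA(rc); mRNA-sense coordinates (``te``/``pe`` used for cDNA
    extraction) refer to ``revcomp(canon)``.
    """

    status: str  # pass | no_polyA | polyA_both_ends | no_adapter
    orientation: Optional[str] = None  # forward | reverse
    canon: Optional[str] = None
    polya_start: Optional[int] = None  # poly(T) run start in canon coords
    polyt_end: Optional[int] = None
    adapter_end: Optional[int] = None
    adapter_mismatches: Optional[int] = None
    internal_adapter: bool = False
    bc_window: Optional[SearchWindow] = None
    umi_window: Optional[SearchWindow] = None
    umi_length: int = 10
    te: Optional[int] = None  # TSO end, mRNA-sense coords
    pe: Optional[int] = None  # poly(A) start, mRNA-sense coords
    te_found: bool = False
    mean_qv: Optional[float] = None

    def window_at(self, start: int, core_len: int) -> Optional[SearchWindow]:
        """Extraction window (core + up to 4 extension bases) at a canonical
        coordinate; None when the core would run past the read end or the
        window contains non-ACGT characters."""
        if start < 0 or self.canon is None or start + core_len > len(self.canon):
            return None
        core = self.canon[start : start + core_len]
        if any(c not in "ACGT" for c in core):
            return None
        ext = self.canon[start + core_len : start + core_len + 4]
        for i, c in enumerate(ext):  # truncate the buffer at the first ambiguous base
            if c not in "ACGT":
                ext = ext[:i]
                break
        return SearchWindow(core=core, extension=ext)


def scan_read(
    seq: str,
    quals: Optional[list[int]] = None,
    umi_len: int = 10,
    bc_len: int = 16,
    adapter: str = ADAPTER,
    tso: str = TSO,
    min_polya_len: int = 20,
    min_polya_frac: float = 0.85,
    end_window: int = 100,
    adapter_max_mismatch: int = 3,
    at_rich_window: int = 50,
) -> ReadScan:
    """Full structural parse of one read.

    Orientation: a 5' poly(T) means the read is already barcode-first
    (canonical); a 3' poly(A) means the reverse complement is.  The barcode
    window starts at the adapter end; the UMI window is re-anchored by the
    assignment stage once the barcode match fixes the net indel shift.
    """
    seq = seq.upper()
    mean_qv = (sum(quals) / len(quals)) if quals else None
    pa = find_polyA(seq, min_polya_len, min_polya_frac, end_window)
    if pa.kind == "none":
        return ReadScan(status="no_polyA", mean_qv=mean_qv)
    if pa.kind == "both":
        return ReadScan(status="polyA_both_ends", mean_qv=mean_qv)
    if pa.kind == "at_5prime":
        orientation, canon = "forward", seq
        polyt = pa.polyt
    else:
        orientation, canon = "reverse", revcomp(seq)
        # the 3' poly(A) becomes the 5' poly(T) after reverse complement
        s, e = pa.polya
        polyt = (len(seq) - e, len(seq) - s)
    probe = adapter[-10:]
    internal = flag_internal_adapter(
        canon,
        probe=probe,
        at_rich_window=at_rich_window,
        max_mismatch=adapter_max_mismatch,
        min_len=min_polya_len,
        min_frac=min_polya_frac,
    )
    hit = find_adapter(canon, polyt[0], probe=probe, max_mismatch=adapter_max_mismatch)
    if hit is None:
        return ReadScan(
            status="no_adapter",
            orientation=orientation,
            canon=canon,
            polya_start=polyt[0],
            polyt_end=polyt[1],
            internal_adapter=internal,
            mean_qv=mean_qv,
        )
    adapter_end, mism = hit
    scan = ReadScan(
        status="pass",
        orientation=orientation,
        canon=canon,
        polya_start=polyt[0],
        polyt_end=polyt[1],
        adapter_end=adapter_end,
        adapter_mismatches=mism,
        internal_adapter=internal,
        umi_length=umi_len,
        mean_qv=mean_qv,
    )
    scan.bc_window = scan.window_at(adapter_end, bc_len)
    scan.umi_window = scan.window_at(adapter_end + bc_len, umi_len)
    # mRNA-sense coordinates for cDNA extraction: the cDNA spans from the
    # TSO end (TE) to the poly(A) start (PE) on the mRNA strand.
    mrna = revcomp(canon)
    scan.pe = len(canon) - polyt[1]
    tso_probe = tso[-10:]
    res = edlib.align(
        tso_probe, mrna[: min(len(mrna), 200)], mode="HW", k=adapter_max_mismatch
    )
    if res["editDistance"] >= 0:
        scan.te = min(loc[1] for loc in res["locations"]) + 1
        scan.te_found = True
    else:
        scan.te = 0  # fallback: start of the mRNA-sense sequence
        scan.te_found = False
    return scan
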