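"""Guided cell-barcode and UMI assignment.

Each scanned read is matched only against the cell barcodes the short-read
guide data observed for its gene (or 500-nt genomic window), and — once a
cell is assigned — its UMI only against the UMIs observed for that
(gene-or-window, cell).  The maximal edit distance allowed for a search is
selected dynamically (1–4) from the size of the candidate set by a policy
calibrated so that the probability of a random window hitting the set stays
below a target false-assignment rate (defaults: 5% for cell barcodes, 2%
for UMIs).  The false-cell rate of reads surviving *both* stages is the
product of the two stage rates, because a wrongly assigned cell almost
never carries a matching UMI for the same gene.

Two accuracy estimators mirror that design: replacing each read's extracted
barcode by a random sequence (edit budget capped at the edit distance the
true pass used for that read) measures the false assignment probability,
and re-running assignment against an unrelated experiment's guide index
measures cross-contamination and the edit-distance inflation it causes.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .guide import GuideIndex, Key, WindowId
from .kernel import (
    EncodedSeq,
    MatchResult,
    SearchWindow,
    count_distinct_cores,
    decode,
    encode,
    find_match,
)
from .scan import ReadScan

__all__ = [
    "EdPolicy",
    "AssignmentRecord",
    "calibrate_ed_policy",
    "assign_cell",
    "assign_umi",
    "assign_reads",
    "estimate_accuracy_random",
    "estimate_accuracy_unrelated",
    "ed_histograms",
]

_BASES = "ACGT"

#: set-size bucket grid: powers of two, 1 .. 2**14
BUCKETS = tuple(2**i for i in range(15))


@dataclass
class EdPolicy:
    """Map from candidate-set size to the maximal allowed edit distance.

    ``table[bucket]`` holds the largest edit distance whose estimated
    collision probability for a search set of that size stays at or below
    ``target_false_rate``.  Set sizes between buckets round down to the
    nearest bucket; sizes above the top bucket use the top bucket.
    """

    table: dict[int, int]
    target_false_rate: float
    barcode_length: int
    n_sims: int = 0
    seed: Optional[int] = None

    def max_ed(self, set_size: int) -> int:
        if set_size < 1:
            return 0
        bucket = BUCKETS[0]
        for b in BUCKETS:
            if b <= set_size:
                bucket = b
            else:
                break
        return self.table[bucket]

    @classmethod
    def fixed(cls, max_ed: int, barcode_length: int) -> "EdPolicy":
        """Fixed edit-distance limit for every set size (no calibration)."""
        return cls(
            table={b: max_ed for b in BUCKETS},
            target_false_rate=float("nan"),
            barcode_length=barcode_length,
        )


def _collision_probs(
    barcode_length: int, n_sims: int, rng: random.Random, n_enum_windows: int = 3
) -> list[float]:
    """Per-candidate collision probabilities p_k for k = 0..4.

    p_k is the probability that one random barcode lies within edit
    distance k of a random read window (core + 4-base extension).  For
    k <= 3 it is estimated as the mean number of distinct cores reachable
    within k edits of a random window (exact enumeration with
    de-duplication on a small sample of windows) divided by 4**L.  For
    k = 4, where exhaustive enumeration is too large, it is estimated by
    Monte-Carlo sampling of (window, barcode) pairs, falling back to a
    growth-rate extrapolation of the enumeration counts when no collisions
    are sampled.
    """
    L = barcode_length
    total = 4.0**L
    counts = [0.0] * 4  # cumulative distinct cores for depth 0..3
    for _ in range(n_enum_windows):
        w = SearchWindow(
            core="".join(rng.choice(_BASES) for _ in range(L)),
            extension="".join(rng.choice(_BASES) for _ in range(4)),
        )
        c = count_distinct_cores(w, 3)
        for k in range(4):
            counts[k] += c[k] / n_enum_windows
    p = [counts[k] / total for k in range(4)]
    # depth 4 by pair sampling
    import edlib

    hits = 0
    for _ in range(n_sims):
        target = "".join(rng.choice(_BASES) for _ in range(L + 4))
        cand = "".join(rng.choice(_BASES) for _ in range(L))
        if edlib.align(cand, target, mode="SHW", k=4)["editDistance"] >= 0:
            hits += 1
    if hits:
        p4 = hits / n_sims
    else:
        growth = counts[3] / counts[2] if counts[2] else 1.0
        p4 = p[3] * growth
    p.append(max(p4, p[3]))
    return p


def calibrate_ed_policy(
    barcode_len: int = 16,
    target_false_rate: float = 0.05,
    n_sims: int = 20000,
    seed: int = 0,
) -> EdPolicy:
    """Simulate collision frequencies and derive the per-set-size edit limit.

    For a search set of ``s`` random distinct barcodes the probability that
    a random window matches at least one within edit distance k is
    ``1 - (1 - p_k)**s``; the policy allows the largest k (capped at 4)
    keeping that at or below ``target_false_rate``.
    """
    if n_sims < 10**4:
        raise ValueError("n_sims must be >= 10^4 for a stable calibration")
    rng = random.Random(seed)
    p = _collision_probs(barcode_len, n_sims, rng)
    table: dict[int, int] = {}
    for s in BUCKETS:
        k_max = 0
        for k in range(1, 5):
            if 1.0 - (1.0 - p[k]) ** s <= target_false_rate:
                k_max = k
        table[s] = k_max
    return EdPolicy(
        table=table,
        target_false_rate=target_false_rate,
        barcode_length=barcode_len,
        n_sims=n_sims,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# per-read assignment
# ---------------------------------------------------------------------------


@dataclass
class AssignmentRecord:
    """Assignment outcome for one read (UMI only set when the cell is)."""

    read_id: str
    cell: Optional[EncodedSeq] = None
    cell_ed: Optional[int] = None
    umi: Optional[EncodedSeq] = None
    umi_ed: Optional[int] = None
    key_source: Optional[str] = None  # gene | window
    key: Optional[Key] = None
    flags: set[str] = field(default_factory=set)
    # realized search parameters, kept for the random-replacement estimator
    cell_max_ed: Optional[int] = None
    umi_max_ed: Optional[int] = None
    umi_start: Optional[int] = None  # canonical coord of the UMI window

    @property
    def assigned(self) -> bool:
        return self.cell is not None and self.umi is not None


def _rank(res: MatchResult, max_ed: int) -> float:
    """Sort key for competing match results: clean hits by edit distance,
    ambiguous ties after any clean hit within the budget."""
    return res.ed if res.ed is not None else max_ed + 0.5


def _best_over_offsets(
    scan: ReadScan,
    candidates: set[EncodedSeq],
    max_ed: int,
    bc_len: int,
    offsets: Sequence[int] = (0, -1, 1),
) -> tuple[Optional[MatchResult], Optional[int]]:
    """Try the barcode window at the adapter end and at +/-1 to absorb
    terminal indels in the adapter match; keep the lowest-ed result (ties
    keep the earlier offset in the given order)."""
    best: Optional[MatchResult] = None
    best_off: Optional[int] = None
    for off in offsets:
        w = scan.window_at(scan.adapter_end + off, bc_len)
        if w is None:
            continue
        res = find_match(w, candidates, max_ed)
        if res.ed is None and not res.ambiguous:
            continue
        if best is None or _rank(res, max_ed) < _rank(best, max_ed):
            best, best_off = res, off
    return best, best_off


def assign_cell(
    scan: ReadScan,
    gene: Union[str, Sequence[str], None],
    window: Optional[WindowId],
    index: GuideIndex,
    policy: EdPolicy,
    read_id: str = "",
) -> AssignmentRecord:
    """Match the read's barcode windows against the guide cell set for its
    locus.  Reads overlapping several genes try each gene's set and keep
    the lower-ed hit (ties fall back to the window set).  Ambiguous matches
    are rejected."""
    rec = AssignmentRecord(read_id=read_id)
    if scan.internal_adapter:
        rec.flags.add("chimeric")
    if scan.status != "pass":
        return rec
    genes: list[Optional[str]]
    if gene is None:
        genes = [None]
    elif isinstance(gene, str):
        genes = [gene]
    else:
        genes = list(gene) or [None]
    tries: list[tuple[set[EncodedSeq], str, Optional[Key]]] = []
    seen_sources = set()
    for g in genes:
        cands, source = index.query_cells(g, window)
        key: Optional[Key] = g if source == "gene" else window
        marker = (source, key)
        if cands and marker not in seen_sources:
            seen_sources.add(marker)
            tries.append((cands, source, key))
    if len(genes) > 1:
        # multi-gene tie policy: the window set is the fallback candidate
        wcands, _ = index.query_cells(None, window)
        if wcands:
            tries.append((wcands, "window", window))
    best: Optional[tuple[MatchResult, int, str, Optional[Key], int]] = None
    for cands, source, key in tries:
        max_ed = policy.max_ed(len(cands))
        res, off = _best_over_offsets(scan, cands, max_ed, index.barcode_length)
        if res is None:
            continue
        if best is None or _rank(res, max_ed) < _rank(best[0], best[4]):
            best = (res, off, source, key, max_ed)
    if best is None:
        return rec
    res, off, source, key, max_ed = best
    rec.key_source, rec.key, rec.cell_max_ed = source, key, max_ed
    if res.ambiguous:
        rec.flags.add("ambiguous_cell")
        return rec
    rec.cell, rec.cell_ed = res.matched, res.ed
    rec.umi_start = scan.adapter_end + off + res.consumed
    return rec


def assign_umi(
    rec: AssignmentRecord,
    scan: ReadScan,
    index: GuideIndex,
    policy: EdPolicy,
) -> AssignmentRecord:
    """Match the UMI window (re-anchored after the matched barcode) against
    the guide UMIs for the assigned (gene-or-window, cell)."""
    if rec.cell is None or rec.key is None:
        return rec
    cands = index.query_umis(rec.key, rec.cell)
    if not cands:
        return rec
    max_ed = policy.max_ed(len(cands))
    rec.umi_max_ed = max_ed
    w = scan.window_at(rec.umi_start, index.umi_length)
    if w is None:
        return rec
    res = find_match(w, cands, max_ed)
    if res.ambiguous:
        rec.flags.add("ambiguous_umi")
        return rec
    if res.matched is not None:
        rec.umi, rec.umi_ed = res.matched, res.ed
    return rec


@dataclass
class AssignmentRun:
    """Assignment records plus the read-fate funnel of one pass."""

    records: list[AssignmentRecord]
    scan_counts: Counter = field(default_factory=Counter)

    @property
    def n_cell_assigned(self) -> int:
        return sum(1 for r in self.records if r.cell is not None)

    @property
    def n_assigned(self) -> int:
        return sum(1 for r in self.records if r.assigned)


def assign_reads(
    items: Iterable[tuple[str, ReadScan, Union[str, Sequence[str], None], Optional[WindowId]]],
    index: GuideIndex,
    cell_policy: EdPolicy,
    umi_policy: EdPolicy,
) -> AssignmentRun:
    """Assign a stream of (read_id, scan, gene, window) items."""
    records = []
    counts: Counter = Counter()
    for read_id, scan, gene, window in items:
        counts[scan.status] += 1
        rec = assign_cell(scan, gene, window, index, cell_policy, read_id=read_id)
        rec = assign_umi(rec, scan, index, umi_policy)
        records.append(rec)
    return AssignmentRun(records=records, scan_counts=counts)


# ---------------------------------------------------------------------------
# accuracy estimation
# ---------------------------------------------------------------------------


def _random_window(rng: random.Random, core_len: int) -> SearchWindow:
    return SearchWindow(
        core="".join(rng.choice(_BASES) for _ in range(core_len)),
        extension="".join(rng.choice(_BASES) for _ in range(4)),
    )


def estimate_accuracy_random(
    run: AssignmentRun,
    index: GuideIndex,
    seed: int = 0,
) -> dict:
    """Random-replacement estimate of the assignment accuracy.

    For every read assigned both a cell and a UMI, the extracted barcode
    (resp. UMI) window is replaced by a uniform random sequence and the
    stage is re-run with the edit budget capped at the edit distance the
    true pass realized for that read; the cell-stage replacement keeps the
    downstream UMI stage in place, so a random cell hit must also survive
    the UMI check to count.  Accuracy = 100 * (1 - assigned_random /
    assigned).  Reads unassigned in the true pass are excluded.
    """
    rng = random.Random(seed)
    assigned = [r for r in run.records if r.assigned]
    if not assigned:
        return {"cell_accuracy": None, "umi_accuracy": None, "assigned": 0}
    cell_rand = 0
    umi_rand = 0
    for rec in assigned:
        # --- cell stage replaced ---
        cands, _ = (
            index.query_cells(rec.key, None)
            if rec.key_source == "gene"
            else index.query_cells(None, rec.key)
        )
        w = _random_window(rng, index.barcode_length)
        res = find_match(w, cands, rec.cell_ed)
        if res.matched is not None:
            # a falsely matched cell must still produce a UMI hit
            umis = index.query_umis(rec.key, res.matched)
            if umis:
                uw = _random_window(rng, index.umi_length)
                # the read's true UMI bases are unrelated to the false cell's
                # UMI set, so the window is random for this stage as well
                ures = find_match(uw, umis, rec.umi_ed)
                if ures.matched is not None:
                    cell_rand += 1
        # --- UMI stage replaced ---
        umis = index.query_umis(rec.key, rec.cell)
        uw = _random_window(rng, index.umi_length)
        ures = find_match(uw, umis, rec.umi_ed)
        if ures.matched is not None:
            umi_rand += 1
    n = len(assigned)
    return {
        "cell_accuracy": 100.0 * (1.0 - cell_rand / n),
        "umi_accuracy": 100.0 * (1.0 - umi_rand / n),
        "assigned": n,
        "cell_assigned_random": cell_rand,
        "umi_assigned_random": umi_rand,
    }


def estimate_accuracy_unrelated(
    items: Sequence[tuple[str, ReadScan, Union[str, Sequence[str], None], Optional[WindowId]]],
    unrelated_index: GuideIndex,
    cell_policy: EdPolicy,
    umi_policy: EdPolicy,
    matched_run: Optional[AssignmentRun] = None,
) -> dict:
    """Cross-assignment against the guide index of an unrelated experiment.

    Unlike the random-replacement estimator, the search proceeds up to the
    full policy-allowed edit distance.  Reports the number of cross-assigned
    reads and the mean realized edit distances; with a matched-guide run
    supplied, also the cross-assignment ratio and the mean-ed comparison
    (cross-assigned reads match far less often and only at high edit
    distance).
    """
    run = assign_reads(items, unrelated_index, cell_policy, umi_policy)
    cell_eds = [r.cell_ed for r in run.records if r.cell_ed is not None]
    umi_eds = [r.umi_ed for r in run.records if r.assigned]
    out = {
        "n_assigned": run.n_assigned,
        "n_cell_assigned": run.n_cell_assigned,
        "mean_cell_ed": (sum(cell_eds) / len(cell_eds)) if cell_eds else None,
        "mean_umi_ed": (sum(umi_eds) / len(umi_eds)) if umi_eds else None,
    }
    if matched_run is not None and matched_run.n_assigned:
        out["assignment_ratio"] = run.n_assigned / matched_run.n_assigned
        m_eds = [r.cell_ed for r in matched_run.records if r.cell_ed is not None]
        out["matched_mean_cell_ed"] = sum(m_eds) / len(m_eds) if m_eds else None
    return out


def ed_histograms(records: Iterable[AssignmentRecord]) -> dict[str, Counter]:
    """Edit-distance distributions of the cell and UMI assignments."""
    cell: Counter = Counter()
    umi: Counter = Counter()
    for r in records:
        if r.cell_ed is not None:
            cell[r.cell_ed] += 1
        if r.umi_ed is not None:
            umi[r.umi_ed] += 1
    return {"cell": cell, "umi": umi}
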