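"""Novel transcript-isoform discovery.

Molecules whose junction chain matches no annotated transcript are
collapsed (after snapping junction coordinates within +/-2 bases onto
annotated splice sites) into candidate novel isoforms supported by their
UMI count; candidates supported by fewer than five molecules are dropped,
and molecules differing only in 5'/3' ends or SNVs fold into the same
candidate because the grouping key is the junction chain alone.

Candidates are classified against the annotation — (i) combination of
known splice junctions, (ii) combination of known splice sites joined into
novel junctions, (iii) at least one unannotated donor/acceptor site — and
validated against three orthogonal tracks: short-read-confirmed junctions,
CAGE transcription start sites (5' end within 50 nt) and polyadenylation
sites (3' end within 50 nt).  A candidate passes only when all three
checks pass.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .isoforms import ExonStructure, Junction, TranscriptModel

__all__ = [
    "NovelCandidate",
    "GeneAnnotationSets",
    "collapse",
    "classify",
    "validate",
    "export_gtf",
    "read_bed_intervals",
    "read_junction_bed",
]


@dataclass
class GeneAnnotationSets:
    """Per-gene annotated junctions and donor/acceptor site sets."""

    junctions: set[Junction] = field(default_factory=set)
    donors: set[int] = field(default_factory=set)
    acceptors: set[int] = field(default_factory=set)
    chains: set[tuple[Junction, ...]] = field(default_factory=set)

    @classmethod
    def from_models(cls, models: Sequence[TranscriptModel]) -> dict[str, "GeneAnnotationSets"]:
        out: dict[str, GeneAnnotationSets] = defaultdict(cls)
        for m in models:
            g = out[m.gene_id]
            g.chains.add(m.structure.junctions)
            for d, a in m.structure.junctions:
                g.junctions.add((d, a))
                g.donors.add(d)
                g.acceptors.add(a)
        return dict(out)


@dataclass
class NovelCandidate:
    gene_id: str
    structure: ExonStructure
    supporting_umis: set[str]
    classification: Optional[str] = None  # known_junctions | known_sites | novel_sites
    validation: dict[str, Optional[bool]] = field(default_factory=dict)

    @property
    def n_umis(self) -> int:
        return len(self.supporting_umis)

    @property
    def passes(self) -> bool:
        return all(self.validation.get(k) is True for k in ("junctions_ok", "tss_ok", "polya_ok"))


def _snap(value: int, sites: set[int], margin: int) -> int:
    """Snap a coordinate onto the closest annotated site within +/-margin."""
    best = value
    best_d = margin + 1
    for s in sites:
        d = abs(s - value)
        if d <= margin and d < best_d:
            best, best_d = s, d
    return best


def collapse(
    molecules: Iterable[tuple[str, str, ExonStructure]],
    annotation: dict[str, GeneAnnotationSets],
    min_umis: int = 5,
    snap_margin: int = 2,
) -> list[NovelCandidate]:
    """Group unmatched molecules into candidate novel isoforms.

    ``molecules`` yields (molecule_id, gene_id, structure) for molecules
    with no annotated isoform match.  Junction coordinates within
    ``snap_margin`` of an annotated donor/acceptor snap onto it before
    grouping, so +/-2 mapping jitter cannot split a candidate.  Groups are
    keyed by the exact snapped junction chain (5'/3' ends and SNVs are
    ignored); snapped chains identical to an annotated transcript's chain
    are discarded (not novel), as are groups supported by fewer than
    ``min_umis`` molecules.  The representative structure is the modal
    (most common) snapped structure of the group's members.
    """
    groups: dict[tuple[str, str, str, tuple[Junction, ...]], list[tuple[str, ExonStructure]]] = defaultdict(list)
    for mol_id, gene_id, struct in molecules:
        ann = annotation.get(gene_id, GeneAnnotationSets())
        snapped_j = tuple(
            (_snap(d, ann.donors, snap_margin), _snap(a, ann.acceptors, snap_margin))
            for d, a in struct.junctions
        )
        if snapped_j in ann.chains:
            continue  # jitter away from an annotated isoform: not novel
        snapped = ExonStructure(struct.chrom, struct.strand, snapped_j, struct.span)
        groups[(gene_id, struct.chrom, struct.strand, snapped_j)].append((mol_id, snapped))
    out: list[NovelCandidate] = []
    for (gene_id, _chrom, _strand, _junc), members in groups.items():
        if len(members) < min_umis:
            continue
        modal = Counter(m[1] for m in members).most_common(1)[0][0]
        out.append(
            NovelCandidate(
                gene_id=gene_id,
                structure=modal,
                supporting_umis={m[0] for m in members},
            )
        )
    out.sort(key=lambda c: (c.structure.chrom, c.structure.span, c.gene_id))
    return out


def classify(candidate: NovelCandidate, annotation: dict[str, GeneAnnotationSets]) -> str:
    """Classify a candidate's junction chain against the annotation.

    known_junctions: every junction annotated, but the chain itself is new
    (e.g. exon skipping).  known_sites: every donor and acceptor site
    annotated but at least one pairing is novel.  novel_sites: at least one
    donor or acceptor is unannotated.
    """
    ann = annotation.get(candidate.gene_id, GeneAnnotationSets())
    juncs = candidate.structure.junctions
    if all(j in ann.junctions for j in juncs):
        cls = "known_junctions"
    elif all(d in ann.donors and a in ann.acceptors for d, a in juncs):
        cls = "known_sites"
    else:
        cls = "novel_sites"
    candidate.classification = cls
    return cls


def _near_interval(tree: IntervalTree, pos: int, tol: int) -> bool:
    """True when pos is within tol of (or inside) any interval."""
    return bool(tree.overlap(pos - tol, pos + tol + 1))


def validate(
    candidate: NovelCandidate,
    short_read_junctions: Optional[set[tuple[str, int, int]]],
    cage_peaks: Optional[dict[str, IntervalTree]],
    polya_sites: Optional[dict[str, IntervalTree]],
    annotation: dict[str, GeneAnnotationSets],
    tol: int = 50,
) -> dict[str, Optional[bool]]:
    """Apply the three validation filters (pure conjunction, any order).

    junctions_ok: every junction annotated for the gene OR present in the
    short-read junction set.  tss_ok / polya_ok: the strand-aware 5'/3'
    genomic end lies within ``tol`` nt (inclusive) of a CAGE peak /
    polyadenylation site interval.  A missing track leaves its flag
    undefined (None) and the candidate held, never passed.
    """
    ann = annotation.get(candidate.gene_id, GeneAnnotationSets())
    s = candidate.structure
    flags: dict[str, Optional[bool]] = {}
    if short_read_junctions is None:
        flags["junctions_ok"] = None
    else:
        flags["junctions_ok"] = all(
            j in ann.junctions or (s.chrom, j[0], j[1]) in short_read_junctions
            for j in s.junctions
        )
    if cage_peaks is None:
        flags["tss_ok"] = None
    else:
        tree = cage_peaks.get(s.chrom, IntervalTree())
        flags["tss_ok"] = _near_interval(tree, s.five_prime(), tol)
    if polya_sites is None:
        flags["polya_ok"] = None
    else:
        tree = polya_sites.get(s.chrom, IntervalTree())
        flags["polya_ok"] = _near_interval(tree, s.three_prime(), tol)
    candidate.validation = flags
    return flags


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_bed_intervals(path: str) -> dict[str, IntervalTree]:
    """BED intervals (chrom, start, end, ...) into per-chromosome trees."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    for chrom, start, end in df.itertuples(index=False):
        if end > start:
            trees[str(chrom)].addi(int(start), int(end))
    return dict(trees)


def read_junction_bed(path: str) -> set[tuple[str, int, int]]:
    """Splice junctions as BED-like rows chrom / donor_end / acceptor_start."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    return {(str(c), int(d), int(a)) for c, d, a in df.itertuples(index=False)}


def export_gtf(candidates: Sequence[NovelCandidate], path: str, source: str = "scnaumi") -> None:
    """Write candidates as GTF transcripts (+ exons), 1-based coordinates,
    with classification and UMI support in the attribute field."""
    with open(path, "w") as fh:
        fh.write("##gff-version 2\n")
        for i, cand in enumerate(candidates):
            s = cand.structure
            tx_id = f"{cand.gene_id}.novel{i + 1}"
            attrs = (
                f'gene_id "{cand.gene_id}"; transcript_id "{tx_id}"; '
                f'novel_class "{cand.classification}"; n_umis "{cand.n_umis}";'
            )
            fh.write(
                "\t".join(
                    [
                        s.chrom,
                        source,
                        "transcript",
                        str(s.span[0] + 1),
                        str(s.span[1]),
                        ".",
                        s.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for start, end in s.exons():
                fh.write(
                    "\t".join(
                        [s.chrom, source, "exon", str(start + 1), str(end), ".", s.strand, ".", attrs]
                    )
                    + "\n"
                )
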