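"""Transcript-isoform assignment of consensus molecules and cell x feature
count matrices.

A molecule is assigned to an annotated transcript when the two share the
same exon makeup: identical splice-junction counts with every junction
coordinate within a +/-2-base margin (absorbing indels and imprecise
spliced mapping at exon boundaries).  Terminal exon ends are deliberately
not compared — transcription start/end variation is handled by the novel
isoform filters, not here.  Molecules matching no transcript are
'undefined' (candidate novel isoforms); molecules matching several
junction-identical transcripts are 'ambiguous' and counted at gene level
only.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExonStructure",
    "TranscriptModel",
    "CellMatrix",
    "load_annotation",
    "match_isoform",
    "MoleculeCall",
    "build_matrices",
]

Junction = tuple[int, int]  # (donor exon end, acceptor exon start), 0-based half-open


@dataclass(frozen=True)
class ExonStructure:
    """Ordered splice-junction chain of an aligned molecule or transcript."""

    chrom: str
    strand: str
    junctions: tuple[Junction, ...]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        prev = None
        for d, a in self.junctions:
            if d >= a:
                raise ValueError(f"junction donor {d} must precede acceptor {a}")
            if prev is not None and d < prev:
                raise ValueError("junctions must be sorted and non-overlapping")
            prev = a

    @classmethod
    def from_exons(
        cls, chrom: str, strand: str, exons: Sequence[tuple[int, int]]
    ) -> "ExonStructure":
        """Build from 0-based half-open exon intervals (genomic order)."""
        exons = sorted(exons)
        junctions = tuple(
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        )
        return cls(chrom, strand, junctions, (exons[0][0], exons[-1][1]))

    @property
    def mono_exonic(self) -> bool:
        return not self.junctions

    def exons(self) -> list[tuple[int, int]]:
        """Recover exon intervals from span + junctions."""
        starts = [self.span[0]] + [a for _, a in self.junctions]
        ends = [d for d, _ in self.junctions] + [self.span[1]]
        return list(zip(starts, ends))

    def five_prime(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1]

    def three_prime(self) -> int:
        return self.span[1] if self.strand == "+" else self.span[0]


@dataclass(frozen=True)
class TranscriptModel:
    gene_id: str
    transcript_id: str
    structure: ExonStructure

    @property
    def tss(self) -> int:
        return self.structure.five_prime()

    @property
    def tes(self) -> int:
        return self.structure.three_prime()


def load_annotation(gtf_path: str) -> list[TranscriptModel]:
    """Parse a GTF into transcript models (one per transcript).

    Exon features are grouped by transcript_id; junction coordinates are
    derived from adjacent exons.  GTF 1-based closed coordinates are
    converted to 0-based half-open.  Malformed lines are skipped with a
    warning count (gffutils is lenient about attribute dialects).
    """
    import gffutils

    db = gffutils.create_db(
        gtf_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, list] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    for exon in db.features_of_type("exon"):
        tx = exon.attributes.get("transcript_id", [None])[0]
        gene = exon.attributes.get("gene_id", [None])[0]
        if tx is None or gene is None:
            continue
        by_tx[tx].append((exon.start - 1, exon.end))  # GTF is 1-based closed
        meta[tx] = (gene, exon.seqid, exon.strand)
    models = []
    for tx, exons in by_tx.items():
        gene, chrom, strand = meta[tx]
        models.append(
            TranscriptModel(
                gene_id=gene,
                transcript_id=tx,
                structure=ExonStructure.from_exons(chrom, strand, exons),
            )
        )
    models.sort(key=lambda m: (m.structure.chrom, m.structure.span, m.transcript_id))
    return models


def _junctions_match(
    a: tuple[Junction, ...], b: tuple[Junction, ...], margin: int
) -> bool:
    if len(a) != len(b):
        return False
    return all(
        abs(x[0] - y[0]) <= margin and abs(x[1] - y[1]) <= margin
        for x, y in zip(a, b)
    )


def match_isoform(
    mol: ExonStructure,
    models: Sequence[TranscriptModel],
    margin: int = 2,
    mono_end_tol: int = 100,
    require_strand: bool = True,
) -> tuple[str, Optional[str]]:
    """Match a molecule's exon structure against its gene's transcripts.

    Multi-exon molecules require an identical junction chain within
    ``margin`` bases at every donor/acceptor.  Mono-exonic molecules match
    mono-exonic models with overlapping spans and both ends within
    ``mono_end_tol``.  Returns ``(status, transcript_id)`` with status in
    {'unique', 'ambiguous', 'undefined'}.
    """
    hits = []
    for model in models:
        s = model.structure
        if s.chrom != mol.chrom:
            continue
        if require_strand and s.strand != mol.strand:
            continue
        if mol.mono_exonic:
            if not s.mono_exonic:
                continue
            if mol.span[1] <= s.span[0] or s.span[1] <= mol.span[0]:
                continue
            if (
                abs(mol.span[0] - s.span[0]) <= mono_end_tol
                and abs(mol.span[1] - s.span[1]) <= mono_end_tol
            ):
                hits.append(model.transcript_id)
        elif _junctions_match(mol.junctions, s.junctions, margin):
            hits.append(model.transcript_id)
    if not hits:
        return "undefined", None
    if len(hits) > 1:
        return "ambiguous", None
    return "unique", hits[0]


@dataclass
class MoleculeCall:
    """Isoform call for one consensus molecule."""

    cell: str
    umi: str
    gene: str
    structure: Optional[ExonStructure] = None
    status: str = "undefined"  # unique | ambiguous | undefined
    transcript: Optional[str] = None
    n_reads: int = 1


@dataclass
class CellMatrix:
    """Integer molecule counts, features x cells."""

    features: list[str]
    cells: list[str]
    counts: scipy.sparse.csr_matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.features, columns=self.cells
        )

    def write(self, outdir: str, feature_label: str = "features") -> None:
        """Cell Ranger-like layout: matrix.mtx + features.tsv + barcodes.tsv."""
        import os

        os.makedirs(outdir, exist_ok=True)
        scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), self.counts)
        with open(os.path.join(outdir, f"{feature_label}.tsv"), "w") as fh:
            fh.write("\n".join(self.features) + ("\n" if self.features else ""))
        with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(self.cells) + ("\n" if self.cells else ""))


def build_matrices(
    calls: Iterable[MoleculeCall],
) -> tuple[CellMatrix, CellMatrix]:
    """Gene-level and isoform-level cell x feature molecule-count matrices.

    Every molecule counts once under its gene; only uniquely matched
    molecules count at isoform level, so each cell's isoform total is at
    most its gene total.
    """
    calls = list(calls)
    cells = sorted({c.cell for c in calls})
    genes = sorted({c.gene for c in calls})
    txs = sorted({c.transcript for c in calls if c.status == "unique"})
    cell_ix = {c: i for i, c in enumerate(cells)}
    gene_ix = {g: i for i, g in enumerate(genes)}
    tx_ix = {t: i for i, t in enumerate(txs)}
    gmat = scipy.sparse.dok_matrix((len(genes), len(cells)), dtype=np.int64)
    tmat = scipy.sparse.dok_matrix((len(txs), len(cells)), dtype=np.int64)
    for c in calls:
        gmat[gene_ix[c.gene], cell_ix[c.cell]] += 1
        if c.status == "unique":
            tmat[tx_ix[c.transcript], cell_ix[c.cell]] += 1
    return (
        CellMatrix(genes, cells, gmat.tocsr()),
        CellMatrix(txs, cells, tmat.tocsr()),
    )
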