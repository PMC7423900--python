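"""Guide index: per-gene and per-genomic-window barcode/UMI sets parsed
from a high-accuracy short-read (Illumina) single-cell dataset.

The guide index is what makes noisy long-read barcode matching accurate:
instead of clustering error-prone barcode reads de novo, each long read is
only compared with the cell barcodes the short-read data observed for the
same gene (or, for reads outside annotated genes, the same 500-nt genomic
window), and each UMI only with the UMIs the short-read data observed for
that (gene, cell) — a search set whose size is the copy number of one gene
in one cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .kernel import EncodedSeq, EncodingError, encode

__all__ = ["GuideIndex", "GuideRecord", "build_index", "load", "read_guide_tsv", "read_guide_bam"]

WindowId = tuple[str, int]
Key = Union[str, WindowId]

_MAGIC = "scnaumi-guide-index"
_VERSION = 1


class GuideIndexError(ValueError):
    """Malformed or incompatible serialized guide index."""


@dataclass
class GuideRecord:
    """One short-read molecule observation: (cell, umi, gene-or-None, locus)."""

    cell: str
    umi: str
    gene: Optional[str]
    chrom: str
    pos: int  # 0-based alignment start


@dataclass
class GuideIndex:
    """Nested maps gene/window -> cell barcodes and (key, cell) -> UMI sets."""

    window_size: int = 500
    umi_length: int = 10
    barcode_length: int = 16
    gene_to_cells: dict[str, set[EncodedSeq]] = field(default_factory=dict)
    window_to_cells: dict[WindowId, set[EncodedSeq]] = field(default_factory=dict)
    key_to_umis: dict[tuple[Key, EncodedSeq], set[EncodedSeq]] = field(default_factory=dict)
    n_records: int = 0
    n_skipped: int = 0

    # -- queries ----------------------------------------------------------

    def query_cells(
        self, gene: Optional[str] = None, window: Optional[WindowId] = None
    ) -> tuple[set[EncodedSeq], str]:
        """Cell-barcode candidate set for a locus.

        The gene-level set is used when the gene is known to the guide
        data; otherwise the read falls back to the 500-nt genomic window of
        its alignment.  Returns ``(cells, source)`` with source in
        {'gene', 'window'}.
        """
        if gene is None and window is None:
            raise ValueError("provide at least one of gene/window")
        if gene is not None and gene in self.gene_to_cells:
            return self.gene_to_cells[gene], "gene"
        if window is not None and window in self.window_to_cells:
            return self.window_to_cells[window], "window"
        return set(), "window"

    def query_umis(self, key: Key, cell: EncodedSeq) -> set[EncodedSeq]:
        """UMIs observed in the guide data for one (gene-or-window, cell)."""
        return self.key_to_umis.get((self._norm_key(key), cell), set())

    def window_of(self, chrom: str, pos: int) -> WindowId:
        return (chrom, pos // self.window_size)

    @staticmethod
    def _norm_key(key: Key) -> Key:
        return tuple(key) if isinstance(key, (list, tuple)) else key

    # -- construction ------------------------------------------------------

    def _add(self, rec: GuideRecord, boundary_margin: int) -> None:
        try:
            cell = encode(rec.cell)
            umi = encode(rec.umi)
        except EncodingError:
            self.n_skipped += 1
            return
        if cell.length != self.barcode_length or umi.length != self.umi_length:
            self.n_skipped += 1
            return
        self.n_records += 1
        keys: list[Key] = []
        if rec.gene:
            self.gene_to_cells.setdefault(rec.gene, set()).add(cell)
            keys.append(rec.gene)
        win = self.window_of(rec.chrom, rec.pos)
        wins = [win]
        # reads near a window boundary also index the adjacent window, so a
        # long read aligning just across the boundary still finds its cell
        off = rec.pos % self.window_size
        if off < boundary_margin and win[1] > 0:
            wins.append((rec.chrom, win[1] - 1))
        elif off >= self.window_size - boundary_margin:
            wins.append((rec.chrom, win[1] + 1))
        for w in wins:
            self.window_to_cells.setdefault(w, set()).add(cell)
            keys.append(w)
        for key in keys:
            self.key_to_umis.setdefault((key, cell), set()).add(umi)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Serialize to a JSON file with a magic/version header."""
        doc = {
            "magic": _MAGIC,
            "version": _VERSION,
            "window_size": self.window_size,
            "umi_length": self.umi_length,
            "barcode_length": self.barcode_length,
            "n_records": self.n_records,
            "n_skipped": self.n_skipped,
            "gene_to_cells": {g: sorted(c.decode() for c in s) for g, s in self.gene_to_cells.items()},
            "window_to_cells": {
                f"{c}:{w}": sorted(x.decode() for x in s)
                for (c, w), s in self.window_to_cells.items()
            },
            "key_to_umis": {
                self._key_str(key) + "\t" + cell.decode(): sorted(u.decode() for u in s)
                for (key, cell), s in self.key_to_umis.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @staticmethod
    def _key_str(key: Key) -> str:
        return f"W|{key[0]}:{key[1]}" if isinstance(key, tuple) else f"G|{key}"

    @staticmethod
    def _key_parse(s: str) -> Key:
        kind, _, body = s.partition("|")
        if kind == "G":
            return body
        chrom, _, w = body.rpartition(":")
        return (chrom, int(w))


def load(path: str) -> GuideIndex:
    """Load a serialized guide index; refuses corrupted or wrong-version files."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise GuideIndexError(f"cannot read guide index {path!r}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("magic") != _MAGIC:
        raise GuideIndexError(f"{path!r} is not a scnaumi guide index")
    if doc.get("version") != _VERSION:
        raise GuideIndexError(
            f"guide index version {doc.get('version')} unsupported (expected {_VERSION})"
        )
    idx = GuideIndex(
        window_size=doc["window_size"],
        umi_length=doc["umi_length"],
        barcode_length=doc["barcode_length"],
        n_records=doc["n_records"],
        n_skipped=doc["n_skipped"],
    )
    idx.gene_to_cells = {g: {encode(c) for c in s} for g, s in doc["gene_to_cells"].items()}
    for ks, s in doc["window_to_cells"].items():
        chrom, _, w = ks.rpartition(":")
        idx.window_to_cells[(chrom, int(w))] = {encode(c) for c in s}
    for ks, s in doc["key_to_umis"].items():
        key_s, _, cell_s = ks.partition("\t")
        idx.key_to_umis[(GuideIndex._key_parse(key_s), encode(cell_s))] = {encode(u) for u in s}
    return idx


def build_index(
    guide_records: Iterable[GuideRecord],
    window_size: int = 500,
    umi_length: int = 10,
    barcode_length: int = 16,
    boundary_margin: int = 100,
) -> GuideIndex:
    """Build a :class:`GuideIndex` from short-read molecule records.

    Records with a gene are indexed under both the gene and the genomic
    window of their alignment start; records without a gene get window keys
    only.  Malformed records (non-ACGT or wrong-length barcodes/UMIs) are
    skipped and counted in ``n_skipped``.  Duplicate records are idempotent.
    """
    idx = GuideIndex(
        window_size=window_size, umi_length=umi_length, barcode_length=barcode_length
    )
    for rec in guide_records:
        idx._add(rec, boundary_margin)
    return idx


# ---------------------------------------------------------------------------
# input dialects
# ---------------------------------------------------------------------------


def read_guide_tsv(path: str) -> Iterable[GuideRecord]:
    """Headered TSV dialect: columns ``cell  umi  gene  chrom  pos``.

    ``gene`` may be empty (intergenic molecule); ``pos`` is the 0-based
    alignment start.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for name in ("cell", "umi", "chrom", "pos"):
            if name not in cols:
                raise GuideIndexError(f"guide TSV missing column {name!r}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            gene = f[cols["gene"]] if "gene" in cols else ""
            yield GuideRecord(
                cell=f[cols["cell"]],
                umi=f[cols["umi"]],
                gene=gene or None,
                chrom=f[cols["chrom"]],
                pos=int(f[cols["pos"]]),
            )


def read_guide_bam(
    path: str,
    cell_tag: str = "CB",
    umi_tag: str = "UB",
    gene_tags: Sequence[str] = ("GX", "GN"),
) -> Iterable[GuideRecord]:
    """Cell Ranger-style tagged BAM/SAM: cell in CB, UMI in UB, gene in GX/GN.

    The trailing GEM-group suffix (``-1``) of the cell tag is stripped.
    Multi-gene tags (``;``-separated) yield one record per gene, so every
    listed gene's search set contains the cell.
    """
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.has_tag(cell_tag) or not rec.has_tag(umi_tag):
                continue
            cell = str(rec.get_tag(cell_tag)).split("-")[0]
            umi = str(rec.get_tag(umi_tag))
            genes: list[Optional[str]] = [None]
            for tag in gene_tags:
                if rec.has_tag(tag):
                    genes = [g for g in str(rec.get_tag(tag)).split(";") if g]
                    break
            for gene in genes:
                yield GuideRecord(
                    cell=cell,
                    umi=umi,
                    gene=gene,
                    chrom=rec.reference_name,
                    pos=rec.reference_start,
                )
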