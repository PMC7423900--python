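"""Ground-truth simulator for the whole pipeline.

Generates a toy genome with multi-exon transcript models, a cell universe
with distinct 16-nt barcodes, per-(cell, gene) molecules tagged with
unique UMIs, a short-read guide dataset covering a configurable fraction
of those molecules (the sequencing saturation), and noisy long reads with
the 10x read architecture

    adapter - cellBC - UMI - poly(T) - cDNA(revcomp) - TSO(revcomp)

subjected to independent per-base substitution/insertion/deletion errors
(default 7% total, split 55/25/20 — the middle of the 5-10% error band of
current long-read chemistry).  Everything is keyed by a single integer
seed and fully reproducible; every downstream stage can be scored exactly
against the returned truth table.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

from .guide import GuideRecord
from .isoforms import ExonStructure, TranscriptModel
from .scan import ADAPTER, TSO, revcomp

__all__ = [
    "Molecule",
    "SimRead",
    "TruthTable",
    "simulate_universe",
    "emit_guide",
    "emit_unrelated_guide",
    "emit_reads",
    "mutate",
    "write_fasta",
    "write_gtf",
    "write_guide_tsv",
    "write_fastq",
]

_BASES = "ACGT"
_BASES_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default error profile: 7% of bases altered, 55% substitutions,
#: 25% insertions, 20% deletions
DEFAULT_SUB_RATE = 0.07 * 0.55
DEFAULT_INS_RATE = 0.07 * 0.25
DEFAULT_DEL_RATE = 0.07 * 0.20


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES_ARR[rng.integers(0, 4, n)].tobytes().decode()


@dataclass
class Molecule:
    mol_id: str
    cell: str
    gene: str
    transcript: str
    umi: str
    cdna: str
    chrom: str
    pos: int  # guide-alignment anchor (3'-end-biased), 0-based


@dataclass
class SimRead:
    read_id: str
    mol_id: str
    seq: str
    orientation: str  # forward | reverse
    cell: str
    umi: str
    gene: str
    chrom: str
    pos: int
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0
    is_chimera: bool = False


@dataclass
class TruthTable:
    seed: int
    cells: list[str]
    genome: dict[str, str]
    models: list[TranscriptModel]
    molecules: list[Molecule]
    junction_bed: list[tuple[str, int, int]] = field(default_factory=list)
    cage_bed: list[tuple[str, int, int]] = field(default_factory=list)
    polya_bed: list[tuple[str, int, int]] = field(default_factory=list)
    umi_length: int = 10
    guide_saturation: Optional[float] = None

    def molecule_by_id(self) -> dict[str, Molecule]:
        return {m.mol_id: m for m in self.molecules}

    def transcript_of(self, tx_id: str) -> TranscriptModel:
        return next(m for m in self.models if m.transcript_id == tx_id)


def _distinct_barcodes(
    rng: np.random.Generator, n: int, length: int, min_dist: int = 4
) -> list[str]:
    """Random barcodes kept pairwise at Levenshtein distance >= min_dist,
    emulating the separation of a real barcode whitelist."""
    import edlib

    out: list[str] = []
    while len(out) < n:
        cand = _random_dna(rng, length)
        if all(
            edlib.align(cand, b, mode="NW", k=min_dist - 1)["editDistance"] < 0
            for b in out
        ):
            out.append(cand)
    return out


def simulate_universe(
    n_cells: int = 50,
    n_genes: int = 20,
    isoforms_per_gene: int = 2,
    umis_per_gene_per_cell: Union[float, Callable] = 0.5,
    seed: int = 0,
    umi_length: int = 10,
    exon_range: tuple[int, int] = (80, 400),
    n_exons_range: tuple[int, int] = (2, 10),
    intron_range: tuple[int, int] = (100, 800),
    intergenic_gap: int = 1500,
    n_decoy_tracks: int = 5,
) -> TruthTable:
    """Build the full synthetic universe: genome, transcript models, cells,
    molecules and validation tracks.

    Genes are laid out on one toy chromosome with 2-10 exons of 80-400 nt;
    each gene gets ``isoforms_per_gene`` isoforms (the full exon chain plus
    internal-exon-skipping variants).  Per cell and gene, the molecule
    count is Poisson with the given mean (or a custom ``callable(rng)``).
    CAGE/polyA/junction tracks are consistent with the models, plus a few
    decoy intervals away from any gene.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    genome_parts: list[str] = []
    cursor = 0
    models: list[TranscriptModel] = []
    junctions: list[tuple[str, int, int]] = []
    cage: list[tuple[str, int, int]] = []
    polya: list[tuple[str, int, int]] = []
    for g in range(n_genes):
        cursor += int(rng.integers(intergenic_gap // 2, intergenic_gap))
        n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        exons: list[tuple[int, int]] = []
        pos = cursor
        for e in range(n_ex):
            length = int(rng.integers(exon_range[0], exon_range[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if e < n_ex - 1:
                pos += int(rng.integers(intron_range[0], intron_range[1] + 1))
        cursor = pos
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{g:04d}"
        full = ExonStructure.from_exons(chrom, strand, exons)
        models.append(TranscriptModel(gene_id, f"{gene_id}.t1", full))
        # skipping variants of distinct internal exons
        skippable = list(range(1, n_ex - 1))
        made = 1
        for k in skippable:
            if made >= isoforms_per_gene:
                break
            variant = exons[:k] + exons[k + 1 :]
            if len(variant) >= 2:
                models.append(
                    TranscriptModel(
                        gene_id,
                        f"{gene_id}.t{made + 1}",
                        ExonStructure.from_exons(chrom, strand, variant),
                    )
                )
                made += 1
        for m in models[-made:]:
            for d, a in m.structure.junctions:
                junctions.append((chrom, d, a))
            cage.append((chrom, max(0, m.tss - 20), m.tss + 20))
            polya.append((chrom, max(0, m.tes - 20), m.tes + 20))
    genome_len = cursor + intergenic_gap
    genome = {chrom: _random_dna(rng, genome_len)}
    # decoy intervals in the trailing intergenic region
    for _ in range(n_decoy_tracks):
        p = int(rng.integers(cursor + 100, genome_len - 50))
        cage.append((chrom, p, p + 20))
        polya.append((chrom, p, p + 20))
        junctions.append((chrom, p, p + int(rng.integers(60, 200))))

    cells = _distinct_barcodes(rng, n_cells, 16)

    def n_umis(r: np.random.Generator) -> int:
        if callable(umis_per_gene_per_cell):
            return int(umis_per_gene_per_cell(r))
        return int(r.poisson(umis_per_gene_per_cell))

    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    molecules: list[Molecule] = []
    seen_umis: set[tuple[str, str, str]] = set()
    for cell in cells:
        for gene_id, gene_models in by_gene.items():
            for _ in range(n_umis(rng)):
                model = gene_models[int(rng.integers(0, len(gene_models)))]
                umi = _random_dna(rng, umi_length)
                while (cell, gene_id, umi) in seen_umis:
                    umi = _random_dna(rng, umi_length)
                seen_umis.add((cell, gene_id, umi))
                cdna = spliced_sequence(genome, model.structure)
                molecules.append(
                    Molecule(
                        mol_id=f"M{len(molecules):06d}",
                        cell=cell,
                        gene=gene_id,
                        transcript=model.transcript_id,
                        umi=umi,
                        cdna=cdna,
                        chrom=chrom,
                        pos=model.tes if model.structure.strand == "+" else model.tss,
                    )
                )
    return TruthTable(
        seed=seed,
        cells=cells,
        genome=genome,
        models=models,
        molecules=molecules,
        junction_bed=junctions,
        cage_bed=cage,
        polya_bed=polya,
        umi_length=umi_length,
    )


def spliced_sequence(genome: dict[str, str], structure: ExonStructure) -> str:
    """mRNA-sense spliced sequence of an exon structure."""
    seq = "".join(genome[structure.chrom][s:e] for s, e in structure.exons())
    return seq if structure.strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# guide emission
# ---------------------------------------------------------------------------


def emit_guide(
    truth: TruthTable, saturation: float = 0.9, seed: int = 1
) -> list[GuideRecord]:
    """Short-read guide records: each molecule is captured independently
    with probability ``saturation`` (the sequencing-saturation ceiling on
    guided UMI assignment)."""
    if not 0.0 <= saturation <= 1.0:
        raise ValueError("saturation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth.guide_saturation = saturation
    return [
        GuideRecord(cell=m.cell, umi=m.umi, gene=m.gene, chrom=m.chrom, pos=m.pos)
        for m in truth.molecules
        if rng.random() < saturation
    ]


def emit_unrelated_guide(truth: TruthTable, seed: int = 2) -> list[GuideRecord]:
    """Guide records emulating an independent experiment: the same genes
    and molecule-count profile, but fresh cells and fresh UMIs, disjoint
    from the truth barcodes."""
    rng = np.random.default_rng(seed)
    taken = set(truth.cells)
    cells = []
    while len(cells) < len(truth.cells):
        c = _random_dna(rng, 16)
        if c not in taken:
            taken.add(c)
            cells.append(c)
    remap = dict(zip(truth.cells, cells))
    return [
        GuideRecord(
            cell=remap[m.cell],
            umi=_random_dna(rng, truth.umi_length),
            gene=m.gene,
            chrom=m.chrom,
            pos=m.pos,
        )
        for m in truth.molecules
    ]


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------


def mutate(
    seq: str,
    n_sub: int = 0,
    n_ins: int = 0,
    n_del: int = 0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> str:
    """Apply exact edit counts at uniform positions.

    Substitutions and deletions hit distinct positions; insertions go
    before uniform positions (including the end).  The Levenshtein
    distance to the input is at most ``n_sub + n_ins + n_del``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_sub + n_del > len(seq):
        raise ValueError("more substitutions+deletions than bases")
    out = list(seq)
    positions = rng.permutation(len(seq))
    sub_pos = positions[:n_sub]
    del_pos = set(positions[n_sub : n_sub + n_del])
    for p in sub_pos:
        out[p] = _BASES[(_BASES.index(out[p]) + int(rng.integers(1, 4))) % 4]
    out = [b for i, b in enumerate(out) if i not in del_pos]
    for _ in range(n_ins):
        p = int(rng.integers(0, len(out) + 1))
        out.insert(p, _BASES[int(rng.integers(0, 4))])
    return "".join(out)


def _mutate_rates(
    seq: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> tuple[str, int, int, int]:
    """Independent per-base errors; returns (read, n_sub, n_ins, n_del)."""
    n = len(seq)
    r = rng.random(n)
    ins_mask = rng.random(n + 1) < ins_rate
    out: list[str] = []
    n_sub = n_ins = n_del = 0
    for i in range(n):
        if ins_mask[i]:
            out.append(_BASES[int(rng.integers(0, 4))])
            n_ins += 1
        if r[i] < del_rate:
            n_del += 1
            continue
        if r[i] < del_rate + sub_rate:
            out.append(_BASES[(_BASES.index(seq[i]) + int(rng.integers(1, 4))) % 4])
            n_sub += 1
        else:
            out.append(seq[i])
    if ins_mask[n]:
        out.append(_BASES[int(rng.integers(0, 4))])
        n_ins += 1
    return "".join(out), n_sub, n_ins, n_del


def _read_core(mol: Molecule, polyt_len: int) -> str:
    """Barcode-strand (canonical) sequence of one molecule, error-free."""
    return (
        ADAPTER + mol.cell + mol.umi + "T" * polyt_len + revcomp(mol.cdna) + revcomp(TSO)
    )


def emit_reads(
    truth: TruthTable,
    reads_per_umi: Union[float, Callable] = 3.0,
    sub_rate: float = DEFAULT_SUB_RATE,
    ins_rate: float = DEFAULT_INS_RATE,
    del_rate: float = DEFAULT_DEL_RATE,
    reverse_fraction: float = 0.5,
    chimera_rate: float = 0.0,
    seed: int = 3,
    polyt_range: tuple[int, int] = (20, 60),
) -> list[SimRead]:
    """Noisy long reads for every molecule.

    ``reads_per_umi``: mean of a shifted Poisson (>=1 read per molecule)
    or a custom ``callable(rng)``.  A ``chimera_rate`` fraction of reads
    are concatemers of two molecules carrying an internal adapter next to
    an internal poly(T); half of all reads are emitted reverse-complemented
    by default.
    """
    for rate in (sub_rate, ins_rate, del_rate):
        if not 0.0 <= rate <= 0.2:
            raise ValueError("per-base error rates must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    reads: list[SimRead] = []
    mols = truth.molecules
    for mol in mols:
        if callable(reads_per_umi):
            n = int(reads_per_umi(rng))
        else:
            n = 1 + int(rng.poisson(max(0.0, reads_per_umi - 1.0)))
        for _ in range(n):
            polyt = int(rng.integers(polyt_range[0], polyt_range[1] + 1))
            chimera = rng.random() < chimera_rate
            if chimera:
                other = mols[int(rng.integers(0, len(mols)))]
                template = (
                    ADAPTER
                    + mol.cell
                    + mol.umi
                    + "T" * polyt
                    + revcomp(mol.cdna)
                    + ADAPTER
                    + other.cell
                    + other.umi
                    + "T" * int(rng.integers(*polyt_range))
                    + revcomp(other.cdna)
                    + revcomp(TSO)
                )
            else:
                template = _read_core(mol, polyt)
            seq, n_sub, n_ins, n_del = _mutate_rates(
                template, sub_rate, ins_rate, del_rate, rng
            )
            orientation = "reverse" if rng.random() < reverse_fraction else "forward"
            if orientation == "reverse":
                seq = revcomp(seq)
            reads.append(
                SimRead(
                    read_id=f"R{len(reads):07d}",
                    mol_id=mol.mol_id,
                    seq=seq,
                    orientation=orientation,
                    cell=mol.cell,
                    umi=mol.umi,
                    gene=mol.gene,
                    chrom=mol.chrom,
                    pos=mol.pos,
                    n_sub=n_sub,
                    n_ins=n_ins,
                    n_del=n_del,
                    is_chimera=chimera,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# file writers (all plain text)
# ---------------------------------------------------------------------------


def write_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(models: Sequence[TranscriptModel], path: str, source: str = "sim") -> None:
    with open(path, "w") as fh:
        for m in models:
            s = m.structure
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for start, end in s.exons():
                fh.write(
                    "\t".join(
                        [s.chrom, source, "exon", str(start + 1), str(end), ".", s.strand, ".", attrs]
                    )
                    + "\n"
                )


def write_guide_tsv(records: Iterable[GuideRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cell\tumi\tgene\tchrom\tpos\n")
        for r in records:
            fh.write(f"{r.cell}\t{r.umi}\t{r.gene or ''}\t{r.chrom}\t{r.pos}\n")


def write_fastq(reads: Iterable[SimRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
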