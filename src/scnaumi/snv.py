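"""Per-molecule nucleotide calls at user-specified genomic sites.

The unit of evidence is the consensus molecule (one UMI), never the raw
read: consensus calling first removes most sequencing errors, so a single
A->G call on a molecule reflects the RNA, not a read error.  Re-aligned
consensus molecules vote at each site; per-cell ref/alt/other counts and
per-group editing rates (alt / (ref+alt), 'other' excluded) plus pairwise
co-occurrence tables (e.g. for linked A-to-I editing sites on the same
transcript) are derived from the molecule-level calls.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "SiteSpec",
    "MoleculeAlignment",
    "SnvCallTable",
    "read_sites_tsv",
    "call_sites",
    "call_sites_sam",
    "editing_rates",
    "co_occurrence",
]


@dataclass(frozen=True)
class SiteSpec:
    """One genomic site to genotype (0-based position, ref != alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    label: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


def read_sites_tsv(path: str) -> list[SiteSpec]:
    """Site list TSV with header chrom/pos/ref/alt/label; positions in the
    file are 1-based and converted internally."""
    df = pd.read_csv(path, sep="\t")
    return [
        SiteSpec(str(r.chrom), int(r.pos) - 1, str(r.ref), str(r.alt), str(r.label))
        for r in df.itertuples(index=False)
    ]


@dataclass
class MoleculeAlignment:
    """Genome alignment of one consensus molecule, as (ref_pos -> base).

    ``bases`` holds the aligned query base per covered reference position;
    positions under deletions or outside the alignment are simply absent.
    """

    molecule_id: str
    cell: str
    chrom: str
    bases: dict[int, str]


@dataclass
class SnvCallTable:
    """Molecule-level base calls and per-cell count table."""

    calls: pd.DataFrame  # columns: molecule_id, cell, label, base, call
    sites: list[SiteSpec]

    def per_cell_counts(self) -> pd.DataFrame:
        """ref/alt/other counts per (cell, site label)."""
        if self.calls.empty:
            return pd.DataFrame(columns=["cell", "label", "ref", "alt", "other"])
        tab = (
            self.calls.groupby(["cell", "label", "call"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=["ref", "alt", "other"], fill_value=0)
            .reset_index()
        )
        return tab


def call_sites(
    molecules: Iterable[MoleculeAlignment],
    sites: Sequence[SiteSpec],
) -> SnvCallTable:
    """Record the aligned base of every molecule covering every site.

    Molecules with a deletion or clip at a site do not vote there.  Bases
    equal to neither ref nor alt are counted as 'other' (kept out of
    editing-rate denominators).
    """
    rows = []
    for mol in molecules:
        for site in sites:
            if site.chrom != mol.chrom:
                continue
            base = mol.bases.get(site.pos)
            if base is None:
                continue
            call = "ref" if base == site.ref else "alt" if base == site.alt else "other"
            rows.append(
                {
                    "molecule_id": mol.molecule_id,
                    "cell": mol.cell,
                    "label": site.label,
                    "base": base,
                    "call": call,
                }
            )
    calls = pd.DataFrame(rows, columns=["molecule_id", "cell", "label", "base", "call"])
    return SnvCallTable(calls=calls, sites=list(sites))


def call_sites_sam(
    sam_path: str,
    sites: Sequence[SiteSpec],
    cell_of: Optional[dict[str, str]] = None,
    min_reads_per_umi: int = 0,
) -> SnvCallTable:
    """Genotype sites from a SAM/BAM of re-aligned consensus molecules.

    Molecule metadata is read from query names of the form
    ``cell|umi|gene|n_reads`` (the consensus FASTA header convention);
    ``cell_of`` can override the cell lookup by query name.  Molecules with
    fewer than ``min_reads_per_umi`` supporting reads are excluded.
    """
    import pysam

    mols = []
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name
            parts = name.split("|")
            cell = cell_of.get(name) if cell_of else (parts[0] if parts else name)
            if len(parts) >= 4 and parts[3].isdigit() and int(parts[3]) < min_reads_per_umi:
                continue
            seq = rec.query_sequence
            bases = {
                ref_pos: seq[q_pos]
                for q_pos, ref_pos in rec.get_aligned_pairs(matches_only=True)
            }
            mols.append(
                MoleculeAlignment(
                    molecule_id=name,
                    cell=cell,
                    chrom=rec.reference_name,
                    bases=bases,
                )
            )
    return call_sites(mols, sites)


def editing_rates(
    table: SnvCallTable,
    grouping: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-group editing rate alt/(ref+alt) at each site.

    ``grouping`` maps cell -> group label (e.g. a cell-type cluster);
    ungrouped cells fall into 'NA'.  Rates are percentages; a group/site
    with zero informative molecules gets NaN.
    """
    if table.calls.empty:
        return pd.DataFrame(columns=["group", "label", "ref", "alt", "rate_pct"])
    calls = table.calls.copy()
    grouping = grouping or {}
    calls["group"] = calls["cell"].map(lambda c: grouping.get(c, "NA"))
    informative = calls[calls["call"].isin(["ref", "alt"])]
    tab = (
        informative.groupby(["group", "label", "call"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["ref", "alt"], fill_value=0)
        .reset_index()
    )
    denom = tab["ref"] + tab["alt"]
    tab["rate_pct"] = 100.0 * tab["alt"] / denom.where(denom > 0)
    return tab


def co_occurrence(table: SnvCallTable, label_a: str, label_b: str) -> dict:
    """2x2 contingency of editing states over molecules covering both sites.

    Only molecules with a ref or alt call at both sites contribute.  The
    returned dict holds the contingency table (rows: site A ref/alt,
    columns: site B ref/alt), the conditional editing rates of A given B's
    state, and a Fisher exact p-value (reported for convenience; no
    filtering is attached to it).
    """
    calls = table.calls
    informative = calls[calls["call"].isin(["ref", "alt"])]
    a = informative[informative["label"] == label_a].set_index("molecule_id")["call"]
    b = informative[informative["label"] == label_b].set_index("molecule_id")["call"]
    both = a.index.intersection(b.index)
    if both.empty:
        return {"n": 0, "table": None, "conditional_rates": None, "fisher_p": None}
    counts = pd.crosstab(a.loc[both], b.loc[both])
    counts = counts.reindex(index=["ref", "alt"], columns=["ref", "alt"], fill_value=0)
    from scipy.stats import fisher_exact

    _, p = fisher_exact(counts.values)
    cond = {}
    for state in ("ref", "alt"):
        col = counts[state]
        tot = col.sum()
        cond[f"rate_a_given_b_{state}"] = (
            100.0 * col["alt"] / tot if tot else float("nan")
        )
    return {"n": int(len(both)), "table": counts, "conditional_rates": cond, "fisher_p": p}
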