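"""Promoter windows around transcription start sites.

Each promoter is the 2,000 bp upstream / 1,000 bp downstream window
around a TSS, strand-aware: minus-strand promoters are reverse
complemented and their per-base conservation is reversed so both are in
5'->3' promoter orientation.  Coordinates are 0-based half-open (BED
convention); the TSS base itself counts as the first downstream base.

Promoters sharing more than 1,500 bp of genomic sequence are redundant
for motif counting; the deduplication step randomly keeps one promoter
out of each overlapping set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

__all__ = [
    "Promoter",
    "PromoterUniverse",
    "read_tss_bed",
    "read_bedgraph",
    "extract_promoter_windows",
    "overlap_bp",
    "dedupe_overlapping",
]


@dataclass
class Promoter:
    gene_id: str
    chrom: str
    start: int  # genomic, 0-based inclusive
    end: int  # genomic, exclusive
    strand: str
    sequence: str  # 5'->3' promoter orientation
    conservation: np.ndarray = field(repr=False)  # aligned to sequence

    def __post_init__(self):
        self.conservation = np.asarray(self.conservation, dtype=float)
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match interval")
        if self.conservation.size != len(self.sequence):
            raise ValueError("conservation length does not match sequence")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def interval(self) -> tuple[str, int, int]:
        return self.chrom, self.start, self.end


@dataclass
class PromoterUniverse:
    promoters: list[Promoter]
    cluster_membership: dict[str, int] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [p.gene_id for p in self.promoters]


def read_tss_bed(path) -> pd.DataFrame:
    """Read a BED6 file of TSS records (one base per record)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    if df.isnull().any().any():
        raise ValueError(f"malformed BED file: {path}")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("BED strand must be '+' or '-'")
    return df


def read_bedgraph(path) -> dict[str, list[tuple[int, int, float]]]:
    """Read bedGraph conservation intervals grouped by chromosome."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    out: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        out[chrom] = list(
            zip(grp["start"].astype(int), grp["end"].astype(int), grp["value"])
        )
    return out


def _dense_conservation(
    intervals: list[tuple[int, int, float]], length: int
) -> np.ndarray:
    """Expand bedGraph intervals into one per-base array (uncovered = 0)."""
    arr = np.zeros(length)
    for s, e, v in intervals:
        lo, hi = max(s, 0), min(e, length)
        if lo < hi:
            arr[lo:hi] = v
    return arr


def extract_promoter_windows(
    tss: pd.DataFrame,
    genome_fasta,
    conservation: dict[str, list[tuple[int, int, float]]] | None = None,
    upstream: int = 2000,
    downstream: int = 1000,
) -> list[Promoter]:
    """Cut strand-aware promoter windows out of the genome.

    For a plus-strand TSS at 0-based position t the window is
    [t - upstream, t + downstream); for a minus-strand TSS it is
    [t - downstream + 1, t + upstream + 1) with the sequence reverse
    complemented.  Windows are clipped at chromosome edges.  Bases with no
    conservation record get conservation 0.
    """
    genome = Fasta(str(genome_fasta)) if not isinstance(genome_fasta, Fasta) else genome_fasta
    conservation = conservation or {}
    dense: dict[str, np.ndarray] = {}
    promoters = []
    for row in tss.itertuples(index=False):
        if row.chrom not in genome:
            raise KeyError(f"chromosome {row.chrom!r} absent from FASTA")
        chrom_len = len(genome[row.chrom])
        if row.chrom not in dense:
            dense[row.chrom] = _dense_conservation(
                conservation.get(row.chrom, []), chrom_len
            )
        t = int(row.start)
        if not 0 <= t < chrom_len:
            raise ValueError(f"TSS {row.gene_id} outside chromosome bounds")
        if row.strand == "+":
            start, end = t - upstream, t + downstream
        else:
            start, end = t - downstream + 1, t + upstream + 1
        start, end = max(0, start), min(chrom_len, end)
        seq = genome[row.chrom][start:end].seq.upper()
        cons = dense[row.chrom][start:end].copy()
        if row.strand == "-":
            seq = seq.translate(COMPLEMENT)[::-1]
            cons = cons[::-1]
        promoters.append(
            Promoter(
                gene_id=row.gene_id, chrom=row.chrom, start=start, end=end,
                strand=row.strand, sequence=seq, conservation=cons,
            )
        )
    return promoters


def overlap_bp(a: Promoter, b: Promoter) -> int:
    """Genomic overlap in bases, irrespective of strand."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def dedupe_overlapping(
    promoters: Sequence[Promoter],
    seed: int,
    max_overlap: int = 1500,
) -> list[Promoter]:
    """Randomly discard promoters until no pair overlaps > ``max_overlap`` bp.

    Overlaps of exactly ``max_overlap`` bases are allowed (the rule is a
    strict inequality).  Violating pairs are visited in deterministic
    order (sorted by chrom, start, gene id) and one member of each is
    discarded by a seeded uniform draw, repeating until clean; promoters
    discarded early that no longer conflict with anything kept are then
    re-admitted, so the result is a maximal conflict-free subset.
    """
    rng = np.random.default_rng(seed)
    kept = sorted(promoters, key=lambda p: (p.chrom, p.start, p.end, p.gene_id))
    removed: list[Promoter] = []
    while True:
        violation = None
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                if kept[j].chrom != kept[i].chrom or kept[j].start >= kept[i].end:
                    break
                if overlap_bp(kept[i], kept[j]) > max_overlap:
                    violation = (i, j)
                    break
            if violation:
                break
        if violation is None:
            break
        drop = violation[int(rng.integers(2))]
        removed.append(kept.pop(drop))
    # re-admit discards whose conflicts were themselves discarded
    changed = True
    while changed:
        changed = False
        for cand in sorted(removed, key=lambda p: (p.chrom, p.start, p.gene_id)):
            if all(overlap_bp(cand, k) <= max_overlap for k in kept):
                kept.append(cand)
                removed.remove(cand)
                changed = True
        kept.sort(key=lambda p: (p.chrom, p.start, p.end, p.gene_id))
    return kept
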