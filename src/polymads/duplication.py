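"""Duplicate-pair calling, tandem/segmental typing and segment localization.

Pairs are called from global CDS identity (≥ 90% by default, inclusive) with
non-homeologous status; a minimum aligned-overlap fraction of the shorter
CDS stands in for a database-dependent E-value cut.  Same-chromosome pairs
are tandem, different placed chromosomes segmental; genes on the unplaced
(U) chromosome can be resolved when all their duplicate partners share one
chromosome.  Chromosome segments follow the R1/R2a/C/R2b/R3 partitioning:
R1 and R3 are distal telomeric, R2a/C/R2b central.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import Align

from .homeology import HomeologGroup

SEGMENTS = ("R1", "R2a", "C", "R2b", "R3")
DISTAL = frozenset({"R1", "R3"})


class DataError(ValueError):
    pass


def _make_nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    return aligner


def cds_identity(a: str, b: str) -> Tuple[float, float]:
    """Percent identity and overlap coverage of two CDS.

    Identity = matches / aligned columns with terminal gap columns excluded
    and internal gaps counted as mismatches, × 100.  Coverage = ungapped
    overlap length / length of the shorter sequence.
    """
    if not a or not b:
        raise DataError("empty CDS")
    aligner = _make_nt_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    first = 0
    last = len(row_a)
    while first < last and (row_a[first] == "-" or row_b[first] == "-"):
        first += 1
    while last > first and (row_a[last - 1] == "-" or row_b[last - 1] == "-"):
        last -= 1
    matches = 0
    overlap = 0
    columns = last - first
    for ca, cb in zip(row_a[first:last], row_b[first:last]):
        if ca != "-" and cb != "-":
            overlap += 1
            if ca == cb:
                matches += 1
    if columns == 0:
        return 0.0, 0.0
    identity = 100.0 * matches / columns
    coverage = overlap / min(len(a), len(b))
    return identity, coverage


@dataclass
class IdentityMatrix:
    gene_ids: List[str]
    identity: pd.DataFrame  # percent, symmetric, diagonal 100
    coverage: pd.DataFrame  # fraction of the shorter CDS aligned


def identity_matrix(cds: Mapping[str, str]) -> IdentityMatrix:
    """All-vs-all CDS identity; symmetric with diagonal 100."""
    genes = sorted(cds)
    n = len(genes)
    ident = np.full((n, n), 100.0)
    cover = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid, cov = cds_identity(cds[genes[i]], cds[genes[j]])
            ident[i, j] = ident[j, i] = pid
            cover[i, j] = cover[j, i] = cov
    return IdentityMatrix(
        genes,
        pd.DataFrame(ident, index=genes, columns=genes),
        pd.DataFrame(cover, index=genes, columns=genes),
    )


def same_subgenome_duplicates(
    matrix: IdentityMatrix,
    subgenome_of: Mapping[str, str],
    threshold: float = 90.0,
    min_coverage: float = 0.5,
) -> List[Tuple[str, str]]:
    """High-identity pairs on one subgenome: duplicates by construction.

    Same-subgenome copies can never be homeologs, so these calls need no
    homeology information and can seed the triad-detection exemptions.
    """
    out = []
    genes = matrix.gene_ids
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if subgenome_of.get(a) != subgenome_of.get(b):
                continue
            if subgenome_of.get(a) not in ("A", "B", "D"):
                continue
            if (
                matrix.identity.at[a, b] >= threshold
                and matrix.coverage.at[a, b] >= min_coverage
            ):
                out.append((a, b))
    return out


@dataclass
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity: float
    coverage: float
    homeologous: bool = False
    dup_type: str = "unplaced"  # tandem | segmental | unplaced
    location_category: Optional[str] = None
    boundary: bool = False  # identity exactly at the threshold

    @property
    def genes(self) -> Tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class DuplicationCalls:
    pairs: List[DuplicatePair]
    nonredundant_genes: List[str]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def call_duplicates(
    matrix: IdentityMatrix,
    groups: Sequence[HomeologGroup],
    subgenome_of: Mapping[str, str],
    threshold: float = 90.0,
    min_coverage: float = 0.5,
    exclude: Iterable[str] = (),
) -> DuplicationCalls:
    """All unordered non-homeologous pairs with identity ≥ threshold.

    A pair is homeologous — and therefore exempt — when its genes share a
    detected homeolog group AND lie on different subgenomes.  ``exclude``
    removes genes (e.g. non-family decoys) from consideration.  Pairs whose
    identity sits exactly at the threshold carry a boundary flag.
    """
    group_of: Dict[str, int] = {}
    for gi, group in enumerate(groups):
        for gid in group.gene_ids:
            group_of[gid] = gi
    excluded = set(exclude)
    pairs: List[DuplicatePair] = []
    genes = [g for g in matrix.gene_ids if g not in excluded]
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            pid = float(matrix.identity.at[a, b])
            cov = float(matrix.coverage.at[a, b])
            if pid < threshold or cov < min_coverage:
                continue
            same_group = group_of.get(a) is not None and group_of.get(a) == group_of.get(b)
            cross_subgenome = subgenome_of.get(a) != subgenome_of.get(b)
            homeologous = same_group and cross_subgenome
            if homeologous:
                continue
            pairs.append(
                DuplicatePair(
                    a, b, identity=pid, coverage=cov,
                    homeologous=False, boundary=(pid == threshold),
                )
            )
    nonredundant = sorted({g for p in pairs for g in p.genes})
    return DuplicationCalls(pairs=pairs, nonredundant_genes=nonredundant)


def classify_dup_type(
    pair: DuplicatePair, chromosome_of: Mapping[str, str]
) -> str:
    """tandem (same chromosome) / segmental (different placed) / unplaced."""
    ca = chromosome_of.get(pair.gene_a, "U")
    cb = chromosome_of.get(pair.gene_b, "U")
    if ca == "U" or cb == "U":
        return "unplaced"
    return "tandem" if ca == cb else "segmental"


def infer_unplaced_chromosome(
    gene: str,
    pairs: Sequence[DuplicatePair],
    chromosome_of: Mapping[str, str],
) -> Optional[str]:
    """Chromosome shared by ALL placed duplicate partners of a U gene."""
    partners = []
    for p in pairs:
        if gene == p.gene_a:
            partners.append(p.gene_b)
        elif gene == p.gene_b:
            partners.append(p.gene_a)
    placed = {chromosome_of.get(p, "U") for p in partners} - {"U"}
    if len(placed) == 1:
        return placed.pop()
    return None


# ---------------------------------------------------------------------------
# chromosome segments


@dataclass
class SegmentMap:
    """Per-chromosome R1/R2a/C/R2b/R3 boundaries."""

    breakpoints: Dict[str, Tuple[int, int, int, int]]
    lengths: Dict[str, int]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SegmentMap":
        df = pd.read_csv(path, sep="\t")
        bps = {
            str(r.chromosome): (int(r.b1), int(r.b2), int(r.b3), int(r.b4))
            for r in df.itertuples()
        }
        lengths = {str(r.chromosome): int(r.length) for r in df.itertuples()}
        return cls(bps, lengths)

    def assign(self, chromosome: str, start: int, end: int) -> Tuple[str, str]:
        """Segment containing the gene midpoint, plus its distal/central zone."""
        if chromosome not in self.breakpoints:
            raise DataError(f"no segment map for chromosome {chromosome}")
        mid = (start + end) / 2.0
        length = self.lengths[chromosome]
        if mid > length or mid < 1:
            raise DataError(f"midpoint {mid} outside chromosome {chromosome}")
        edges = [0, *self.breakpoints[chromosome], length]
        for seg, lo, hi in zip(SEGMENTS, edges[:-1], edges[1:]):
            if mid <= hi:
                return seg, ("distal" if seg in DISTAL else "central")
        return "R3", "distal"


def assign_segment(
    gene: str, annotation: Mapping[str, Tuple[str, int, int]], segmap: SegmentMap
) -> Tuple[str, str]:
    """Segment + zone for one gene given (chromosome, start, end)."""
    chrom, start, end = annotation[gene]
    return segmap.assign(chrom, start, end)


def locate_pair_category(zone_a: str, zone_b: str) -> str:
    """distal+distal → distal_telomeric; mixed → sub_telomeric; else proximal."""
    distal = (zone_a == "distal") + (zone_b == "distal")
    if distal == 2:
        return "distal_telomeric"
    if distal == 1:
        return "sub_telomeric"
    return "proximal"


def annotate_pairs(
    calls: DuplicationCalls,
    chromosome_of: Mapping[str, str],
    coords: Mapping[str, Tuple[str, int, int]],
    segmap: Optional[SegmentMap] = None,
) -> DuplicationCalls:
    """Fill dup_type (resolving U genes when possible) and location category."""
    resolved = dict(chromosome_of)
    for p in calls.pairs:
        for g in p.genes:
            if resolved.get(g, "U") == "U":
                inferred = infer_unplaced_chromosome(g, calls.pairs, chromosome_of)
                if inferred is not None:
                    resolved[g] = inferred
    for p in calls.pairs:
        p.dup_type = classify_dup_type(p, resolved)
        if segmap is not None and p.dup_type != "unplaced":
            zones = []
            for g in p.genes:
                if g in coords and resolved.get(g, "U") != "U":
                    chrom = resolved[g]
                    _, start, end = coords[g]
                    zones.append(segmap.assign(chrom, start, end)[1])
            if len(zones) == 2:
                p.location_category = locate_pair_category(*zones)
    return calls


def chromosome_density(
    annotation: pd.DataFrame, lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Genes per chromosome and per Mbp (distribution-figure style table)."""
    counts = annotation.groupby("chromosome")["gene_id"].count()
    rows = []
    for chrom in sorted(lengths):
        n = int(counts.get(chrom, 0))
        rows.append(
            {
                "chromosome": chrom,
                "n_genes": n,
                "genes_per_mbp": n / (lengths[chrom] / 1e6),
            }
        )
    return pd.DataFrame(rows)
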